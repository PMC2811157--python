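"""Tests for motif matching, site annotation and the recurrent-conserved
consensus-site filter."""

import numpy as np
import pytest

from phosconet import (
    DEFAULT_SPECIES,
    KinaseMotif,
    MotifLibrary,
    PhosphoSiteRecord,
    SimulationConfig,
    annotate_site,
    annotate_sites,
    filter_recurrent_conserved,
    match_motif,
    score_site,
    score_sites,
    simulate_family,
)
from phosconet.errors import ConfigError, InputError, InvalidPositionError
from phosconet.records import AMINO_ACIDS
from conftest import make_family
from helpers import brute_match_motif

MPM2_PEPTIDE = "PFIVPSSPTEQEGRY"  # pSer at position 7 (S-S-P context)


class TestMatchMotif:
    def test_atm_atr_sq_context(self, library):
        assert match_motif("AAAAASQAAAA", 6, library.get("ATM/ATR"))

    def test_cdk_and_pbd_on_ssp_context(self, library):
        assert match_motif(MPM2_PEPTIDE, 7, library.get("CDK-minimal"))
        assert match_motif(MPM2_PEPTIDE, 7, library.get("PBD-docking"))

    def test_sq_context_is_not_cdk(self, library):
        assert not match_motif("AAAAASQAAAA", 6, library.get("CDK-minimal"))

    def test_required_slot_outside_sequence_fails(self, library):
        assert not match_motif("AS", 2, library.get("ATM/ATR"))  # +1 off the end

    def test_out_of_range_position_rejected(self, library):
        with pytest.raises(InvalidPositionError):
            match_motif("AAAA", 9, library.get("ATM/ATR"))

    def test_agrees_with_brute_force_checker(self, library):
        rng = np.random.default_rng(77)
        motifs = list(library)
        for _ in range(300):
            L = int(rng.integers(3, 25))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            pos = int(rng.integers(1, L + 1))
            motif = motifs[int(rng.integers(len(motifs)))]
            expected = brute_match_motif(
                seq, pos, motif.central_allowed, dict(motif.required)
            )
            assert match_motif(seq, pos, motif) is expected

    def test_invariant_under_changes_outside_required_slots(self, library):
        rng = np.random.default_rng(88)
        motif = library.get("Plk1")
        base = "AAADASQAAAA"
        pos = 6
        expected = match_motif(base, pos, motif)
        touched = {pos + off for off in motif.required} | {pos}
        for _ in range(100):
            i = int(rng.integers(1, len(base) + 1))
            if i in touched:
                continue
            mutated = base[:i - 1] + str(rng.choice(list(AMINO_ACIDS))) + base[i:]
            assert match_motif(mutated, pos, motif) is expected


def test_default_library_contents(library):
    assert set(library.names) == {
        "ATM/ATR", "CDK-minimal", "CDK-strict", "Plk1", "PBD-docking", "Chk1/2"
    }
    atm = library.get("ATM/ATR")
    assert atm.central_allowed == frozenset("ST") and atm.required == {1: frozenset("Q")}
    plk1 = library.get("Plk1")
    assert plk1.required == {-2: frozenset("DE")}


def test_library_from_custom_yaml(tmp_path):
    path = tmp_path / "motifs.yaml"
    path.write_text(
        "motifs:\n"
        "  - name: CK2\n"
        "    kinase: CK2\n"
        "    central: [S, T]\n"
        "    required:\n"
        "      \"+3\": [D, E]\n"
    )
    lib = MotifLibrary.from_yaml(path)
    ck2 = lib.get("CK2")
    assert ck2.required == {3: frozenset("DE")}
    assert match_motif("AAASAADAA", 4, ck2)


def test_bad_offset_rejected():
    with pytest.raises(ConfigError):
        KinaseMotif("bad", frozenset("S"), {6: frozenset("Q")})


class TestAnnotateSite:
    def test_known_kinase_kept_regardless_of_motifs(self, library):
        seq = "AAAAASQAAAA"
        fam = make_family("P1", {"H.sap": seq, "M.mus": seq})
        site = PhosphoSiteRecord("P1", 6, "S", known_kinases=("ATM",))
        ann = annotate_site(site, fam, library)
        assert ann.assigned_kinases == (("ATM", "known"),)
        assert "ATM/ATR" in ann.matched_motifs

    def test_sp_context_predicts_cdk(self, library):
        seq = "AAAAASPAAAA"
        fam = make_family("P1", {"H.sap": seq, "M.mus": seq})
        site = PhosphoSiteRecord("P1", 6, "S")
        ann = annotate_site(site, fam, library)
        assert ("CDK1/2", "predicted") in ann.assigned_kinases

    def test_external_predictions_attached(self, library):
        seq = "AAAAASQAAAA"
        fam = make_family("P1", {"H.sap": seq, "M.mus": seq})
        site = PhosphoSiteRecord("P1", 6, "S")
        ann = annotate_site(site, fam, library,
                            external_predictions={("P1", 6): ["PLK3"]})
        assert ("PLK3", "predicted") in ann.assigned_kinases

    def test_pbd_docking_flag(self, library):
        fam = make_family("P1", {"H.sap": MPM2_PEPTIDE, "M.mus": MPM2_PEPTIDE})
        ann = annotate_site(PhosphoSiteRecord("P1", 7, "S"), fam, library)
        assert ann.pbd_site

    def test_protein_mismatch_rejected(self, library):
        fam = make_family("P1", {"H.sap": "AAAAASQAAAA"})
        with pytest.raises(InputError):
            annotate_site(PhosphoSiteRecord("P2", 6, "S"), fam, library)

    def test_planted_motif_fully_conserved_at_zero_factor(self, library):
        """With constraint_factor=0 a planted Plk1 consensus survives in
        every present species, so its motif conservation is exactly 1."""
        cfg = SimulationConfig(seed=13, constraint_factor=0.0)
        fam, records, truth = simulate_family(cfg, planted_motif=library.get("Plk1"))
        constrained = set(truth.positions("constrained"))
        for rec in records:
            if rec.position not in constrained:
                continue
            ann = annotate_site(rec, fam, library)
            assert ann.motif_conservation["Plk1"] == 1.0


class TestFilter:
    def _pipeline(self, chk2_roster, library, **kw):
        family, sites = chk2_roster
        families = {"CHK2FHA": family}
        summaries = score_sites(families, sites)
        annotations = annotate_sites(sites, families, library)
        return filter_recurrent_conserved(sites, annotations, summaries,
                                          library=library, **kw)

    def test_exactly_three_sites_survive(self, chk2_roster, library):
        """Observed >= 2, conserved phospho-residue, conserved [D/E]X[S/T]
        consensus: the planted S164/T205/S210 trio and nothing else."""
        kept = self._pipeline(chk2_roster, library)
        assert [s.position for s in kept] == [164, 205, 210]

    def test_single_observation_dropped(self, chk2_roster, library):
        kept = self._pipeline(chk2_roster, library)
        assert 100 not in {s.position for s in kept}  # conserved but seen once

    def test_seed_without_motif_dropped(self, chk2_roster, library):
        kept = self._pipeline(chk2_roster, library)
        assert 130 not in {s.position for s in kept}

    def test_raising_min_observations_never_adds_sites(self, chk2_roster, library):
        previous = None
        for m in range(1, 7):
            kept = {s.position for s in
                    self._pipeline(chk2_roster, library, min_observations=m)}
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_relaxed_threshold_recovers_partially_conserved(self, chk2_roster, library):
        kept = {s.position for s in
                self._pipeline(chk2_roster, library, conservation_threshold=0.9)}
        assert {164, 205, 210, 140, 150} <= kept

    def test_unknown_motif_rejected(self, chk2_roster, library):
        with pytest.raises(ConfigError):
            self._pipeline(chk2_roster, library, motif_name="NoSuchMotif")

    def test_missing_summary_rejected(self, chk2_roster, library):
        family, sites = chk2_roster
        families = {"CHK2FHA": family}
        annotations = annotate_sites(sites, families, library)
        with pytest.raises(InputError):
            filter_recurrent_conserved(sites, annotations, [], library=library)
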