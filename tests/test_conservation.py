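"""Tests for the conservation statistic: the S<->T central rule, window
scoring against a brute-force oracle, and the across-species aggregation."""

import numpy as np
import pytest

from phosconet import (
    PhosphoSiteRecord,
    SiteWindow,
    SpeciesScore,
    central_conserved,
    site_summary,
    window_conservation,
)
from phosconet.errors import InputError
from phosconet.records import AMINO_ACIDS, GAP, UNKNOWN
from helpers import brute_window_score


def _window(center, flanks, species="M.mus"):
    """Build a SiteWindow from a (seed, orth) center pair and flank pairs."""
    pairs = []
    offsets = [o for o in range(-5, 6) if o != 0]
    for off, (s, o) in zip(offsets, flanks):
        pairs.append((off, s, o))
    return SiteWindow(
        protein_id="P1", position=50, species=species, variant="variant1",
        central_column=49, central_pair=center, flank_pairs=tuple(pairs),
    )


class TestCentralRule:
    def test_serine_threonine_interchange(self):
        assert central_conserved("S", "T")
        assert central_conserved("T", "S")

    def test_tyrosine_swap_not_permitted(self):
        assert not central_conserved("S", "Y")
        assert not central_conserved("T", "Y")
        assert central_conserved("Y", "Y")
        assert not central_conserved("Y", "S")

    def test_gap_never_conserves(self):
        assert not central_conserved("S", GAP)
        assert not central_conserved("Y", GAP)

    def test_exhaustive_truth_table(self):
        """The rule over every pair drawn from the 20 amino acids plus gap:
        conserved iff identical residues, or both in {S, T}."""
        alphabet = AMINO_ACIDS + GAP
        for a in alphabet:
            for b in alphabet:
                expected = (a == b and a != GAP) or (a in "ST" and b in "ST")
                assert central_conserved(a, b) is expected, (a, b)


class TestWindowConservation:
    def test_seven_of_eight_flanks(self):
        """8 comparable flanks, 7 identical, conserved center -> 87.5%."""
        flanks = [("A", "A")] * 7 + [("L", "V")]
        score = window_conservation(_window(("S", "S"), flanks))
        assert score.status == "numeric"
        assert score.window_score == pytest.approx(0.875)
        assert score.n_comparable_flanks == 8

    def test_five_of_eight_flanks(self):
        """8 comparable flanks, 5 identical, conserved center -> 62.5%."""
        flanks = [("A", "A")] * 5 + [("L", "V"), ("K", "R"), ("E", "D")]
        score = window_conservation(_window(("S", "T"), flanks))
        assert score.window_score == pytest.approx(0.625)

    def test_identical_window_scores_one(self):
        flanks = [(ch, ch) for ch in "ALKEDFIVPM"]
        score = window_conservation(_window(("T", "T"), flanks))
        assert score.window_score == 1.0 and score.central_conserved

    def test_central_loss_forces_zero(self):
        flanks = [(ch, ch) for ch in "ALKEDFIVPM"]
        score = window_conservation(_window(("S", "A"), flanks))
        assert score.status == "numeric"
        assert score.window_score == 0.0
        assert score.central_conserved is False

    def test_gap_flank_is_comparable_but_not_conserved(self):
        flanks = [("A", "A")] * 7 + [("L", GAP)]
        score = window_conservation(_window(("S", "S"), flanks))
        assert score.window_score == pytest.approx(7 / 8)
        assert score.n_comparable_flanks == 8

    def test_unknown_flank_excluded_from_denominator(self):
        flanks = [("A", "A")] * 7 + [("L", UNKNOWN)]
        score = window_conservation(_window(("S", "S"), flanks))
        assert score.window_score == 1.0
        assert score.n_comparable_flanks == 7

    def test_unknown_center_is_incomplete(self):
        flanks = [("A", "A")] * 10
        score = window_conservation(_window(("S", UNKNOWN), flanks))
        assert score.status == "Incomplete"
        assert score.window_score is None

    def test_no_comparable_flanks_is_incomplete(self):
        flanks = [("A", UNKNOWN)] * 10
        score = window_conservation(_window(("S", "S"), flanks))
        assert score.status == "Incomplete"

    def test_matches_brute_force_on_random_windows(self):
        """The scorer agrees exactly with an independent column-walking
        oracle on 1,000 random simulated alignment windows."""
        rng = np.random.default_rng(123)
        alphabet = list(AMINO_ACIDS + GAP + UNKNOWN)
        for _ in range(1000):
            L = int(rng.integers(11, 40))
            seed_chars = rng.choice(list(AMINO_ACIDS + GAP), size=L)
            center_col = int(rng.integers(L))
            seed_chars[center_col] = rng.choice(list("STY"))
            seed_aln = "".join(seed_chars)
            orth_aln = "".join(rng.choice(alphabet, size=L))
            seed_cols = [i for i, ch in enumerate(seed_aln) if ch != GAP]
            p = seed_cols.index(center_col) + 1
            pairs = []
            for off in range(-5, 6):
                if off == 0 or not 1 <= p + off <= len(seed_cols):
                    continue
                col = seed_cols[p + off - 1]
                pairs.append((off, seed_aln[col], orth_aln[col]))
            window = SiteWindow("P", p, "M.mus", "variant1", center_col,
                                (seed_aln[center_col], orth_aln[center_col]),
                                tuple(pairs))
            got = window_conservation(window)
            status, score, central = brute_window_score(seed_aln, orth_aln, center_col)
            assert got.status == status
            if status == "numeric":
                assert got.window_score == score
                assert got.central_conserved == central


SITE = PhosphoSiteRecord("H2AX", 139, "S")


def _scores(values, species=None):
    species = species or ["M.mul", "C.fam", "M.mus", "R.nor", "O.ana", "X.tro"]
    return [
        SpeciesScore(sp, "numeric", v, v > 0, 8) for sp, v in zip(species, values)
    ]


class TestSiteSummary:
    def test_mean_of_fig_style_values(self):
        """Per-species scores 100, 100, 87.5, 87.5, 75, 62.5 (%) average to
        85.4% under the arithmetic mean over scored species."""
        summary = site_summary(SITE, _scores([1.0, 1.0, 0.875, 0.875, 0.75, 0.625]))
        assert summary.mean_window_conservation == pytest.approx(5.125 / 6)
        assert round(summary.mean_window_conservation, 3) == 0.854
        assert summary.central_conservation_rate == 1.0

    def test_single_species(self):
        summary = site_summary(SITE, _scores([1.0], ["M.mus"]))
        assert summary.mean_window_conservation == 1.0
        assert summary.central_conservation_rate == 1.0

    def test_all_na_gives_na(self):
        scores = [SpeciesScore(sp, "NA") for sp in ("M.mus", "R.nor")]
        summary = site_summary(SITE, scores)
        assert summary.mean_window_conservation is None
        assert summary.central_conservation_rate is None

    def test_incomplete_excluded_from_mean(self):
        scores = _scores([0.5], ["M.mus"]) + [SpeciesScore("R.nor", "Incomplete")]
        summary = site_summary(SITE, scores)
        assert summary.mean_window_conservation == 0.5

    def test_self_comparison_excluded_by_default(self):
        scores = _scores([1.0], ["H.sap"]) + _scores([0.5], ["M.mus"])
        excl = site_summary(SITE, scores, include_self=False, seed_species="H.sap")
        incl = site_summary(SITE, scores, include_self=True, seed_species="H.sap")
        assert excl.mean_window_conservation == 0.5
        assert incl.mean_window_conservation == 0.75

    def test_duplicate_species_rejected(self):
        with pytest.raises(InputError):
            site_summary(SITE, _scores([1.0, 0.5], ["M.mus", "M.mus"]))

    def test_mean_monotone_in_any_species_score(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            values = rng.random(6)
            base = site_summary(SITE, _scores(list(values)))
            i = int(rng.integers(6))
            bumped = values.copy()
            bumped[i] = min(1.0, bumped[i] + rng.random() * (1 - bumped[i]))
            improved = site_summary(SITE, _scores(list(bumped)))
            assert improved.mean_window_conservation >= base.mean_window_conservation
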