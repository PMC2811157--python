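"""Shared fixtures: hand-built ortholog families and the synthetic Chk2-like
FHA phosphopeptide roster used by the recurrent-conserved-site filter tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phosconet import (
    DEFAULT_SPECIES,
    MotifLibrary,
    OrthologFamily,
    PhosphoSiteRecord,
    plant_site,
)


def make_family(
    protein_id: str,
    members: dict,
    seed_key=("H.sap", "variant1"),
    species=DEFAULT_SPECIES,
) -> OrthologFamily:
    """Build a family from {(species, variant) | species: aligned sequence}."""
    normalized = {}
    for key, seq in members.items():
        if isinstance(key, str):
            key = (key, "variant1")
        normalized[key] = seq
    return OrthologFamily(
        protein_id=protein_id, members=normalized, seed_key=seed_key, species=species
    )


@pytest.fixture(scope="session")
def library() -> MotifLibrary:
    return MotifLibrary.default()


@pytest.fixture(scope="session")
def chk2_roster(library):
    """Synthetic stand-in for a kinase-FHA-domain phosphopeptide roster.

    Seven candidate phosphosites on one 260-residue protein with orthologs in
    all 11 species.  Exactly three sites — S164, T205, S210 — carry a
    recurrently observed, fully conserved [D/E]X[S/T] consensus; every other
    site fails exactly one of the three filter criteria.
    """
    rng = np.random.default_rng(20)
    length = 260
    aa = "ACDEFGHIKLMNPQRVW"  # no S/T/Y: centers are planted explicitly
    seed = "".join(rng.choice(list(aa), size=length))
    plk1 = library.get("Plk1")

    passing = [(164, "S"), (205, "T"), (210, "S")]
    # failing sites: (position, central, planted?, failure mode)
    only_once = (100, "S")       # conserved consensus, observed once
    no_motif = (130, "S")        # recurrent + conserved, no D/E at -2
    central_lost = (140, "T")    # consensus, but phospho-residue lost in mouse
    motif_lost = (150, "S")      # consensus on seed, -2 acidic residue lost in frog

    for pos, central in passing + [only_once, central_lost, motif_lost]:
        seed = plant_site(seed, pos, plk1, central)
    chars = list(seed)
    chars[no_motif[0] - 1] = no_motif[1]
    chars[no_motif[0] - 3] = "G"  # ensure no acidic residue at -2
    seed = "".join(chars)

    members = {sp: seed for sp in DEFAULT_SPECIES}
    mouse = list(seed)
    mouse[central_lost[0] - 1] = "A"  # central loss
    members["M.mus"] = "".join(mouse)
    frog = list(seed)
    frog[motif_lost[0] - 3] = "A"  # -2 slot loses the D/E requirement
    members["X.tro"] = "".join(frog)
    family = make_family("CHK2FHA", members)

    counts = {164: 3, 205: 2, 210: 5, 100: 1, 130: 3, 140: 2, 150: 2}
    residues = dict(passing + [only_once, no_motif, central_lost, motif_lost])
    sites = [
        PhosphoSiteRecord(
            protein_id="CHK2FHA",
            position=pos,
            residue=residues[pos],
            observation_count=counts[pos],
            source="synthetic-roster",
        )
        for pos in sorted(counts)
    ]
    return family, sites
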