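"""Synthetic ortholog families and phosphosite tables with the statistical
structure the conservation analysis assumes.

The generator emulates the study design: per-protein families of 11
vertebrate species (seed = human), some species missing, some sequences
truncated, several splice variants per species, and phospho-site −5/+5
windows evolving under stronger purifying constraint than the sequence
background.  Evolution follows a star phylogeny — each non-seed lineage
derives independently from the root — with a per-position substitution
probability ``p_sub_neutral`` outside constrained windows and
``p_sub_neutral × constraint_factor`` inside them.  Central residues of
true sites substitute only within {S, T}, mirroring the permitted S↔T
interchange; decoy sites evolve neutrally with unconstrained centers.
Because the model is substitution-only, the emitted family is already
aligned (columns are preserved); an optional gap mode inserts gap segments
to exercise gap handling downstream.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, InvalidPositionError
from .motifs import KinaseMotif
from .records import (
    AMINO_ACIDS,
    DEFAULT_SPECIES,
    GAP,
    OrthologFamily,
    PhosphoSiteRecord,
    UNKNOWN,
)

WINDOW_FLANK = 5
MIN_SITE_SPACING = 2 * WINDOW_FLANK + 1  # windows never overlap


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ortholog family.

    ``n_species`` counts the seed; probabilities are per-lineage (star
    phylogeny), so ``p_sub_neutral`` is the expected per-position divergence
    of each species from the human root.
    """

    n_species: int = 11
    seq_length: int = 400
    n_true_sites: int = 5
    n_decoy_sites: int = 5
    p_sub_neutral: float = 0.3
    constraint_factor: float = 0.2
    p_species_missing: float = 0.0
    p_truncation: float = 0.0
    n_variants_per_species: int = 1
    p_gap_segment: float = 0.0
    seed: int = 0
    protein_id: str = "SIM1"
    species: tuple[str, ...] = DEFAULT_SPECIES

    def validate(self) -> None:
        for name in ("p_sub_neutral", "constraint_factor", "p_species_missing",
                     "p_truncation", "p_gap_segment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.seq_length < MIN_SITE_SPACING:
            raise InvalidConfigError(
                f"seq_length must be >= {MIN_SITE_SPACING}, got {self.seq_length}"
            )
        if self.n_true_sites < 0 or self.n_decoy_sites < 0:
            raise InvalidConfigError("site counts must be non-negative")
        if not 1 <= self.n_species <= len(self.species):
            raise InvalidConfigError(
                f"n_species must lie in 1..{len(self.species)} "
                f"(declared species), got {self.n_species}"
            )
        if self.n_variants_per_species < 1:
            raise InvalidConfigError("n_variants_per_species must be >= 1")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one planted site: its class, any planted motif, and
    the realized substitution count in its window per present species."""

    site_id: str
    protein_id: str
    position: int
    site_class: str  # constrained | neutral
    planted_motif: str | None
    window_substitutions: Mapping[str, int]  # present species only


@dataclass(frozen=True)
class TruthTable:
    entries: tuple[TruthEntry, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    def by_class(self, site_class: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.site_class == site_class]

    def positions(self, site_class: str | None = None) -> list[int]:
        return [
            e.position
            for e in self.entries
            if site_class is None or e.site_class == site_class
        ]


def simulate_root_sequence(
    length: int,
    rng: np.random.Generator,
    composition: Sequence[float] | None = None,
) -> str:
    """A random root protein sequence, uniform over the 20 amino acids
    unless a composition vector (length 20, order ACDEFGHIKLMNPQRSTVWY)
    is supplied."""
    if length < MIN_SITE_SPACING:
        raise InvalidConfigError(f"length must be >= {MIN_SITE_SPACING}, got {length}")
    p = None
    if composition is not None:
        p = np.asarray(composition, dtype=float)
        if p.shape != (20,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise InvalidConfigError("composition must be 20 non-negative weights summing to 1")
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=p)
    return "".join(letters)


def plant_site(
    sequence: str,
    position: int,
    motif: KinaseMotif,
    central: str = "S",
) -> str:
    """Rewrite a sequence so that ``position`` matches the motif.

    Only the center and the motif's required slots are rewritten (each slot
    gets the alphabetically first allowed residue).  ``central`` must be one
    of the motif's allowed acceptors.
    """
    if central not in motif.central_allowed:
        raise InvalidConfigError(
            f"central residue {central!r} not allowed by motif {motif.name}"
        )
    if not 1 <= position <= len(sequence):
        raise InvalidPositionError(f"position {position} outside sequence")
    chars = list(sequence)
    for off, allowed in motif.required.items():
        j = position + off
        if not 1 <= j <= len(sequence):
            raise InvalidPositionError(
                f"motif {motif.name} offset {off:+d} falls outside the sequence "
                f"at position {position}"
            )
        chars[j - 1] = min(allowed)
    chars[position - 1] = central
    return "".join(chars)


def _place_site_positions(rng: np.random.Generator, length: int, n_sites: int) -> list[int]:
    """Sorted 1-based positions with full windows and pairwise spacing
    >= MIN_SITE_SPACING (windows never overlap)."""
    if n_sites == 0:
        return []
    lo, hi = WINDOW_FLANK + 1, length - WINDOW_FLANK
    # classic min-gap transform: draw sorted distinct values from a range
    # shrunk by (n-1)*(gap-1), then re-expand -- uniform over valid layouts
    shrink = (n_sites - 1) * (MIN_SITE_SPACING - 1)
    reduced = np.arange(lo, hi + 1 - shrink)
    if len(reduced) < n_sites:
        raise InvalidConfigError(
            f"cannot place {n_sites} sites >= {MIN_SITE_SPACING} residues apart "
            f"in a sequence of length {length}"
        )
    pos = np.sort(rng.choice(reduced, size=n_sites, replace=False))
    pos += np.arange(n_sites) * (MIN_SITE_SPACING - 1)
    return [int(p) for p in pos]


def _substitute(rng: np.random.Generator, residue: str) -> str:
    """Uniform draw from the 19 residues different from ``residue``."""
    others = AMINO_ACIDS.replace(residue, "")
    return others[int(rng.integers(len(others)))]


def simulate_family(
    config: SimulationConfig,
    planted_motif: KinaseMotif | None = None,
):
    """Simulate one aligned ortholog family.

    Returns ``(family, site_records, truth)``: the aligned family (seed
    first), phosphosite records for every true and decoy site (true sites
    carry observation counts >= 1 drawn from a shifted Poisson), and the
    ground-truth table with realized per-species window substitution counts.
    Byte-identical outputs for identical config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = config.species[: config.n_species]
    seed_species = species[0]
    L = config.seq_length
    n_sites = config.n_true_sites + config.n_decoy_sites

    root = simulate_root_sequence(L, rng)
    positions = _place_site_positions(rng, L, n_sites)
    classes = ["constrained"] * config.n_true_sites + ["neutral"] * config.n_decoy_sites
    rng.shuffle(classes)

    # Plant phospho-acceptor centers (and any motif) on the root.
    chars = list(root)
    for pos, cls in zip(positions, classes):
        central = "S" if rng.random() < 0.5 else "T"
        chars[pos - 1] = central
        if cls == "constrained" and planted_motif is not None:
            chars = list(
                plant_site("".join(chars), pos, planted_motif,
                           central if central in planted_motif.central_allowed else min(
                               planted_motif.central_allowed))
            )
    root = "".join(chars)

    true_positions = [p for p, c in zip(positions, classes) if c == "constrained"]
    true_centers = {p - 1 for p in true_positions}
    p_vec = np.full(L, config.p_sub_neutral)
    for pos in true_positions:
        lo = max(0, pos - 1 - WINDOW_FLANK)
        hi = min(L, pos + WINDOW_FLANK)
        p_vec[lo:hi] = config.p_sub_neutral * config.constraint_factor

    members: dict[tuple[str, str], str] = {(seed_species, "variant1"): root}
    per_species_counts: dict[str, dict[int, int]] = {}

    for sp in species[1:]:
        if rng.random() < config.p_species_missing:
            continue
        sub_mask = rng.random(L) < p_vec
        seq = list(root)
        for i in np.flatnonzero(sub_mask):
            i = int(i)
            if i in true_centers:
                seq[i] = "T" if seq[i] == "S" else "S"
            else:
                seq[i] = _substitute(rng, seq[i])
        if rng.random() < config.p_truncation:
            anchor = positions[int(rng.integers(n_sites))] if n_sites else L // 2
            cut = max(2, min(L, anchor + int(rng.integers(-WINDOW_FLANK, WINDOW_FLANK + 1))))
            seq[cut - 1:] = [UNKNOWN] * (L - cut + 1)
        if config.p_gap_segment > 0 and rng.random() < config.p_gap_segment:
            glen = int(rng.integers(5, 16))
            gstart = int(rng.integers(0, max(1, L - glen)))
            seq[gstart:gstart + glen] = [GAP] * glen
        evolved = "".join(seq)
        members[(sp, "variant1")] = evolved
        for k in range(2, config.n_variants_per_species + 1):
            vlen = int(rng.integers(8, 31))
            vstart = int(rng.integers(0, max(1, L - vlen)))
            vchars = list(evolved)
            vchars[vstart:vstart + vlen] = [GAP] * vlen
            members[(sp, f"variant{k}")] = "".join(vchars)
        counts = {}
        for pos in positions:
            lo = max(0, pos - 1 - WINDOW_FLANK)
            hi = min(L, pos + WINDOW_FLANK)
            counts[pos] = sum(
                1
                for j in range(lo, hi)
                if evolved[j] in AMINO_ACIDS and evolved[j] != root[j]
            )
        per_species_counts[sp] = counts

    family = OrthologFamily(
        protein_id=config.protein_id,
        members=members,
        seed_key=(seed_species, "variant1"),
        species=species,
    )

    records = []
    entries = []
    for pos, cls in zip(positions, classes):
        if cls == "constrained":
            count = 1 + int(rng.poisson(1.2))
            source = "sim:true"
        else:
            count = 1
            source = "sim:decoy"
        records.append(
            PhosphoSiteRecord(
                protein_id=config.protein_id,
                position=pos,
                residue=root[pos - 1],
                known_kinases=(),
                observation_count=count,
                source=source,
            )
        )
        entries.append(
            TruthEntry(
                site_id=f"{config.protein_id}:{pos}",
                protein_id=config.protein_id,
                position=pos,
                site_class=cls,
                planted_motif=(
                    planted_motif.name
                    if (planted_motif is not None and cls == "constrained")
                    else None
                ),
                window_substitutions={
                    sp: counts[pos] for sp, counts in per_species_counts.items()
                },
            )
        )
    return family, records, TruthTable(tuple(entries))


KINASE_POOL = ("ATM", "ATR", "CHK1", "CHK2", "CDK1", "CDK2", "PLK1", "CK2")
SOURCE_POOL = ("Phospho.ELM", "Phosphosite", "PBD-proteomics")


def simulate_site_collection(
    n_proteins: int = 33,
    n_sites: int = 244,
    seed: int = 0,
    protein_prefix: str = "DDR",
) -> list[PhosphoSiteRecord]:
    """A synthetic site collection shaped like the curated study input:
    ``n_sites`` mapped phospho-residues spread over ``n_proteins`` proteins,
    each site with residue, known kinases (possibly none), observation count
    and source tag.  Site positions are distinct within each protein."""
    if n_proteins < 1 or n_sites < n_proteins:
        raise InvalidConfigError("need n_sites >= n_proteins >= 1")
    rng = np.random.default_rng(seed)
    counts = np.ones(n_proteins, dtype=int)
    counts += rng.multinomial(n_sites - n_proteins, np.full(n_proteins, 1.0 / n_proteins))
    records = []
    for i, c in enumerate(counts):
        protein = f"{protein_prefix}{i + 1:02d}"
        length = 150 + 40 * int(c)
        positions = np.sort(rng.choice(np.arange(8, length - 7), size=int(c), replace=False))
        for pos in positions:
            residue = rng.choice(["S", "T", "Y"], p=[0.6, 0.3, 0.1])
            if rng.random() < 0.5:
                k = 1 + int(rng.random() < 0.2)
                kinases = tuple(rng.choice(KINASE_POOL, size=k, replace=False))
            else:
                kinases = ()
            records.append(
                PhosphoSiteRecord(
                    protein_id=protein,
                    position=int(pos),
                    residue=str(residue),
                    known_kinases=kinases,
                    observation_count=1 + int(rng.poisson(1.0)),
                    source=str(rng.choice(SOURCE_POOL)),
                )
            )
    return records


def simulate_cohort(
    n_proteins: int,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
    planted_motif: KinaseMotif | None = None,
    protein_prefix: str = "SIM",
):
    """Simulate families for a roster of proteins with per-protein child
    seeds derived deterministically from ``seed``.

    Returns ``(families, records, truths)`` keyed/concatenated by protein.
    """
    if base_config is None:
        base_config = SimulationConfig(
            seq_length=160, n_true_sites=2, n_decoy_sites=1, p_species_missing=0.1
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_proteins) & 0x7FFFFFFF
    families: dict[str, OrthologFamily] = {}
    records: list[PhosphoSiteRecord] = []
    truths: dict[str, TruthTable] = {}
    for i in range(n_proteins):
        cfg = replace(
            base_config,
            protein_id=f"{protein_prefix}{i + 1:02d}",
            seed=int(child_seeds[i]),
        )
        fam, recs, truth = simulate_family(cfg, planted_motif)
        families[cfg.protein_id] = fam
        records.extend(recs)
        truths[cfg.protein_id] = truth
    return families, records, truths
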