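"""Core domain records: phosphosites, ortholog families, site windows and
per-species conservation scores.

Coordinate conventions
----------------------
Phosphosite positions are 1-based residue indices on the *ungapped* human
seed sequence (the convention in which sites like "Ser139" are reported).
Alignment columns are internal and 0-based.  Gap characters (``-``) denote
an alignment gap / evolutionary loss; ``X`` denotes an unknown or
unretrievable residue (e.g. a truncated sequence model) — the two are kept
distinct throughout because they are scored differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import AlignmentError, ParseError, SeedError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: The 11 vertebrate genomes scored by default (human is the seed).
DEFAULT_SPECIES = (
    "H.sap",  # Homo sapiens (seed)
    "M.mul",  # Macaca mulatta
    "M.mus",  # Mus musculus
    "R.nor",  # Rattus norvegicus
    "B.tau",  # Bos taurus
    "C.fam",  # Canis familiaris
    "O.ana",  # Ornithorhynchus anatinus
    "G.gal",  # Gallus gallus
    "X.tro",  # Xenopus tropicalis
    "D.rer",  # Danio rerio
    "T.nig",  # Tetraodon nigroviridis
)
SEED_SPECIES = DEFAULT_SPECIES[0]

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class PhosphoSiteRecord:
    """One in-vivo mapped phospho-residue on a human protein."""

    protein_id: str
    position: int  # 1-based on the ungapped seed
    residue: str  # S, T or Y
    known_kinases: tuple[str, ...] = ()
    observation_count: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParseError(
                f"site {self.protein_id}: position must be >= 1, got {self.position}"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise ParseError(
                f"site {self.protein_id}:{self.position}: residue must be one of "
                f"S/T/Y, got {self.residue!r}"
            )
        if self.observation_count < 0:
            raise ParseError(
                f"site {self.protein_id}:{self.position}: negative observation count"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any character outside the 20 amino acids and the gap
    character to ``X`` (unknown)."""
    out = []
    for ch in seq.upper():
        out.append(ch if (ch in AMINO_ACIDS or ch == GAP) else UNKNOWN)
    return "".join(out)


@dataclass(frozen=True)
class OrthologFamily:
    """A protein's aligned sequences across species and splice variants.

    ``members`` maps ``(species, variant)`` to the aligned sequence; exactly
    one member — ``seed_key`` — is the human seed in which the phosphosites
    were mapped.  All member sequences share ``alignment_length`` columns.
    """

    protein_id: str
    members: Mapping[tuple[str, str], str]
    seed_key: tuple[str, str]
    species: tuple[str, ...] = DEFAULT_SPECIES
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.members:
            raise AlignmentError(f"family {self.protein_id}: no members")
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"family {self.protein_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if self.seed_key not in self.members:
            raise SeedError(f"family {self.protein_id}: seed record missing")
        unknown = {sp for sp, _ in self.members if sp not in self.species}
        if unknown:
            raise ParseError(
                f"family {self.protein_id}: unknown species tags {sorted(unknown)}"
            )
        object.__setattr__(self, "alignment_length", lengths.pop())

    @property
    def seed_sequence(self) -> str:
        return self.members[self.seed_key]

    @property
    def seed_species(self) -> str:
        return self.seed_key[0]

    def ungapped_seed(self) -> str:
        return self.seed_sequence.replace(GAP, "")

    def variants_of(self, species: str) -> list[str]:
        """Variant ids present for a species, sorted for determinism."""
        return sorted(v for sp, v in self.members if sp == species)

    def has_species(self, species: str) -> bool:
        return any(sp == species for sp, _ in self.members)


@dataclass(frozen=True)
class SiteWindow:
    """The −flank/+flank residue window of one site in one ortholog.

    ``flank_pairs`` holds ``(offset, seed_residue, ortholog_char)`` for every
    offset whose seed residue exists (windows shrink at sequence termini —
    absent offsets are omitted, never padded).  The ortholog character may be
    a residue, ``-`` (gap) or ``X`` (unknown).
    """

    protein_id: str
    position: int
    species: str
    variant: str
    central_column: int  # 0-based alignment column
    central_pair: tuple[str, str]
    flank_pairs: tuple[tuple[int, str, str], ...]


@dataclass(frozen=True)
class SpeciesScore:
    """Per-species outcome of window conservation scoring.

    ``status`` is ``numeric`` (window_score defined), ``NA`` (no ortholog for
    the species) or ``Incomplete`` (central residue unretrievable, or no
    comparable flank with a conserved center).
    """

    species: str
    status: str  # numeric | NA | Incomplete
    window_score: float | None = None
    central_conserved: bool | None = None
    n_comparable_flanks: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("numeric", "NA", "Incomplete"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "numeric":
            if self.window_score is None or not (0.0 <= self.window_score <= 1.0):
                raise ValueError("numeric score must lie in [0, 1]")
            if self.central_conserved is False and self.window_score != 0.0:
                raise ValueError("central loss forces a window score of 0")
        elif self.window_score is not None:
            raise ValueError("window_score defined only for numeric status")


@dataclass(frozen=True)
class ConservationSummary:
    """The per-site conservation row: one status/score per declared species,
    the across-species mean window conservation ("column M") and the
    central-residue conservation rate ("column N")."""

    protein_id: str
    position: int
    residue: str
    species_scores: Mapping[str, SpeciesScore]
    mean_window_conservation: float | None
    central_conservation_rate: float | None

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)
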