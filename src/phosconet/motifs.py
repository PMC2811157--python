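"""Kinase consensus motifs, Polo-box docking-site detection, per-species
motif conservation, and the recurrent-conserved-site filter.

A motif is an offset-indexed set of allowed residues around the
phospho-acceptor, e.g. ATM/ATR = central {S,T} with +1 = Q ("[S/T]Q"),
Plk1 = central {S,T} with −2 = {D,E} ("[D/E]X[S/T]"), and the Plk1 Polo-box
docking consensus S-[pS/pT]-P (−1 = S, +1 = P).  Motifs are deliberately
simple allowed-set patterns, not position-weight matrices: they are consumed
as annotations, and richer external predictors can be supplied as a table.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .alignment_map import DEFAULT_FLANK, extract_window, map_position_to_column, select_variant
from .errors import ConfigError, InputError, InvalidPositionError
from .records import (
    AMINO_ACIDS,
    ConservationSummary,
    OrthologFamily,
    PhosphoSiteRecord,
    SiteWindow,
)

PBD_MOTIF_NAME = "PBD-docking"


@dataclass(frozen=True)
class KinaseMotif:
    """An offset-indexed consensus: allowed central acceptors plus required
    residue sets at offsets −5…+5 (0 excluded).  ``kinase`` is the upstream
    kinase the motif is diagnostic of; None for pure docking motifs."""

    name: str
    central_allowed: frozenset
    required: Mapping[int, frozenset]
    kinase: str | None = None

    def __post_init__(self) -> None:
        if not self.central_allowed:
            raise ConfigError(f"motif {self.name}: empty central set")
        for off, allowed in self.required.items():
            if off == 0 or not -5 <= off <= 5:
                raise ConfigError(f"motif {self.name}: offset {off} outside -5..+5")
            if not allowed:
                raise ConfigError(f"motif {self.name}: empty residue set at {off:+d}")


class MotifLibrary:
    """Ordered, name-keyed collection of motifs, loadable from YAML."""

    def __init__(self, motifs: Iterable[KinaseMotif]):
        self._motifs: dict[str, KinaseMotif] = {}
        for m in motifs:
            if m.name in self._motifs:
                raise ConfigError(f"duplicate motif name {m.name!r}")
            self._motifs[m.name] = m

    def __iter__(self):
        return iter(self._motifs.values())

    def __len__(self) -> int:
        return len(self._motifs)

    def __contains__(self, name: str) -> bool:
        return name in self._motifs

    def get(self, name: str) -> KinaseMotif:
        if name not in self._motifs:
            raise ConfigError(f"unknown motif {name!r}; known: {sorted(self._motifs)}")
        return self._motifs[name]

    @property
    def names(self) -> list[str]:
        return list(self._motifs)

    @classmethod
    def from_yaml(cls, source) -> "MotifLibrary":
        """Load a library from a YAML path or file object."""
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "motifs" not in doc:
            raise ConfigError("motif library file must contain a top-level 'motifs' list")
        motifs = []
        for entry in doc["motifs"]:
            required = {
                int(str(off)): frozenset(str(r) for r in allowed)
                for off, allowed in (entry.get("required") or {}).items()
            }
            motifs.append(
                KinaseMotif(
                    name=str(entry["name"]),
                    central_allowed=frozenset(str(r) for r in entry["central"]),
                    required=required,
                    kinase=entry.get("kinase"),
                )
            )
        return cls(motifs)

    @classmethod
    def default(cls) -> "MotifLibrary":
        with resources.files("phosconet.data").joinpath("default_motifs.yaml").open(
            "r", encoding="utf-8"
        ) as fh:
            return cls.from_yaml(fh)


def match_motif(sequence: str, position: int, motif: KinaseMotif) -> bool:
    """Does an ungapped protein sequence satisfy the motif at ``position``?

    True iff the central residue is an allowed acceptor and every required
    offset lies inside the sequence and holds an allowed residue.
    """
    if not 1 <= position <= len(sequence):
        raise InvalidPositionError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    if sequence[position - 1] not in motif.central_allowed:
        return False
    for off, allowed in motif.required.items():
        j = position + off
        if not 1 <= j <= len(sequence):
            return False
        if sequence[j - 1] not in allowed:
            return False
    return True


def window_matches_motif(window: SiteWindow, motif: KinaseMotif) -> bool:
    """Does the *ortholog* side of a site window satisfy the motif?

    Evaluated on the species' aligned residues at the seed's window offsets;
    a required slot falling on a gap, an unknown residue, or beyond the seed
    terminus counts as motif failure.
    """
    orth_central = window.central_pair[1]
    if orth_central not in AMINO_ACIDS or orth_central not in motif.central_allowed:
        return False
    by_offset = {off: orth for off, _seed, orth in window.flank_pairs}
    for off, allowed in motif.required.items():
        orth = by_offset.get(off)
        if orth is None or orth not in AMINO_ACIDS or orth not in allowed:
            return False
    return True


@dataclass(frozen=True)
class SiteAnnotation:
    """Motif/kinase annotation of one site: motifs matched on the human seed,
    assigned kinases with provenance (known beats predicted), the Polo-box
    docking flag, and per-motif cross-species conservation fractions."""

    protein_id: str
    position: int
    residue: str
    matched_motifs: tuple[str, ...] = ()
    assigned_kinases: tuple[tuple[str, str], ...] = ()  # (kinase, known|predicted)
    pbd_site: bool = False
    motif_conservation: Mapping[str, float | None] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


def motif_conservation_fraction(
    family: OrthologFamily,
    position: int,
    motif: KinaseMotif,
    species_list: Sequence[str] | None = None,
    include_self: bool = False,
    flank: int = DEFAULT_FLANK,
) -> float | None:
    """Fraction of non-NA species whose selected-variant window satisfies the
    motif; None when no species is scorable."""
    species_list = tuple(species_list) if species_list is not None else family.species
    column = map_position_to_column(family, position)
    holds = 0
    total = 0
    for species in species_list:
        if not include_self and species == family.seed_species:
            continue
        if not family.has_species(species):
            continue  # NA: excluded from the denominator
        variant = select_variant(family, species, position, flank)
        window = extract_window(family, species, variant, column, flank)
        total += 1
        if window_matches_motif(window, motif):
            holds += 1
    return holds / total if total else None


def annotate_site(
    site: PhosphoSiteRecord,
    family: OrthologFamily,
    library: MotifLibrary | None = None,
    external_predictions: Mapping[tuple[str, int], Sequence[str]] | None = None,
    species_list: Sequence[str] | None = None,
    include_self: bool = False,
    flank: int = DEFAULT_FLANK,
) -> SiteAnnotation:
    """Annotate one site with motifs, kinases and the PBD docking flag.

    Experimentally known kinases are copied with provenance ``known`` and are
    never displaced; only when a site has no known kinase are motif-implied
    kinases (and any rows from an external prediction table, e.g.
    NetworKIN-style output) attached with provenance ``predicted``.
    """
    if site.protein_id != family.protein_id:
        raise InputError(
            f"site {site.protein_id}:{site.position} annotated against family "
            f"{family.protein_id}"
        )
    library = library if library is not None else MotifLibrary.default()
    seed_seq = family.ungapped_seed()
    matched = tuple(m.name for m in library if match_motif(seed_seq, site.position, m))
    assigned: list[tuple[str, str]] = [(k, "known") for k in site.known_kinases]
    if not assigned:
        seen = set()
        for name in matched:
            kinase = library.get(name).kinase
            if kinase and kinase not in seen:
                assigned.append((kinase, "predicted"))
                seen.add(kinase)
        if external_predictions:
            for kinase in external_predictions.get(site.key, ()):
                if kinase not in seen:
                    assigned.append((kinase, "predicted"))
                    seen.add(kinase)
    conservation = {
        name: motif_conservation_fraction(
            family, site.position, library.get(name), species_list, include_self, flank
        )
        for name in matched
    }
    return SiteAnnotation(
        protein_id=site.protein_id,
        position=site.position,
        residue=site.residue,
        matched_motifs=matched,
        assigned_kinases=tuple(assigned),
        pbd_site=PBD_MOTIF_NAME in matched,
        motif_conservation=conservation,
    )


def annotate_sites(
    sites: Iterable[PhosphoSiteRecord],
    families: Mapping[str, OrthologFamily],
    library: MotifLibrary | None = None,
    external_predictions: Mapping[tuple[str, int], Sequence[str]] | None = None,
    species_list: Sequence[str] | None = None,
    include_self: bool = False,
    flank: int = DEFAULT_FLANK,
) -> list[SiteAnnotation]:
    library = library if library is not None else MotifLibrary.default()
    out = []
    for site in sites:
        if site.protein_id not in families:
            raise InputError(f"no ortholog family for protein {site.protein_id}")
        out.append(
            annotate_site(
                site,
                families[site.protein_id],
                library,
                external_predictions,
                species_list,
                include_self,
                flank,
            )
        )
    return out


def filter_recurrent_conserved(
    sites: Sequence[PhosphoSiteRecord],
    annotations: Iterable[SiteAnnotation],
    summaries: Iterable[ConservationSummary],
    min_observations: int = 2,
    motif_name: str = "Plk1",
    conservation_threshold: float = 1.0,
    library: MotifLibrary | None = None,
) -> list[PhosphoSiteRecord]:
    """Select recurrently observed, evolutionarily conserved consensus sites.

    A site survives iff it was observed at least ``min_observations`` times,
    its central phospho-residue is conserved in at least
    ``conservation_threshold`` of scored species, and the named consensus
    motif (default the Plk1 [D/E]X[S/T] consensus) holds in at least the same
    fraction of species.  Input order is preserved.
    """
    library = library if library is not None else MotifLibrary.default()
    library.get(motif_name)  # raises ConfigError for an unknown motif
    ann_by_key = {}
    for a in annotations:
        ann_by_key[a.key] = a
    sum_by_key = {}
    for s in summaries:
        sum_by_key[s.key] = s
    kept = []
    for site in sites:
        if site.key not in ann_by_key or site.key not in sum_by_key:
            raise InputError(
                f"site {site.protein_id}:{site.position} lacks an annotation or summary"
            )
        if site.observation_count < min_observations:
            continue
        summary = sum_by_key[site.key]
        rate = summary.central_conservation_rate
        if rate is None or rate < conservation_threshold:
            continue
        motif_frac = ann_by_key[site.key].motif_conservation.get(motif_name)
        if motif_frac is None or motif_frac < conservation_threshold:
            continue
        kept.append(site)
    return kept
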