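"""The conservation statistic: per-species window conservation with the
S↔T central-residue rule, and its across-species aggregation.

A site's window is the 11-mer centered on the phospho-residue (5 flanking
residues on each side, fewer near a terminus).  For each species the score is
the fraction of *comparable* flanking residues identical to the human seed;
the central phospho-acceptor is tracked separately and governs the score:

* center conserved (identical, or an S↔T interchange) — score = identical
  flanks / comparable flanks;
* center lost (any other residue, a Y-swap, or a gap) — score = 0, however
  conserved the flanks are;
* center unretrievable (``X``) — the species is reported ``Incomplete``;
* species without an ortholog — ``NA``.

An ortholog-side gap in a flank slot counts as a comparable, non-conserved
position (evolutionary loss); an ortholog-side ``X`` is excluded from the
denominator (missing data).  These two states are deliberately distinct.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

from .alignment_map import DEFAULT_FLANK, extract_window, map_position_to_column, select_variant
from .errors import InputError
from .records import (
    AMINO_ACIDS,
    ConservationSummary,
    OrthologFamily,
    PhosphoSiteRecord,
    SiteWindow,
    SpeciesScore,
    UNKNOWN,
)


def central_conserved(seed_residue: str, ortholog_residue: str) -> bool:
    """Is the central phospho-acceptor conserved?

    True iff the residues are identical, or both lie in {S, T} (serine and
    threonine are interchangeable phospho-acceptors).  A tyrosine seed is
    conserved only by tyrosine; gaps and unknown residues never conserve.
    The seed residue is normally S, T or Y but the rule is total.
    """
    if ortholog_residue not in AMINO_ACIDS or seed_residue not in AMINO_ACIDS:
        return False
    if seed_residue == ortholog_residue:
        return True
    return seed_residue in "ST" and ortholog_residue in "ST"


def window_conservation(window: SiteWindow) -> SpeciesScore:
    """Score one species' window against the seed.

    Returns a numeric :class:`SpeciesScore` (possibly 0 on central loss), or
    ``Incomplete`` when the central ortholog residue is unknown or when the
    center is conserved but no flank is comparable (a 0/0 score is refused
    rather than defined as 1).
    """
    seed_c, orth_c = window.central_pair
    if orth_c == UNKNOWN:
        return SpeciesScore(window.species, "Incomplete")
    identical = 0
    comparable = 0
    for _off, seed_res, orth_res in window.flank_pairs:
        if orth_res == UNKNOWN:
            continue  # unretrievable: excluded from the denominator
        comparable += 1
        if orth_res == seed_res:
            identical += 1
    if not central_conserved(seed_c, orth_c):
        return SpeciesScore(window.species, "numeric", 0.0, False, comparable)
    if comparable == 0:
        return SpeciesScore(window.species, "Incomplete")
    return SpeciesScore(
        window.species, "numeric", identical / comparable, True, comparable
    )


def site_summary(
    site: PhosphoSiteRecord,
    scores: Iterable[SpeciesScore],
    include_self: bool = False,
    seed_species: str | None = None,
) -> ConservationSummary:
    """Aggregate per-species scores into the per-site summary row.

    ``mean_window_conservation`` is the arithmetic mean of numeric window
    scores; ``central_conservation_rate`` is the fraction of numeric species
    whose central residue is conserved.  NA and Incomplete species are
    excluded from both.  The seed species' trivial self-comparison is
    excluded unless ``include_self`` is set.  All-NA input yields NA (None)
    aggregates.
    """
    scores = list(scores)
    seen: set[str] = set()
    for s in scores:
        if s.species in seen:
            raise InputError(f"duplicate species {s.species!r} in site summary input")
        seen.add(s.species)
    eligible = [
        s
        for s in scores
        if include_self or seed_species is None or s.species != seed_species
    ]
    numeric = [s for s in eligible if s.status == "numeric"]
    if numeric:
        mean = sum(s.window_score for s in numeric) / len(numeric)
        rate = sum(1 for s in numeric if s.central_conserved) / len(numeric)
    else:
        mean = None
        rate = None
    return ConservationSummary(
        protein_id=site.protein_id,
        position=site.position,
        residue=site.residue,
        species_scores={s.species: s for s in scores},
        mean_window_conservation=mean,
        central_conservation_rate=rate,
    )


def score_site(
    family: OrthologFamily,
    site: PhosphoSiteRecord,
    species_list: Iterable[str] | None = None,
    include_self: bool = False,
    flank: int = DEFAULT_FLANK,
) -> ConservationSummary:
    """Score one site across every declared species of its family.

    For each species the best splice variant is selected first; species with
    no ortholog are reported NA.  The seed species scores 1.0 against itself
    and is kept in the per-species columns but excluded from the aggregates
    unless ``include_self``.
    """
    if site.protein_id != family.protein_id:
        raise InputError(
            f"site {site.protein_id}:{site.position} scored against family "
            f"{family.protein_id}"
        )
    species_list = tuple(species_list) if species_list is not None else family.species
    column = map_position_to_column(family, site.position)
    scores = []
    for species in species_list:
        if not family.has_species(species):
            scores.append(SpeciesScore(species, "NA"))
            continue
        variant = select_variant(family, species, site.position, flank)
        window = extract_window(family, species, variant, column, flank)
        scores.append(window_conservation(window))
    return site_summary(site, scores, include_self, family.seed_species)


def score_sites(
    families: Mapping[str, OrthologFamily],
    sites: Iterable[PhosphoSiteRecord],
    species_list: Iterable[str] | None = None,
    include_self: bool = False,
    flank: int = DEFAULT_FLANK,
) -> list[ConservationSummary]:
    """Score a site table against a dict of families keyed by protein id."""
    out = []
    for site in sites:
        if site.protein_id not in families:
            raise InputError(f"no ortholog family for protein {site.protein_id}")
        out.append(
            score_site(families[site.protein_id], site, species_list, include_self, flank)
        )
    return out
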