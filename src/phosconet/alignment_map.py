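"""Mapping seed-site positions into alignment columns and extracting
per-species residue windows.

The seed coordinate system is 1-based over the ungapped human sequence;
alignment columns are 0-based.  A window is defined over seed residues at
offsets −flank…+flank of the phospho-residue: each offset contributes the
alignment column of that *seed* residue, and the ortholog character found in
that column.  Offsets that run off the seed's termini are simply absent.
"""

from __future__ import annotations

from .errors import InvalidPositionError, SpeciesMissingError
from .records import GAP, OrthologFamily, SiteWindow

DEFAULT_FLANK = 5


def seed_position_columns(family: OrthologFamily) -> list[int]:
    """0-based alignment column of each ungapped seed residue.

    Entry ``i`` is the column of seed residue ``i + 1`` (1-based).
    """
    return [col for col, ch in enumerate(family.seed_sequence) if ch != GAP]


def map_position_to_column(family: OrthologFamily, position: int) -> int:
    """Alignment column holding the seed residue at ``position`` (1-based)."""
    if position < 1:
        raise InvalidPositionError(
            f"{family.protein_id}: position must be >= 1, got {position}"
        )
    cols = seed_position_columns(family)
    if position > len(cols):
        raise InvalidPositionError(
            f"{family.protein_id}: position {position} beyond seed length {len(cols)}"
        )
    return cols[position - 1]


def extract_window(
    family: OrthologFamily,
    species: str,
    variant: str,
    column: int,
    flank: int = DEFAULT_FLANK,
) -> SiteWindow:
    """Extract the −flank/+flank window around the seed residue at ``column``
    for one (species, variant) member.

    Raises :class:`SpeciesMissingError` if the member is absent (the caller
    maps this to an NA score) and :class:`InvalidPositionError` if ``column``
    does not hold a seed residue.
    """
    key = (species, variant)
    if key not in family.members:
        raise SpeciesMissingError(
            f"{family.protein_id}: no member for species={species} variant={variant}"
        )
    cols = seed_position_columns(family)
    try:
        position = cols.index(column) + 1
    except ValueError:
        raise InvalidPositionError(
            f"{family.protein_id}: column {column} is not a seed residue column"
        ) from None
    seed = family.seed_sequence
    orth = family.members[key]
    flank_pairs = []
    for off in range(-flank, flank + 1):
        if off == 0:
            continue
        pos = position + off
        if not 1 <= pos <= len(cols):
            continue  # window shrinks at termini
        col = cols[pos - 1]
        flank_pairs.append((off, seed[col], orth[col]))
    return SiteWindow(
        protein_id=family.protein_id,
        position=position,
        species=species,
        variant=variant,
        central_column=column,
        central_pair=(seed[column], orth[column]),
        flank_pairs=tuple(flank_pairs),
    )


def select_variant(
    family: OrthologFamily,
    species: str,
    position: int,
    flank: int = DEFAULT_FLANK,
) -> str:
    """Pick the splice variant of ``species`` that maximizes the site's
    window conservation.

    Ortholog databases carry several splice variants per species; the score
    used downstream is that of the most favorable variant.  Ties break by
    higher central-residue conservation, then longer ungapped sequence, then
    lexicographically smallest variant id — the result is therefore
    deterministic and independent of member insertion order.
    """
    variants = family.variants_of(species)
    if not variants:
        raise SpeciesMissingError(
            f"{family.protein_id}: species {species} absent from family"
        )
    from .conservation import window_conservation  # deferred: avoids cycle

    column = map_position_to_column(family, position)
    status_rank = {"numeric": 2, "Incomplete": 1, "NA": 0}

    def sort_key(variant: str):
        score = window_conservation(extract_window(family, species, variant, column, flank))
        numeric = score.window_score if score.window_score is not None else -1.0
        central = 1 if score.central_conserved else 0
        unglen = sum(1 for ch in family.members[(species, variant)] if ch != GAP)
        return (-status_rank[score.status], -numeric, -central, -unglen, variant)

    return min(variants, key=sort_key)
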