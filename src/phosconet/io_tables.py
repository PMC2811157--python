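"""Readers and writers for every external format: phosphosite tables,
aligned ortholog FASTA, per-species conservation tables, edge lists,
annotation tables and external kinase predictions.

All tables are UTF-8 tab-delimited with a header row.  Readers validate and
reject malformed input (naming the offending row and field) rather than
coercing it; every writer/reader pair is an exact inverse on valid data.
Conservation values are written with 3 decimals on the 0–1 scale, with
``NA`` (species unavailable) and ``Incomplete`` (residue unretrievable) as
literal tokens.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, ParseError, SeedError, SerializationError
from .records import (
    DEFAULT_SPECIES,
    ConservationSummary,
    OrthologFamily,
    PhosphoSiteRecord,
    SpeciesScore,
    normalize_sequence,
)
from .motifs import SiteAnnotation

SITE_COLUMNS = [
    "protein_id", "position", "residue", "known_kinases", "observation_count", "source",
]


def _read_rows(path, required: Sequence[str]) -> tuple[list[str], list[dict]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {missing}")
        return header, list(reader)


def read_site_table(path) -> list[PhosphoSiteRecord]:
    """Parse a phosphosite TSV into validated records, preserving row order."""
    _header, rows = _read_rows(path, SITE_COLUMNS)
    records = []
    for i, row in enumerate(rows, start=2):  # 1-based file line of the row
        try:
            position = int(row["position"])
            count = int(row["observation_count"])
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: non-integer position/count ({exc})") from None
        kinases = tuple(k for k in row["known_kinases"].split(";") if k)
        try:
            records.append(
                PhosphoSiteRecord(
                    protein_id=row["protein_id"],
                    position=position,
                    residue=row["residue"],
                    known_kinases=kinases,
                    observation_count=count,
                    source=row["source"],
                )
            )
        except ParseError as exc:
            raise ParseError(f"{path}, line {i}: {exc}") from None
    return records


def write_site_table(records: Iterable[PhosphoSiteRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.protein_id, r.position, r.residue, ";".join(r.known_kinases),
                 r.observation_count, r.source]
            )


SEED_TOKEN = "seed"


def read_family(path, species_list: Sequence[str] = DEFAULT_SPECIES) -> OrthologFamily:
    """Read one aligned multi-FASTA family.

    Headers are ``proteinID|species|variantN`` with a trailing ``|seed``
    token on exactly one record (the human seed).  All sequences must share
    one alignment length; species tags outside ``species_list`` are rejected.
    """
    members: dict[tuple[str, str], str] = {}
    seed_keys = []
    protein_ids = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 3:
            raise ParseError(f"{path}: header {rec.id!r} is not proteinID|species|variant")
        protein_id, species, variant = fields[0], fields[1], fields[2]
        protein_ids.add(protein_id)
        key = (species, variant)
        if key in members:
            raise ParseError(f"{path}: duplicate member {species}|{variant}")
        members[key] = normalize_sequence(str(rec.seq))
        if SEED_TOKEN in fields[3:]:
            seed_keys.append(key)
    if not members:
        raise ParseError(f"{path}: no FASTA records")
    if len(protein_ids) != 1:
        raise ParseError(f"{path}: mixed protein ids {sorted(protein_ids)}")
    if len(seed_keys) != 1:
        raise SeedError(f"{path}: expected exactly one seed record, found {len(seed_keys)}")
    lengths = {len(s) for s in members.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return OrthologFamily(
        protein_id=protein_ids.pop(),
        members=members,
        seed_key=seed_keys[0],
        species=tuple(species_list),
    )


def write_family(family: OrthologFamily, path) -> None:
    """Write a family as aligned multi-FASTA (seed first, then sorted)."""
    keys = sorted(family.members, key=lambda k: (k != family.seed_key, k))
    records = []
    for species, variant in keys:
        header = f"{family.protein_id}|{species}|{variant}"
        if (species, variant) == family.seed_key:
            header += f"|{SEED_TOKEN}"
        records.append(
            SeqRecord(Seq(family.members[(species, variant)]), id=header, description="")
        )
    SeqIO.write(records, str(path), "fasta")


def _format_score(score: SpeciesScore) -> str:
    if score.status == "numeric":
        if not 0.0 <= score.window_score <= 1.0:
            raise SerializationError(f"score {score.window_score} outside [0, 1]")
        return f"{score.window_score:.3f}"
    return score.status


def _format_value(value: float | None) -> str:
    if value is None:
        return "NA"
    if not 0.0 <= value <= 1.0:
        raise SerializationError(f"value {value} outside [0, 1]")
    return f"{value:.3f}"


def write_conservation_table(
    summaries: Iterable[ConservationSummary],
    path,
    species_list: Sequence[str] = DEFAULT_SPECIES,
) -> None:
    """Write the per-site conservation table: site identity, one column per
    species (value / NA / Incomplete), mean window conservation (column M)
    and central-residue conservation rate (column N)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "residue", *species_list, "M", "N"])
        for s in summaries:
            cells = []
            for sp in species_list:
                score = s.species_scores.get(sp, SpeciesScore(sp, "NA"))
                cells.append(_format_score(score))
            writer.writerow(
                [s.protein_id, s.position, s.residue, *cells,
                 _format_value(s.mean_window_conservation),
                 _format_value(s.central_conservation_rate)]
            )


def read_conservation_table(path) -> list[ConservationSummary]:
    """Read a conservation table back into summaries.

    Per-species entries are reconstructed as numeric/NA/Incomplete scores;
    flags not represented in the table (central conservation, comparable
    flank counts) come back as None/0.
    """
    header, rows = _read_rows(path, ["protein_id", "position", "residue", "M", "N"])
    species = [c for c in header if c not in ("protein_id", "position", "residue", "M", "N")]
    out = []
    for i, row in enumerate(rows, start=2):
        scores = {}
        for sp in species:
            cell = row[sp]
            if cell in ("NA", "Incomplete"):
                scores[sp] = SpeciesScore(sp, cell)
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise ParseError(f"{path}, line {i}: bad score {cell!r} for {sp}") from None
                if not 0.0 <= value <= 1.0:
                    raise ParseError(f"{path}, line {i}: score {value} outside [0, 1]")
                scores[sp] = SpeciesScore(sp, "numeric", value, value > 0 or None)
        def parse_agg(cell: str) -> float | None:
            if cell == "NA":
                return None
            value = float(cell)
            if not 0.0 <= value <= 1.0:
                raise ParseError(f"{path}, line {i}: aggregate {value} outside [0, 1]")
            return value
        out.append(
            ConservationSummary(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                residue=row["residue"],
                species_scores=scores,
                mean_window_conservation=parse_agg(row["M"]),
                central_conservation_rate=parse_agg(row["N"]),
            )
        )
    return out


def read_edge_list(path) -> list[tuple[str, str, str]]:
    """Edge-list TSV: proteinA, proteinB, optional label."""
    header, rows = _read_rows(path, ["proteinA", "proteinB"])
    edges = []
    for i, row in enumerate(rows, start=2):
        a, b = row["proteinA"], row["proteinB"]
        if not a or not b:
            raise ParseError(f"{path}, line {i}: empty edge endpoint")
        edges.append((a, b, row.get("label") or ""))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["proteinA", "proteinB", "label"])
        for a, b, label in edges:
            writer.writerow([a, b, label])


def read_predictions(path) -> dict[tuple[str, int], list[str]]:
    """External kinase predictions (e.g. NetworKIN-style output): TSV with
    protein_id, position, kinase, score — consumed purely as annotations."""
    _header, rows = _read_rows(path, ["protein_id", "position", "kinase"])
    out: dict[tuple[str, int], list[str]] = {}
    for i, row in enumerate(rows, start=2):
        try:
            key = (row["protein_id"], int(row["position"]))
        except ValueError:
            raise ParseError(f"{path}, line {i}: non-integer position") from None
        out.setdefault(key, []).append(row["kinase"])
    return out


ANNOTATION_COLUMNS = [
    "protein_id", "position", "residue", "matched_motifs", "assigned_kinases",
    "pbd_site", "motif_conservation",
]


def write_annotations(annotations: Iterable[SiteAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            cons = ";".join(
                f"{name}={'NA' if frac is None else format(frac, '.6f')}"
                for name, frac in a.motif_conservation.items()
            )
            writer.writerow(
                [a.protein_id, a.position, a.residue,
                 ";".join(a.matched_motifs),
                 ";".join(f"{k}:{prov}" for k, prov in a.assigned_kinases),
                 int(a.pbd_site), cons]
            )


def read_annotations(path) -> list[SiteAnnotation]:
    _header, rows = _read_rows(path, ANNOTATION_COLUMNS)
    out = []
    for i, row in enumerate(rows, start=2):
        try:
            kinases = tuple(
                tuple(item.rsplit(":", 1))
                for item in row["assigned_kinases"].split(";")
                if item
            )
            cons = {}
            for item in row["motif_conservation"].split(";"):
                if not item:
                    continue
                name, _, value = item.rpartition("=")
                cons[name] = None if value == "NA" else float(value)
            out.append(
                SiteAnnotation(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    residue=row["residue"],
                    matched_motifs=tuple(m for m in row["matched_motifs"].split(";") if m),
                    assigned_kinases=kinases,
                    pbd_site=bool(int(row["pbd_site"])),
                    motif_conservation=cons,
                )
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}, line {i}: malformed annotation row ({exc})") from None
    return out


def write_truth_table(truths: Mapping[str, "TruthTable"], path) -> None:
    """Ground-truth TSV for simulated cohorts (one row per planted site)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["site_id", "protein_id", "position", "class",
                         "planted_motif", "window_substitutions"])
        for truth in truths.values():
            for e in truth.entries:
                subs = ";".join(f"{sp}={n}" for sp, n in e.window_substitutions.items())
                writer.writerow(
                    [e.site_id, e.protein_id, e.position, e.site_class,
                     e.planted_motif or "", subs]
                )
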