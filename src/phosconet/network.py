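"""Assembly, export and rendering of the annotated phosphorylation network:
protein nodes carrying per-site conservation columns and kinase/PBD display
classes, connected by curated signaling edges.

Edges are an *input* (established signaling interactions); nothing is
inferred.  Per-site display follows the two-bar convention: the central bar
height is the central-residue conservation rate, the flanking bar height the
mean window conservation, and bar colors encode the assigned kinase class.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import asdict, dataclass, field

import networkx as nx

from .errors import ConfigError, InputError
from .motifs import SiteAnnotation
from .records import ConservationSummary, SpeciesScore

logger = logging.getLogger(__name__)

#: Display classes and colors (kinase class -> hex color).
KINASE_CLASS_PALETTE = {
    "CDK": "#f5c710",        # Cdk1/2: yellow
    "ATM/ATR": "#d62728",    # red
    "CHK1/2": "#ff7f0e",     # orange
    "PLK1": "#1f77b4",       # blue
    "other-known": "#555555",
    "unknown": "#bbbbbb",
    "PBD": "#2ca02c",        # Polo-box docking sites: green
}

_CLASS_BY_KINASE = {
    "ATM": "ATM/ATR", "ATR": "ATM/ATR", "ATM/ATR": "ATM/ATR",
    "CDK1": "CDK", "CDK2": "CDK", "CDK1/2": "CDK", "CDC2": "CDK",
    "CHK1": "CHK1/2", "CHK2": "CHK1/2", "CHK1/2": "CHK1/2",
    "PLK1": "PLK1",
}


def kinase_display_class(annotation: SiteAnnotation) -> str:
    """Display class of a site: the class of its first assigned kinase,
    ``other-known`` for a known kinase outside the four highlighted classes,
    ``unknown`` when no kinase is assigned."""
    for kinase, _prov in annotation.assigned_kinases:
        cls = _CLASS_BY_KINASE.get(kinase.upper())
        if cls:
            return cls
    if any(prov == "known" for _k, prov in annotation.assigned_kinases):
        return "other-known"
    return "unknown"


@dataclass(frozen=True)
class SiteEntry:
    """One displayed site column on a protein node."""

    position: int
    residue: str
    summary: ConservationSummary
    annotation: SiteAnnotation

    @property
    def central_height(self) -> float:
        return self.summary.central_conservation_rate or 0.0

    @property
    def flank_height(self) -> float:
        return self.summary.mean_window_conservation or 0.0


@dataclass(frozen=True)
class SiteNetwork:
    """Protein nodes with ordered site entries, undirected labeled edges,
    optional module grouping, and the kinase-class palette."""

    nodes: Mapping[str, tuple[SiteEntry, ...]]
    edges: tuple[tuple[str, str, str], ...] = ()
    groups: Mapping[str, str] = field(default_factory=dict)
    palette: Mapping[str, str] = field(default_factory=lambda: dict(KINASE_CLASS_PALETTE))

    def node_count(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return len(self.edges)


def build_network(
    summaries: Iterable[ConservationSummary],
    annotations: Iterable[SiteAnnotation],
    edge_list: Iterable[tuple[str, str, str]] = (),
    groups: Mapping[str, str] | None = None,
) -> SiteNetwork:
    """Assemble the network: one node per protein in the summaries, sites in
    position order, edges copied after endpoint validation (edges touching
    unknown proteins are dropped with a logged warning)."""
    ann_by_key = {a.key: a for a in annotations}
    by_protein: dict[str, list[SiteEntry]] = {}
    for s in summaries:
        if s.key not in ann_by_key:
            raise InputError(f"site {s.protein_id}:{s.position} has no annotation")
        by_protein.setdefault(s.protein_id, []).append(
            SiteEntry(s.position, s.residue, s, ann_by_key[s.key])
        )
    nodes = {
        protein: tuple(sorted(entries, key=lambda e: e.position))
        for protein, entries in by_protein.items()
    }
    kept_edges = []
    for a, b, label in edge_list:
        if a not in nodes or b not in nodes:
            logger.warning("dropping edge %s-%s: endpoint not in network", a, b)
            continue
        kept_edges.append((a, b, label))
    groups = {p: g for p, g in (groups or {}).items() if p in nodes}
    return SiteNetwork(nodes=nodes, edges=tuple(kept_edges), groups=groups)


# ---------------------------------------------------------------------------
# JSON (lossless) serialization


def _summary_to_dict(s: ConservationSummary) -> dict:
    return {
        "protein_id": s.protein_id,
        "position": s.position,
        "residue": s.residue,
        "species_scores": {sp: asdict(score) for sp, score in s.species_scores.items()},
        "mean_window_conservation": s.mean_window_conservation,
        "central_conservation_rate": s.central_conservation_rate,
    }


def _summary_from_dict(d: dict) -> ConservationSummary:
    return ConservationSummary(
        protein_id=d["protein_id"],
        position=d["position"],
        residue=d["residue"],
        species_scores={sp: SpeciesScore(**sc) for sp, sc in d["species_scores"].items()},
        mean_window_conservation=d["mean_window_conservation"],
        central_conservation_rate=d["central_conservation_rate"],
    )


def _annotation_to_dict(a: SiteAnnotation) -> dict:
    return {
        "protein_id": a.protein_id,
        "position": a.position,
        "residue": a.residue,
        "matched_motifs": list(a.matched_motifs),
        "assigned_kinases": [list(pair) for pair in a.assigned_kinases],
        "pbd_site": a.pbd_site,
        "motif_conservation": dict(a.motif_conservation),
    }


def _annotation_from_dict(d: dict) -> SiteAnnotation:
    return SiteAnnotation(
        protein_id=d["protein_id"],
        position=d["position"],
        residue=d["residue"],
        matched_motifs=tuple(d["matched_motifs"]),
        assigned_kinases=tuple((k, p) for k, p in d["assigned_kinases"]),
        pbd_site=d["pbd_site"],
        motif_conservation=dict(d["motif_conservation"]),
    )


def network_to_dict(network: SiteNetwork) -> dict:
    return {
        "nodes": {
            protein: [
                {
                    "position": e.position,
                    "residue": e.residue,
                    "summary": _summary_to_dict(e.summary),
                    "annotation": _annotation_to_dict(e.annotation),
                }
                for e in entries
            ]
            for protein, entries in network.nodes.items()
        },
        "edges": [list(edge) for edge in network.edges],
        "groups": dict(network.groups),
        "palette": dict(network.palette),
    }


def network_from_dict(doc: dict) -> SiteNetwork:
    nodes = {
        protein: tuple(
            SiteEntry(
                position=e["position"],
                residue=e["residue"],
                summary=_summary_from_dict(e["summary"]),
                annotation=_annotation_from_dict(e["annotation"]),
            )
            for e in entries
        )
        for protein, entries in doc["nodes"].items()
    }
    return SiteNetwork(
        nodes=nodes,
        edges=tuple((a, b, label) for a, b, label in doc["edges"]),
        groups=dict(doc["groups"]),
        palette=dict(doc["palette"]),
    )


def export_network(network: SiteNetwork, path, format: str = "JSON") -> None:
    """Serialize the network; JSON is lossless (export∘import is identity),
    GraphML flattens per-site records into JSON-encoded node attributes."""
    fmt = format.upper()
    if fmt == "JSON":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(network_to_dict(network), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "GRAPHML":
        g = to_networkx(network)
        nx.write_graphml(g, str(path))
    else:
        raise ConfigError(f"unknown export format {format!r}; use GraphML or JSON")


def import_network(path) -> SiteNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return network_from_dict(json.load(fh))


def to_networkx(network: SiteNetwork) -> nx.Graph:
    """The network as a networkx Graph; each node carries its site columns
    (positions, bar heights, display classes, PBD flags) as attributes,
    complex per-site detail as a JSON-encoded string (GraphML-safe)."""
    g = nx.Graph()
    for protein, entries in network.nodes.items():
        g.add_node(
            protein,
            n_sites=len(entries),
            group=network.groups.get(protein, ""),
            positions=",".join(str(e.position) for e in entries),
            central_heights=",".join(f"{e.central_height:.6f}" for e in entries),
            flank_heights=",".join(f"{e.flank_height:.6f}" for e in entries),
            site_classes=",".join(kinase_display_class(e.annotation) for e in entries),
            pbd_sites=",".join(str(int(e.annotation.pbd_site)) for e in entries),
            sites_json=json.dumps(
                [
                    {
                        "position": e.position,
                        "residue": e.residue,
                        "summary": _summary_to_dict(e.summary),
                        "annotation": _annotation_to_dict(e.annotation),
                    }
                    for e in entries
                ],
                sort_keys=True,
            ),
        )
    for a, b, label in network.edges:
        g.add_edge(a, b, label=label)
    return g


def render_summary_plot(network: SiteNetwork, path) -> None:
    """Static per-protein bar-column figure.

    One panel per protein; each site is a two-bar column (central-residue
    conservation next to mean window conservation), colored by kinase class,
    with PBD docking sites marked by a green dot above the column.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "phosconet"
    proteins = sorted(network.nodes)
    n = max(1, len(proteins))
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.2 * nrows), squeeze=False
    )
    for ax in axes.flat:
        ax.set_axis_off()
    for idx, protein in enumerate(proteins):
        ax = axes[idx // ncols][idx % ncols]
        ax.set_axis_on()
        entries = network.nodes[protein]
        for i, e in enumerate(entries):
            cls = kinase_display_class(e.annotation)
            color = network.palette.get(cls, "#bbbbbb")
            ax.bar(i - 0.18, e.central_height, width=0.34, color=color)
            ax.bar(i + 0.18, e.flank_height, width=0.34, color="#999999")
            if e.annotation.pbd_site:
                ax.plot(i, 1.08, marker="o", color=network.palette.get("PBD", "#2ca02c"),
                        markersize=4, clip_on=False)
        ax.set_ylim(0, 1.05)
        ax.set_xticks(range(len(entries)))
        ax.set_xticklabels(
            [f"{e.residue}{e.position}" for e in entries], rotation=90, fontsize=6
        )
        ax.set_title(protein, fontsize=8)
        ax.tick_params(axis="y", labelsize=6)
    fig.tight_layout()
    fig.savefig(str(path), metadata=_stable_metadata(str(path)))
    plt.close(fig)


def _stable_metadata(path: str) -> dict | None:
    # strip the embedded creation date so identical inputs give identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "phosconet"}
    return None
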