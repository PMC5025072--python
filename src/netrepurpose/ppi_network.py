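"""Disease-specific protein–protein interaction network construction.

Reads STRING-style weighted interaction exports, filters them to
high-confidence edges supported by the requested evidence channels, and
builds the disease network seeded on a list of disease proteins (DPs):
the node set is the DP list plus their direct interactors, the edge set
is every qualifying interaction between included nodes, and edge weights
carry the interaction confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Evidence channels an edge must support (any one of them positive).
DEFAULT_REQUIRED_CHANNELS = frozenset({"experimental", "database"})

#: Confidence cutoff below which interactions are discarded (strict).
DEFAULT_MIN_CONFIDENCE = 0.7

_PROTEIN_A_ALIASES = ("protein1", "protein_a", "proteina", "node1", "item_id_a")
_PROTEIN_B_ALIASES = ("protein2", "protein_b", "proteinb", "node2", "item_id_b")
_SCORE_ALIASES = ("combined_score", "score", "combined")


class FormatError(ValueError):
    """Raised when an input table lacks required columns or structure."""


@dataclass(frozen=True)
class InteractionRecord:
    """One protein–protein interaction with per-channel evidence scores.

    All scores live in [0, 1] after normalization; ``channel_scores``
    maps evidence-channel names (e.g. ``experimental``, ``database``)
    to their individual confidences.
    """

    protein_a: str
    protein_b: str
    combined_score: float
    channel_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction {self.protein_a!r} is not a record")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(
                f"combined score {self.combined_score} outside [0, 1] "
                f"for ({self.protein_a}, {self.protein_b})"
            )


@dataclass
class DiseaseNetwork:
    """Weighted undirected PPI graph with disease-protein flags.

    ``graph`` is a :class:`networkx.Graph` whose edges carry a
    ``weight`` attribute in (0, 1]; ``dp_set`` is the subset of nodes
    that are disease proteins.  Isolated DPs (no qualifying edge) are
    retained as nodes so downstream scoring still covers them.
    """

    graph: nx.Graph
    dp_set: frozenset[str]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["weight"])


def _resolve_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(f"missing required column for {what}; tried {list(aliases)}")


def load_interactions(
    path: str | Path,
    score_scale: str = "unit",
) -> list[InteractionRecord]:
    """Read a STRING-export style TSV into interaction records.

    Parameters
    ----------
    path
        Tab-separated file with a header row.  Protein columns may be
        named ``protein1``/``protein2`` (STRING) or ``protein_a``/
        ``protein_b``; the combined confidence column ``combined_score``
        is required.  Any other numeric column is treated as an
        evidence-channel score.
    score_scale
        ``"unit"`` if scores are already in [0, 1], ``"string999"`` if
        they use STRING's integer 0–999 convention (divided by 1000).

    Self-loops are dropped and malformed rows are skipped; both are
    logged with their line numbers.
    """
    if score_scale not in ("unit", "string999"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    divisor = 1000.0 if score_scale == "string999" else 1.0

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty file, no header")
    col_a = _resolve_column(df.columns, _PROTEIN_A_ALIASES, "protein A")
    col_b = _resolve_column(df.columns, _PROTEIN_B_ALIASES, "protein B")
    col_score = _resolve_column(df.columns, _SCORE_ALIASES, "combined score")
    channel_cols = [c for c in df.columns if c not in (col_a, col_b, col_score)]

    records: list[InteractionRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        a, b = row[col_a], row[col_b]
        try:
            score = float(row[col_score]) / divisor
        except (TypeError, ValueError):
            logger.warning("line %d: malformed combined score %r, skipped",
                           line_no, row[col_score])
            continue
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"line {line_no}: combined score {score} outside [0, 1] "
                f"after {score_scale} normalization"
            )
        if pd.isna(a) or pd.isna(b):
            logger.warning("line %d: missing protein identifier, skipped", line_no)
            continue
        if a == b:
            logger.warning("line %d: self-loop on %r dropped", line_no, a)
            continue
        channels: dict[str, float] = {}
        for c in channel_cols:
            raw = row[c]
            if pd.isna(raw):
                continue
            try:
                channels[c] = float(raw) / divisor
            except (TypeError, ValueError):
                continue  # non-numeric annotation column
        records.append(InteractionRecord(str(a), str(b), score, channels))
    return records


def load_dp_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line disease-protein list."""
    dps = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            dps.append(line)
    return dps


def _edge_qualifies(
    rec: InteractionRecord,
    min_confidence: float,
    required_channels: frozenset[str],
) -> bool:
    if rec.combined_score <= min_confidence:  # strict: 0.70 itself is excluded
        return False
    if not required_channels:
        return True
    return any(rec.channel_scores.get(ch, 0.0) > 0.0 for ch in required_channels)


def build_disease_network(
    records: Iterable[InteractionRecord],
    dp_list: Sequence[str],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    required_channels: Iterable[str] = DEFAULT_REQUIRED_CHANNELS,
    confidence_mode: str = "fixed",
) -> DiseaseNetwork:
    """Build the DP-seeded, confidence-filtered disease network.

    The node set is the DP list plus every direct interactor of a DP
    connected by a qualifying edge (one-hop expansion); an edge is then
    retained iff its combined score strictly exceeds ``min_confidence``,
    at least one required evidence channel is positive, and both
    endpoints belong to the node set.  Edge weight equals the combined
    confidence score.

    ``confidence_mode="percentile"`` reinterprets ``min_confidence`` as
    a quantile of the input score distribution (e.g. 0.7 → the 70th
    percentile) instead of a fixed cutoff.
    """
    if not dp_list:
        raise ValueError("dp_list must be non-empty")
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    records = list(records)
    required = frozenset(required_channels)
    dp_set = frozenset(dp_list)

    if confidence_mode == "percentile":
        scores = sorted(r.combined_score for r in records)
        if scores:
            cut_idx = int(min_confidence * len(scores))
            min_confidence = scores[min(cut_idx, len(scores) - 1)]
            logger.info("percentile mode: realized confidence cutoff %.4f",
                        min_confidence)
    elif confidence_mode != "fixed":
        raise ValueError(f"unknown confidence_mode {confidence_mode!r}")

    qualifying = [r for r in records if _edge_qualifies(r, min_confidence, required)]

    # one-hop expansion: DPs plus their qualifying direct interactors
    node_set: set[str] = set(dp_set)
    for rec in qualifying:
        if rec.protein_a in dp_set:
            node_set.add(rec.protein_b)
        if rec.protein_b in dp_set:
            node_set.add(rec.protein_a)

    graph = nx.Graph()
    graph.add_nodes_from(sorted(node_set))
    for rec in qualifying:
        if rec.protein_a in node_set and rec.protein_b in node_set:
            # duplicate/opposite-orientation rows collapse onto one edge;
            # keep the highest confidence seen
            u, v = rec.protein_a, rec.protein_b
            if graph.has_edge(u, v):
                graph.edges[u, v]["weight"] = max(
                    graph.edges[u, v]["weight"], rec.combined_score
                )
            else:
                graph.add_edge(u, v, weight=rec.combined_score)

    isolated_dps = [n for n in sorted(dp_set) if graph.degree(n) == 0]
    if isolated_dps:
        logger.info("%d DPs retained with no qualifying edge: %s",
                    len(isolated_dps), ", ".join(isolated_dps[:10]))
    if graph.number_of_edges() == 0:
        logger.warning("no edges survived filtering; returning edgeless network")
    return DiseaseNetwork(graph=graph, dp_set=dp_set)


def write_network(net: DiseaseNetwork, edge_path: str | Path,
                  node_path: str | Path) -> None:
    """Serialize a disease network as edge-list and node-attribute TSVs."""
    edges = sorted((min(u, v), max(u, v), d["weight"])
                   for u, v, d in net.graph.edges(data=True))
    pd.DataFrame(edges, columns=["node_a", "node_b", "weight"]).to_csv(
        edge_path, sep="\t", index=False)
    nodes = sorted(net.graph.nodes)
    pd.DataFrame(
        {"node": nodes, "is_dp": [int(n in net.dp_set) for n in nodes]}
    ).to_csv(node_path, sep="\t", index=False)


def read_network(edge_path: str | Path, node_path: str | Path) -> DiseaseNetwork:
    """Inverse of :func:`write_network`; round-trips exactly."""
    nodes_df = pd.read_csv(node_path, sep="\t", dtype={"node": str})
    edges_df = pd.read_csv(edge_path, sep="\t",
                           dtype={"node_a": str, "node_b": str})
    graph = nx.Graph()
    graph.add_nodes_from(nodes_df["node"])
    for _, row in edges_df.iterrows():
        graph.add_edge(row["node_a"], row["node_b"], weight=float(row["weight"]))
    dp_set = frozenset(nodes_df.loc[nodes_df["is_dp"] == 1, "node"])
    return DiseaseNetwork(graph=graph, dp_set=dp_set)
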