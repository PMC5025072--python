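"""Target-protein selection by hub exclusion, bridging centrality and druggability.

A candidate target protein (TP) must satisfy three constraints on the
disease network: (i) it is not a hub (hubs are excluded for toxicity /
essentiality reasons), (ii) it is a bridging node — high bridging
centrality BR(i) = BC(i)·B(i), where B is the random-walk (current-flow)
betweenness and BC the bridging coefficient
BC(i) = D(i) / Σ_{v∈N(i)} 1/D(v) — and (iii) it is druggable, i.e. it
has at least one sufficiently confident drug association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .ppi_network import DiseaseNetwork, FormatError

logger = logging.getLogger(__name__)

DEFAULT_HUB_FRACTION = 0.20
DEFAULT_BRIDGING_QUANTILE = 0.25
DEFAULT_DRUG_CONFIDENCE = 0.9
#: Sources whose associations are curated and exempt from the confidence cutoff.
DEFAULT_CURATED_SOURCES = frozenset({"drugbank", "ctd"})


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node centralities entering the bridging-centrality ranking."""

    node: str
    degree: int
    rwbc: float            # B(i), random-walk betweenness
    bridging_coeff: float  # BC(i); nan for isolated nodes
    bridging_centrality: float  # BR(i) = BC(i)·B(i)


@dataclass
class TargetSelection:
    """Outcome of the three-constraint target selection.

    ``tps`` is (bridging ∩ druggable) \\ hubs; ``provenance`` records the
    realized fractions, cutoffs and counts for reproducibility.
    """

    hubs: set[str]
    bridging_nodes: set[str]
    druggable_nodes: set[str]
    tps: set[str]
    profiles: dict[str, CentralityProfile] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def compute_degree(net: DiseaseNetwork) -> dict[str, int]:
    """Unweighted degree D(i) — the neighbor count — for every node."""
    return {n: int(d) for n, d in net.graph.degree()}


def detect_hubs(degrees: Mapping[str, int],
                fraction: float = DEFAULT_HUB_FRACTION) -> set[str]:
    """The top ``fraction`` highest-degree nodes, k = floor(fraction·N).

    Ties at the cut are broken lexicographically by node ID so the
    selection is deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(degrees)
    if n == 0:
        return set()
    k = math.floor(fraction * n)
    ranked = sorted(degrees, key=lambda v: (-degrees[v], v))
    hubs = set(ranked[:k])
    cutoff = degrees[ranked[k - 1]] if k else None
    logger.info("hub detection: N=%d, k=%d, realized degree cutoff=%s",
                n, k, cutoff)
    return hubs


def compute_rwbc(net: DiseaseNetwork, weight: str | None = "weight") -> dict[str, float]:
    """Random-walk (current-flow) betweenness B(i), per connected component.

    Uses Newman's current-flow betweenness with edge weights as
    conductances, normalized by (N−1)(N−2)/2 within each component of
    size N.  Components of fewer than three nodes (including isolated
    nodes) carry no through-flow and get 0.
    """
    result: dict[str, float] = {n: 0.0 for n in net.graph.nodes}
    for comp in nx.connected_components(net.graph):
        if len(comp) < 3:
            continue
        sub = net.graph.subgraph(comp)
        result.update(nx.current_flow_betweenness_centrality(
            sub, normalized=True, weight=weight))
    return {n: float(v) for n, v in result.items()}


def bridging_coefficient(net: DiseaseNetwork) -> dict[str, float]:
    """BC(i) = D(i) / Σ_{v∈N(i)} 1/D(v); undefined (nan) for isolated nodes."""
    degrees = compute_degree(net)
    bc: dict[str, float] = {}
    isolated = []
    for node in net.graph.nodes:
        d = degrees[node]
        if d == 0:
            bc[node] = float("nan")
            isolated.append(node)
            continue
        inv_sum = sum(1.0 / degrees[v] for v in net.graph.neighbors(node))
        bc[node] = d / inv_sum
    if isolated:
        logger.warning("bridging coefficient undefined for %d isolated node(s)",
                       len(isolated))
    return bc


def bridging_centrality(rwbc: Mapping[str, float],
                        bc: Mapping[str, float]) -> dict[str, float]:
    """BR(i) = BC(i)·B(i), elementwise over a shared node domain.

    Isolated nodes (nan BC) get BR = nan and are excluded from ranking.
    """
    if set(rwbc) != set(bc):
        raise ValueError("rwbc and bridging-coefficient maps cover different nodes")
    return {n: bc[n] * rwbc[n] for n in rwbc}


def select_bridging(br: Mapping[str, float],
                    quantile: float = DEFAULT_BRIDGING_QUANTILE) -> set[str]:
    """The top-quantile bridging-centrality nodes, k = ceil(quantile·N).

    N counts only nodes with a defined BR; lexicographic tie-break.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    defined = {n: v for n, v in br.items() if not math.isnan(v)}
    n = len(defined)
    if n == 0:
        return set()
    k = math.ceil(quantile * n)
    ranked = sorted(defined, key=lambda v: (-defined[v], v))
    threshold = defined[ranked[k - 1]]
    logger.info("bridging selection: N=%d, k=%d, realized BR threshold=%.6g",
                n, k, threshold)
    return set(ranked[:k])


def load_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a drug–target TSV (drug_id, target_id, optional confidence/source/action)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot read drug table {path}: {exc}") from exc
    required = {"drug_id", "target_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"drug table missing columns {required - set(df.columns)}")
    if "confidence" in df.columns:
        df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    else:
        df["confidence"] = float("nan")
    if "source" not in df.columns:
        df["source"] = ""
    return df


def filter_druggable(
    nodes: Iterable[str],
    drug_table: pd.DataFrame | str | Path,
    min_confidence: float = DEFAULT_DRUG_CONFIDENCE,
    curated_sources: Iterable[str] = DEFAULT_CURATED_SOURCES,
) -> set[str]:
    """Keep nodes with ≥1 drug association above ``min_confidence`` (strict)
    or from a curated, confidence-exempt source."""
    if not isinstance(drug_table, pd.DataFrame):
        drug_table = load_drug_table(drug_table)
    curated = {s.lower() for s in curated_sources}
    confident = drug_table["confidence"] > min_confidence
    is_curated = drug_table["source"].fillna("").str.lower().isin(curated)
    druggable_targets = set(drug_table.loc[confident | is_curated, "target_id"])
    return set(nodes) & druggable_targets


def centrality_profiles(net: DiseaseNetwork) -> dict[str, CentralityProfile]:
    """Compute D, B, BC and BR for every node of the network."""
    degrees = compute_degree(net)
    rwbc = compute_rwbc(net)
    bc = bridging_coefficient(net)
    br = bridging_centrality(rwbc, bc)
    return {
        n: CentralityProfile(node=n, degree=degrees[n], rwbc=rwbc[n],
                             bridging_coeff=bc[n], bridging_centrality=br[n])
        for n in net.graph.nodes
    }


def select_targets(
    net: DiseaseNetwork,
    drug_table: pd.DataFrame | str | Path,
    hub_fraction: float = DEFAULT_HUB_FRACTION,
    bridging_quantile: float = DEFAULT_BRIDGING_QUANTILE,
    min_drug_confidence: float = DEFAULT_DRUG_CONFIDENCE,
    curated_sources: Iterable[str] = DEFAULT_CURATED_SOURCES,
) -> TargetSelection:
    """Apply the three target constraints on one network.

    Returns the hub, bridging and druggable sets together with
    ``tps = (bridging ∩ druggable) \\ hubs`` and full provenance.
    """
    profiles = centrality_profiles(net)
    degrees = {n: p.degree for n, p in profiles.items()}
    br = {n: p.bridging_centrality for n, p in profiles.items()}

    hubs = detect_hubs(degrees, hub_fraction)
    bridging = select_bridging(br, bridging_quantile)
    druggable = filter_druggable(net.graph.nodes, drug_table,
                                 min_drug_confidence, curated_sources)
    tps = (bridging & druggable) - hubs
    if not tps:
        logger.warning("target selection produced an empty TP set")
    return TargetSelection(
        hubs=hubs,
        bridging_nodes=bridging,
        druggable_nodes=druggable,
        tps=tps,
        profiles=profiles,
        provenance={
            "n_nodes": net.n_nodes,
            "hub_fraction": hub_fraction,
            "n_hubs": len(hubs),
            "bridging_quantile": bridging_quantile,
            "n_bridging": len(bridging),
            "n_druggable": len(druggable),
            "min_drug_confidence": min_drug_confidence,
            "n_tps": len(tps),
        },
    )
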