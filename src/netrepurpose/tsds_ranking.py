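"""Topological Score of Drug Synergy (TSDS) for target triplets.

Every unordered triplet of candidate target proteins (TPs) is scored by
how strongly its members reach the disease proteins (DPs) along
high-confidence shortest paths.  With edge length −ln(weight), the
minimum-length path maximizes the product of edge confidences, and the
path strength exp(−length) lies in [0, 1].  The triplet score is the
mean over DPs of the best TP→DP path strength, so a high-TSDS triplet
covers all DPs through reliable interactions.  Significance is assessed
against an empirical null of uniformly sampled TP triplets with an
add-one permutation-style p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ppi_network import DiseaseNetwork

DEFAULT_ALPHA = 0.01
DEFAULT_NULL_SAMPLES = 10_000

Triplet = tuple[str, str, str]
#: Signature of an injectable triplet scorer: (net, triplet, dp_set) -> score.
TripletScorer = Callable[[DiseaseNetwork, Sequence[str], frozenset[str]], float]


@dataclass(frozen=True)
class TripletResult:
    """A TP triplet with its TSDS score and empirical significance."""

    triplet: Triplet
    tsds: float
    p_value: float
    significant: bool


@dataclass
class NullDistribution:
    """Empirical TSDS null from uniformly sampled TP triplets."""

    samples: np.ndarray
    n_samples: int
    seed: int


def enumerate_triplets(tps: Iterable[str]) -> list[Triplet]:
    """All C(|tps|, 3) unordered triplets in deterministic (sorted) order."""
    tps = sorted(set(tps))
    if len(tps) < 3:
        raise ValueError(f"need at least 3 TPs, got {len(tps)}")
    return list(itertools.combinations(tps, 3))


def _length_graph(net: DiseaseNetwork) -> nx.Graph:
    """Copy of the network with edge attribute length = −ln(weight)."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        w = float(d["weight"])
        if not 0.0 < w <= 1.0:
            raise ValueError(f"edge weight {w} outside (0, 1] on ({u}, {v})")
        g.add_edge(u, v, length=-math.log(w))
    return g


def path_strength(net: DiseaseNetwork, source: str, sink: str) -> float:
    """Best product of edge confidences over paths from source to sink.

    Equals exp(−L) for the weighted shortest path length L under edge
    length −ln(weight); 1 for a node to itself, 0 for disconnected pairs.
    """
    for node in (source, sink):
        if node not in net.graph:
            raise ValueError(f"unknown node {node!r}")
    if source == sink:
        return 1.0
    g = _length_graph(net)
    try:
        length = nx.dijkstra_path_length(g, source, sink, weight="length")
    except nx.NetworkXNoPath:
        return 0.0
    return math.exp(-length)


def path_strength_matrix(
    net: DiseaseNetwork,
    sources: Sequence[str],
    sinks: Sequence[str],
) -> pd.DataFrame:
    """Path strengths for every (source, sink) pair, one Dijkstra per source."""
    g = _length_graph(net)
    sinks = list(sinks)
    mat = np.zeros((len(sources), len(sinks)))
    for i, s in enumerate(sources):
        if s not in g:
            raise ValueError(f"unknown node {s!r}")
        lengths = nx.single_source_dijkstra_path_length(g, s, weight="length")
        for j, t in enumerate(sinks):
            if t not in g:
                raise ValueError(f"unknown node {t!r}")
            if t in lengths:
                mat[i, j] = math.exp(-lengths[t])
    return pd.DataFrame(mat, index=list(sources), columns=sinks)


def score_triplet(
    net: DiseaseNetwork,
    triplet: Sequence[str],
    dp_set: Iterable[str],
) -> float:
    """TSDS(T) = (1/|DP|) Σ_{d∈DP} max_{t∈T} path_strength(t, d)."""
    dps = sorted(set(dp_set))
    if not dps:
        raise ValueError("dp_set must be non-empty")
    strengths = path_strength_matrix(net, list(triplet), dps)
    return float(strengths.max(axis=0).mean())


def score_all_triplets(
    net: DiseaseNetwork,
    tps: Iterable[str],
    dp_set: Iterable[str],
    score_fn: TripletScorer | None = None,
) -> dict[Triplet, float]:
    """TSDS for every TP triplet.

    With the default scorer the TP→DP strength matrix is computed once
    and reused; an injected ``score_fn`` is called per triplet.
    """
    tps = sorted(set(tps))
    triplets = enumerate_triplets(tps)
    dps = sorted(set(dp_set))
    if not dps:
        raise ValueError("dp_set must be non-empty")
    if score_fn is not None:
        return {t: score_fn(net, t, frozenset(dps)) for t in triplets}
    strengths = path_strength_matrix(net, tps, dps).to_numpy()
    idx = {tp: i for i, tp in enumerate(tps)}
    return {
        t: float(strengths[[idx[a] for a in t], :].max(axis=0).mean())
        for t in triplets
    }


def null_distribution(
    net: DiseaseNetwork,
    tps: Iterable[str],
    dp_set: Iterable[str],
    n_samples: int = DEFAULT_NULL_SAMPLES,
    seed: int = 0,
    score_fn: TripletScorer | None = None,
) -> NullDistribution:
    """TSDS null from ``n_samples`` uniform random triplets of the TP set.

    Each draw samples three distinct TPs without replacement; draws are
    independent, so the null is exchangeable over the same support as
    the observed triplets.
    """
    tps = sorted(set(tps))
    if len(tps) < 3:
        raise ValueError(f"need at least 3 TPs, got {len(tps)}")
    dps = sorted(set(dp_set))
    rng = np.random.default_rng(seed)
    if score_fn is None:
        strengths = path_strength_matrix(net, tps, dps).to_numpy()
        draws = np.empty((n_samples, 3), dtype=np.int64)
        for i in range(n_samples):
            draws[i] = rng.choice(len(tps), size=3, replace=False)
        samples = strengths[draws, :].max(axis=1).mean(axis=1)
    else:
        samples = np.empty(n_samples)
        for i in range(n_samples):
            chosen = rng.choice(len(tps), size=3, replace=False)
            samples[i] = score_fn(net, tuple(tps[j] for j in chosen),
                                  frozenset(dps))
    return NullDistribution(samples=np.asarray(samples, dtype=float),
                            n_samples=n_samples, seed=seed)


def empirical_p_value(score: float, null: NullDistribution) -> float:
    """Add-one upper-tail estimator: (1 + #{null ≥ score}) / (1 + n)."""
    return float((1 + int(np.sum(null.samples >= score))) / (1 + null.n_samples))


def significant_triplets(
    scores: Mapping[Triplet, float],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
) -> list[TripletResult]:
    """Triplets with empirical p < alpha, sorted by TSDS descending.

    Returns a :class:`TripletResult` for every scored triplet; only the
    ``significant`` flag distinguishes kept from rejected combinations.
    ``alpha >= 1`` is the degenerate keep-everything setting (the
    add-one estimator can return exactly 1, which a strict comparison
    would otherwise drop).
    """
    if null.n_samples < 1:
        raise ValueError("null distribution is empty")
    keep_all = alpha >= 1.0
    # vectorized upper-tail counts via a sorted null
    sorted_null = np.sort(null.samples)
    results = []
    for triplet in sorted(scores):
        s = scores[triplet]
        n_ge = null.n_samples - int(np.searchsorted(sorted_null, s, side="left"))
        p = (1 + n_ge) / (1 + null.n_samples)
        results.append(TripletResult(triplet=triplet, tsds=float(s),
                                     p_value=float(p),
                                     significant=keep_all or p < alpha))
    results.sort(key=lambda r: (-r.tsds, r.triplet))
    return results


def tp_frequency(significant: Iterable[TripletResult]) -> dict[str, int]:
    """Membership count of each TP over the significant triplets."""
    counts: dict[str, int] = {}
    for res in significant:
        if not res.significant:
            continue
        for tp in res.triplet:
            counts[tp] = counts.get(tp, 0) + 1
    return counts


def results_table(results: Iterable[TripletResult]) -> pd.DataFrame:
    """Tabular view: triplet members, tsds, p_value, significant."""
    rows = [
        {"tp_1": r.triplet[0], "tp_2": r.triplet[1], "tp_3": r.triplet[2],
         "tsds": r.tsds, "p_value": r.p_value, "significant": r.significant}
        for r in results
    ]
    return pd.DataFrame(rows)
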