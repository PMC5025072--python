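"""Drug-action simulation scoring: PathEFF, DrugEFF, EFFECT, DPscore, Borda.

A treatment (single drug or compatible combination) initializes its
target nodes to 0/1 (drug decreases / increases the target), disease
nodes keep their expression-derived values, and every remaining node is
randomized; M Monte-Carlo simulations of the pathway ODE then measure
how often disease nodes are *regularized* (their discretized final
state flips away from the disease value) without perturbing healthy
nodes.  Per pathway this yields a confusion matrix whose F-measure is
PathEFF; averaging over simulations and aggregating over the pathways
containing treatment targets gives DrugEFF, and EFFECT is its
percentage change relative to the untreated (noDrug) baseline.
Disease-protein monitoring panels come from per-pathway regularization
probabilities (DPscore = median of the nonzero values) aggregated
across treatments by Borda count.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathway_boolean import (
    DEFAULT_HILL_K,
    DEFAULT_HILL_N,
    DEFAULT_T_END,
    DEFAULT_TAU,
    PathwayModel,
    simulate_ode_batch,
)

logger = logging.getLogger(__name__)

DEFAULT_M = 1000
DISCRETIZATION_THRESHOLD = 0.5


class IncompatibleCombinationError(ValueError):
    """Raised when combined drugs act oppositely on a shared target."""

    def __init__(self, conflicting_targets: Sequence[str]):
        self.conflicting_targets = list(conflicting_targets)
        super().__init__(
            "drugs act oppositely on shared target(s): "
            + ", ".join(self.conflicting_targets)
        )


@dataclass(frozen=True)
class DrugSpec:
    """A drug with its per-target action values (0 decreases, 1 increases)."""

    drug_id: str
    actions: Mapping[str, int]


@dataclass(frozen=True)
class TreatmentPlan:
    """A compatible drug set with the merged target→action map."""

    drugs: tuple[str, ...]
    merged_actions: Mapping[str, int]

    @property
    def name(self) -> str:
        return "+".join(self.drugs) if self.drugs else "noDrug"


@dataclass(frozen=True)
class ConfusionCounts:
    """Regularization confusion matrix of one simulation run."""

    trp: int  # disease nodes flipped away from their disease value
    fp: int   # free nodes perturbed by the treatment
    fn: int   # disease nodes left at their disease value
    tn: int   # free nodes left unperturbed


@dataclass
class MCRuns:
    """Initial/final discretized states of M Monte-Carlo runs of one pathway."""

    pathway_id: str
    node_order: list[str]
    initial: np.ndarray   # (M × N) binary
    final: np.ndarray     # (M × N) binary, discretized at 0.5
    dn_values: dict[str, int]
    clamped_targets: list[str]


@dataclass
class EfficacyScores:
    """Full scoring layer output for a set of treatments."""

    path_eff_mc: dict[tuple[str, str], float]  # (treatment, pathway) → mean PathEFF
    pathway_sets: dict[str, list[str]]
    drug_eff: dict[str, float]
    no_drug_eff: dict[str, float]
    effect: dict[str, float]
    m: int
    mode: str
    dp_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    borda: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Drug actions and combination compatibility
# ---------------------------------------------------------------------------

def drug_target_values(rows: pd.DataFrame | Iterable[Mapping],
                       drug_id: str | None = None) -> DrugSpec:
    """Derive per-target 0/1 action values from curated interaction rows.

    Each row carries ``drug_id``, ``target_id`` and a free-text
    ``action`` descriptor; descriptors containing "decreases" map to 0
    and "increases" to 1, other descriptors are ignored with a report.
    Conflicting rows for one (drug, target) pair are resolved by
    majority; exact ties drop the target.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if drug_id is not None:
        rows = rows[rows["drug_id"] == drug_id]
    elif rows["drug_id"].nunique() != 1:
        raise ValueError("rows span multiple drugs; pass drug_id explicitly")
    else:
        drug_id = str(rows["drug_id"].iloc[0])

    votes: dict[str, list[int]] = {}
    for _, row in rows.iterrows():
        action = str(row.get("action", "")).lower()
        if "decreas" in action:
            value = 0
        elif "increas" in action:
            value = 1
        else:
            logger.warning("drug %s target %s: unrecognized action %r ignored",
                           drug_id, row["target_id"], row.get("action"))
            continue
        votes.setdefault(str(row["target_id"]), []).append(value)

    actions = {}
    for target, vals in votes.items():
        ones, zeros = sum(vals), len(vals) - sum(vals)
        if ones == zeros:
            logger.warning("drug %s target %s: tied action votes, dropped",
                           drug_id, target)
            continue
        actions[target] = 1 if ones > zeros else 0
    return DrugSpec(drug_id=drug_id, actions=actions)


def compatible_combination(drugs: Sequence[DrugSpec]) -> TreatmentPlan:
    """Merge drug actions, rejecting combinations with opposite actions.

    Raises :class:`IncompatibleCombinationError` (listing the offending
    genes) iff any shared target receives both 0 and 1 across drugs.
    """
    if not drugs:
        raise ValueError("at least one drug is required")
    merged: dict[str, int] = {}
    conflicts: set[str] = set()
    for drug in drugs:
        for target, value in drug.actions.items():
            if target in merged and merged[target] != value:
                conflicts.add(target)
            merged[target] = int(value)
    if conflicts:
        raise IncompatibleCombinationError(sorted(conflicts))
    return TreatmentPlan(drugs=tuple(d.drug_id for d in drugs),
                         merged_actions=merged)


# ---------------------------------------------------------------------------
# Monte-Carlo simulation
# ---------------------------------------------------------------------------

def plan_targets_in(model: PathwayModel, plan: TreatmentPlan | None) -> list[str]:
    """Treatment targets present in the pathway (empty → pathway skipped)."""
    if plan is None:
        return []
    return sorted(set(plan.merged_actions) & set(model.rules))


def run_mc(
    model: PathwayModel,
    plan: TreatmentPlan | None,
    m: int = DEFAULT_M,
    seed: int = 0,
    hill_n: float = DEFAULT_HILL_N,
    hill_k: float = DEFAULT_HILL_K,
    tau: float = DEFAULT_TAU,
    t_end: float = DEFAULT_T_END,
    free_init: str = "bernoulli",
) -> MCRuns:
    """M Monte-Carlo simulations of one pathway under a treatment.

    Per run: disease nodes start at their expression-derived values,
    treatment targets at the drug-action values (initial values only —
    never clamped during integration), and every other node at an
    independent fair Bernoulli draw (``free_init="uniform"`` draws
    continuous U(0,1) instead).  ``plan=None`` is the noDrug condition:
    targets are randomized like free nodes.
    """
    if m < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(model.rules)
    index = {n: i for i, n in enumerate(order)}

    targets = plan_targets_in(model, plan)
    if free_init == "bernoulli":
        init = rng.integers(0, 2, size=(m, len(order))).astype(float)
    elif free_init == "uniform":
        init = rng.uniform(0.0, 1.0, size=(m, len(order)))
    else:
        raise ValueError(f"unknown free_init {free_init!r}")
    for node, value in model.dn_values.items():
        init[:, index[node]] = float(value)
    if plan is not None:
        for node in targets:
            init[:, index[node]] = float(plan.merged_actions[node])

    final = simulate_ode_batch(model.rules, init, node_order=order,
                               hill_n=hill_n, hill_k=hill_k, tau=tau,
                               t_end=t_end)
    return MCRuns(
        pathway_id=model.pathway_id,
        node_order=order,
        initial=(init > DISCRETIZATION_THRESHOLD).astype(int),
        final=(final > DISCRETIZATION_THRESHOLD).astype(int),
        dn_values=dict(model.dn_values),
        clamped_targets=targets,
    )


def confusion(
    initial: Mapping[str, int],
    final: Mapping[str, int],
    dn_values: Mapping[str, int],
    clamped_targets: Iterable[str] = (),
) -> ConfusionCounts:
    """Regularization confusion counts for one run.

    True positives are disease nodes whose discretized final state
    differs from the disease value; false positives are free (non-DN,
    non-target) nodes whose state changed from its initial draw — the
    drug's own target nodes are excluded, since changing them is the
    intervention, not a side effect.
    """
    clamped = set(clamped_targets)
    trp = fn = fp = tn = 0
    for node, disease_value in dn_values.items():
        if int(final[node]) != int(disease_value):
            trp += 1
        else:
            fn += 1
    for node in initial:
        if node in dn_values or node in clamped:
            continue
        if int(final[node]) != int(initial[node]):
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(trp=trp, fp=fp, fn=fn, tn=tn)


def confusion_per_run(runs: MCRuns) -> list[ConfusionCounts]:
    """Vectorized confusion counts for every Monte-Carlo run."""
    idx = {n: i for i, n in enumerate(runs.node_order)}
    dn_idx = np.array([idx[n] for n in runs.dn_values], dtype=int)
    dn_vals = np.array([runs.dn_values[n] for n in runs.dn_values], dtype=int)
    excluded = set(runs.dn_values) | set(runs.clamped_targets)
    free_idx = np.array([i for n, i in idx.items() if n not in excluded],
                        dtype=int)
    out = []
    for r in range(runs.initial.shape[0]):
        flipped = runs.final[r, dn_idx] != dn_vals if dn_idx.size else np.array([], bool)
        changed = (runs.final[r, free_idx] != runs.initial[r, free_idx]
                   if free_idx.size else np.array([], bool))
        out.append(ConfusionCounts(
            trp=int(flipped.sum()), fn=int((~flipped).sum()),
            fp=int(changed.sum()), tn=int((~changed).sum()),
        ))
    return out


# ---------------------------------------------------------------------------
# Efficacy indices
# ---------------------------------------------------------------------------

def path_eff(c: ConfusionCounts) -> float:
    """F-measure of the regularization confusion matrix (0 when TrP = 0)."""
    if c.trp == 0:
        return 0.0
    precision = c.trp / (c.trp + c.fp)
    recall = c.trp / (c.trp + c.fn)
    return 2.0 * precision * recall / (precision + recall)


def path_eff_mc(runs: MCRuns | Iterable[ConfusionCounts]) -> float:
    """Mean PathEFF over the M Monte-Carlo runs."""
    counts = confusion_per_run(runs) if isinstance(runs, MCRuns) else list(runs)
    if not counts:
        raise ValueError("no runs to average")
    return float(np.mean([path_eff(c) for c in counts]))


def drug_eff(
    path_scores: Mapping[str, float],
    pathway_set: Sequence[str],
    mode: str = "mean",
) -> float:
    """Aggregate PathEFF_MC over the pathways containing treatment targets.

    ``mode="mean"`` averages (the default), ``mode="sum"`` totals; the
    EFFECT index is invariant to this choice as long as the treated and
    untreated aggregations use the same pathway set and mode.
    """
    if not pathway_set:
        raise ValueError("empty pathway set: treatment has no simulated pathway")
    vals = [path_scores[p] for p in pathway_set]
    if mode == "mean":
        return float(np.mean(vals))
    if mode == "sum":
        return float(np.sum(vals))
    raise ValueError(f"unknown mode {mode!r}")


def effect_index(drug_eff_value: float, no_drug_eff_value: float) -> float:
    """EFFECT = 100 · (DrugEFF − noDrugEFF) / noDrugEFF."""
    if no_drug_eff_value <= 0:
        raise ValueError("noDrugEFF must be positive for a defined EFFECT")
    return 100.0 * (drug_eff_value - no_drug_eff_value) / no_drug_eff_value


# ---------------------------------------------------------------------------
# Disease-protein monitoring ranking
# ---------------------------------------------------------------------------

def dp_probability(nr: int, m: int, in_pathway: bool) -> float:
    """P_k(DP) = Nr/M when the DP belongs to pathway k, else 0."""
    if not in_pathway:
        return 0.0
    if not 0 <= nr <= m:
        raise ValueError("regularization count outside [0, M]")
    return nr / m


def regularization_probabilities(runs: MCRuns) -> dict[str, float]:
    """Per-DN fraction of runs in which the node was regularized."""
    idx = {n: i for i, n in enumerate(runs.node_order)}
    m = runs.final.shape[0]
    return {
        n: float((runs.final[:, idx[n]] != v).sum()) / m
        for n, v in runs.dn_values.items()
    }


def dp_score(p_values: Iterable[float]) -> float | None:
    """DPscore = median of the nonzero per-pathway probabilities.

    The median (rather than the mean over all pathways) favors DPs that
    respond strongly even if they appear in few pathways.  All-zero
    input returns None: the DP is excluded from that treatment's ranking.
    """
    nonzero = [p for p in p_values if p > 0]
    if not nonzero:
        return None
    return float(statistics.median(nonzero))


def borda_consensus(
    rankings: Mapping[str, Sequence[str] | Sequence[tuple[str, float]]],
) -> list[tuple[str, float]]:
    """Borda-count consensus over per-treatment DP rankings.

    In a ranking of m candidates the one at rank r (1-based) earns
    m − r points, so the top earns m − 1; candidates sharing a score
    (when rankings are given as (dp, score) pairs) share the average of
    the tied ranks' points, and candidates missing from a ranking earn
    0 from it.  The output is ordered by total points, lexicographic
    tie-break.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    totals: dict[str, float] = {}
    for _treatment, ranking in rankings.items():
        ranking = list(ranking)
        if ranking and isinstance(ranking[0], tuple):
            items = [(str(dp), float(s)) for dp, s in ranking]
            items.sort(key=lambda x: (-x[1], x[0]))
        else:
            items = [(str(dp), float(-r)) for r, dp in enumerate(ranking)]
        m = len(items)
        r = 0
        while r < m:
            tied = [items[r]]
            while r + len(tied) < m and items[r + len(tied)][1] == items[r][1]:
                tied.append(items[r + len(tied)])
            points = float(np.mean([m - (r + o + 1) for o in range(len(tied))]))
            for dp, _ in tied:
                totals[dp] = totals.get(dp, 0.0) + points
            r += len(tied)
    for ranking in rankings.values():
        for entry in ranking:
            dp = entry[0] if isinstance(entry, tuple) else entry
            totals.setdefault(str(dp), 0.0)
    return sorted(totals.items(), key=lambda x: (-x[1], x[0]))


# ---------------------------------------------------------------------------
# Orchestration over treatments and pathways
# ---------------------------------------------------------------------------

def score_treatments(
    models: Sequence[PathwayModel],
    plans: Sequence[TreatmentPlan],
    m: int = DEFAULT_M,
    seed: int = 0,
    mode: str = "mean",
    added_drug_targets: Mapping[str, Iterable[str]] | None = None,
    **sim_kwargs,
) -> EfficacyScores:
    """Run the full Monte-Carlo scoring layer for a set of treatments.

    For each treatment the pathway set contains the pathways where the
    treatment (or, when ``added_drug_targets`` names the drugs added on
    top of a base drug, any of those added drugs) has at least one
    target; the noDrug baseline is recomputed over the identical
    pathway set.  Per-treatment per-DP scores and the Borda consensus
    are filled in alongside the EFFECT indices.
    """
    rng = np.random.default_rng(seed)
    pathway_seed = {mdl.pathway_id: int(rng.integers(2**31)) for mdl in models}

    # noDrug runs are shared across treatments (same pathway, same seed)
    nodrug_runs = {
        mdl.pathway_id: run_mc(mdl, None, m=m, seed=pathway_seed[mdl.pathway_id],
                               **sim_kwargs)
        for mdl in models
    }
    nodrug_path_eff = {pid: path_eff_mc(r) for pid, r in nodrug_runs.items()}

    path_scores: dict[tuple[str, str], float] = {}
    pathway_sets: dict[str, list[str]] = {}
    drug_effs: dict[str, float] = {}
    nodrug_effs: dict[str, float] = {}
    effects: dict[str, float] = {}
    dp_scores: dict[tuple[str, str], float] = {}
    dp_rankings: dict[str, list[tuple[str, float]]] = {}

    for plan in plans:
        selector = None
        if added_drug_targets and plan.name in added_drug_targets:
            selector = set(added_drug_targets[plan.name])
        pset = []
        dp_probs: dict[str, list[float]] = {}
        for mdl in models:
            targets = plan_targets_in(mdl, plan)
            relevant = (set(targets) & selector) if selector is not None else targets
            if not targets or not relevant:
                logger.info("treatment %s: pathway %s skipped (no targets)",
                            plan.name, mdl.pathway_id)
                continue
            runs = run_mc(mdl, plan, m=m, seed=pathway_seed[mdl.pathway_id],
                          **sim_kwargs)
            path_scores[(plan.name, mdl.pathway_id)] = path_eff_mc(runs)
            pset.append(mdl.pathway_id)
            for dp, p in regularization_probabilities(runs).items():
                dp_probs.setdefault(dp, []).append(p)
        pathway_sets[plan.name] = pset
        if not pset:
            logger.warning("treatment %s has no pathway with targets; skipped",
                           plan.name)
            continue
        d_eff = drug_eff({p: path_scores[(plan.name, p)] for p in pset}, pset, mode)
        nd_eff = drug_eff(nodrug_path_eff, pset, mode)
        drug_effs[plan.name] = d_eff
        nodrug_effs[plan.name] = nd_eff
        effects[plan.name] = effect_index(d_eff, nd_eff)
        ranking = []
        for dp, probs in dp_probs.items():
            score = dp_score(probs)
            if score is not None:
                dp_scores[(plan.name, dp)] = score
                ranking.append((dp, score))
        if ranking:
            dp_rankings[plan.name] = sorted(ranking, key=lambda x: (-x[1], x[0]))

    borda = borda_consensus(dp_rankings) if dp_rankings else []
    return EfficacyScores(
        path_eff_mc=path_scores, pathway_sets=pathway_sets,
        drug_eff=drug_effs, no_drug_eff=nodrug_effs, effect=effects,
        m=m, mode=mode, dp_scores=dp_scores, borda=borda,
    )
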