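"""Drug–target prediction by collective matrix tri-factorization.

Heterogeneous sources over three object types (diseases, drugs,
proteins) are fused by jointly factorizing every relation matrix
R_ij ≈ G_i S_ij G_jᵀ with shared non-negative type factors G_i and
within-type constraint (penalty) matrices Θ_i.  The optimizer minimizes

    Σ_(i,j) ‖R_ij − G_i S_ij G_jᵀ‖_F²  +  Σ_i Σ_t tr(G_iᵀ Θ_i^(t) G_i)

subject to G_i ≥ 0, alternating an exact least-squares step for each
core S_ij with multiplicative updates for each G_i (positive/negative
part splitting handles sign-indefinite terms).  Reconstructed relation
entries that were zero in the input but score above a per-column
threshold are reported as predicted associations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

_EPS = 1e-12
_RIDGE = 1e-9

#: Conventional object-type indices for the drug-repurposing system.
DISEASE, DRUG, PROTEIN = 1, 2, 3


def _pos(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _neg(a: np.ndarray) -> np.ndarray:
    return np.maximum(-a, 0.0)


@dataclass
class FusionSystem:
    """Object types with their relation and constraint matrices.

    ``relations[(i, j)]`` is the non-negative n_i×n_j matrix linking
    types i and j; ``constraints[i]`` is a list of symmetric n_i×n_i
    penalty matrices (negative entries encode must-link similarity,
    positive entries cannot-link); ``labels[i]`` names the rows of
    type i; ``ranks[i]`` is the latent dimension k_i < n_i.
    """

    sizes: dict[int, int]
    relations: dict[tuple[int, int], np.ndarray]
    constraints: dict[int, list[np.ndarray]] = field(default_factory=dict)
    labels: dict[int, list[str]] = field(default_factory=dict)
    ranks: dict[int, int] = field(default_factory=dict)


@dataclass
class FusionFactors:
    """Learned non-negative factors G_i and cores S_ij with the objective trace."""

    G: dict[int, np.ndarray]
    S: dict[tuple[int, int], np.ndarray]
    objective_trace: list[float]


def default_rank(n: int) -> int:
    """Default latent dimension k = ceil(sqrt(n)/2), capped below n."""
    return min(max(1, math.ceil(math.sqrt(n) / 2)), n - 1)


def assemble_system(
    relations: Mapping[tuple[int, int], tuple[np.ndarray | sp.spmatrix,
                                              Sequence[str], Sequence[str]]],
    constraints: Mapping[int, list[tuple[np.ndarray | sp.spmatrix,
                                         Sequence[str]]]] | None = None,
    ranks: Mapping[int, int] | None = None,
) -> FusionSystem:
    """Validate labeled matrices and build a consistent fusion system.

    Each relation is supplied as (matrix, row_labels, col_labels) and
    each constraint as (matrix, labels).  Label sets of the same object
    type are intersected across matrices (mismatches are logged), every
    matrix is reindexed onto the common ordering, and non-negativity /
    symmetry invariants are checked.
    """
    if not relations:
        raise ValueError("at least one relation matrix is required")
    constraints = dict(constraints or {})

    # collect the label universe per type, then intersect
    type_labels: dict[int, list[set[str]]] = {}
    for (i, j), (mat, rows, cols) in relations.items():
        mat = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        if mat.size == 0:
            raise ValueError(f"relation R_{i}{j} is empty")
        if mat.min() < 0:
            raise ValueError(f"relation R_{i}{j} has negative entries")
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(f"relation R_{i}{j} shape/label mismatch")
        type_labels.setdefault(i, []).append(set(rows))
        type_labels.setdefault(j, []).append(set(cols))
    for i, mats in constraints.items():
        for t, (mat, labs) in enumerate(mats):
            dense = np.asarray(mat.todense() if sp.issparse(mat) else mat,
                               dtype=float)
            if not np.allclose(dense, dense.T, atol=1e-10):
                raise ValueError(f"constraint Θ_{i}[{t}] is not symmetric")
            type_labels.setdefault(i, []).append(set(labs))

    common: dict[int, list[str]] = {}
    for i, sets in type_labels.items():
        inter = set.intersection(*sets)
        union = set.union(*sets)
        if inter != union:
            logger.info("type %d: %d/%d labels shared across matrices; "
                        "restricting to the intersection",
                        i, len(inter), len(union))
        if not inter:
            raise ValueError(f"type {i}: label intersection is empty")
        common[i] = sorted(inter)

    def _reindex(mat, rows, cols, ri, cj):
        dense = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        ridx = [list(rows).index(lab) for lab in common[ri]]
        cidx = [list(cols).index(lab) for lab in common[cj]]
        return dense[np.ix_(ridx, cidx)]

    rel_out = {(i, j): _reindex(mat, rows, cols, i, j)
               for (i, j), (mat, rows, cols) in relations.items()}
    con_out = {
        i: [_reindex(mat, labs, labs, i, i) for mat, labs in mats]
        for i, mats in constraints.items()
    }
    sizes = {i: len(labs) for i, labs in common.items()}
    rank_out = {}
    for i, n in sizes.items():
        k = (ranks or {}).get(i, default_rank(n))
        if not 0 < k < n:
            raise ValueError(f"rank k_{i}={k} must satisfy 0 < k < n_{i}={n}")
        rank_out[i] = k
    return FusionSystem(sizes=sizes, relations=rel_out, constraints=con_out,
                        labels=common, ranks=rank_out)


def _objective(sys: FusionSystem, G: dict[int, np.ndarray],
               S: dict[tuple[int, int], np.ndarray]) -> float:
    obj = 0.0
    for (i, j), R in sys.relations.items():
        obj += float(np.linalg.norm(R - G[i] @ S[(i, j)] @ G[j].T, "fro") ** 2)
    for i, thetas in sys.constraints.items():
        for theta in thetas:
            obj += float(np.trace(G[i].T @ theta @ G[i]))
    return obj


def _solve_cores(sys: FusionSystem, G: dict[int, np.ndarray]
                 ) -> dict[tuple[int, int], np.ndarray]:
    """Exact least-squares core: S_ij = (G_iᵀG_i)⁻¹ G_iᵀ R_ij G_j (G_jᵀG_j)⁻¹."""
    S = {}
    for (i, j), R in sys.relations.items():
        GtGi = G[i].T @ G[i]
        GtGj = G[j].T @ G[j]
        for GtG in (GtGi, GtGj):
            if np.linalg.cond(GtG) > 1e12:
                GtG += _RIDGE * np.eye(GtG.shape[0])
                logger.debug("singular GᵀG regularized with ridge %g", _RIDGE)
        S[(i, j)] = np.linalg.solve(GtGi, G[i].T @ R @ G[j]) @ np.linalg.inv(
            GtGj + _RIDGE * np.eye(GtGj.shape[0]))
    return S


def _update_factors(sys: FusionSystem, G: dict[int, np.ndarray],
                    S: dict[tuple[int, int], np.ndarray]
                    ) -> dict[int, np.ndarray]:
    """Elementwise multiplicative factors sqrt(num/den) for every G_i.

    Positive/negative part splitting keeps numerator and denominator
    non-negative; rows with a vanishing denominator (objects without
    relation entries) get their factor clipped so a single sweep cannot
    overshoot — the caller damps the step further if the objective
    would increase.
    """
    factors = {}
    for i in sorted(sys.sizes):
        num = np.zeros_like(G[i])
        den = np.zeros_like(G[i])
        for (a, b), R in sys.relations.items():
            if a == i:
                Sab = S[(a, b)]
                RGS = R @ G[b] @ Sab.T
                GSGGS = G[i] @ (Sab @ (G[b].T @ G[b]) @ Sab.T)
                num += _pos(RGS) + _neg(GSGGS)
                den += _neg(RGS) + _pos(GSGGS)
            if b == i:
                Sab = S[(a, b)]
                RGS = R.T @ G[a] @ Sab
                GSGGS = G[i] @ (Sab.T @ (G[a].T @ G[a]) @ Sab)
                num += _pos(RGS) + _neg(GSGGS)
                den += _neg(RGS) + _pos(GSGGS)
        for theta in sys.constraints.get(i, []):
            num += _neg(theta) @ G[i]
            den += _pos(theta) @ G[i]
        factors[i] = np.clip(np.sqrt((num + _EPS) / (den + _EPS)), 0.01, 100.0)
    return factors


def factorize(
    sys: FusionSystem,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    n_restarts: int = 3,
) -> FusionFactors:
    """Fit non-negative factors by alternating S-solves and G-updates.

    Runs ``n_restarts`` seeded random non-negative initializations and
    keeps the one with the lowest final objective.  Iteration stops when
    the relative objective change drops below ``tol`` or after
    ``max_iter`` sweeps; the objective trace of the winning restart is
    returned and is non-increasing (within numerical slack).
    """
    best: FusionFactors | None = None
    master = np.random.default_rng(seed)
    for restart in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        G = {i: rng.uniform(0.1, 1.0, size=(n, sys.ranks[i]))
             for i, n in sys.sizes.items()}
        S = _solve_cores(sys, G)
        trace = [_objective(sys, G, S)]
        for _ in range(max_iter):
            factors = _update_factors(sys, G, S)
            prev = trace[-1]
            # damped multiplicative step: shrink the exponent until the
            # objective does not increase (keeps the trace monotone)
            gamma, accepted = 1.0, None
            while gamma >= 1.0 / 64.0:
                G_try = {i: G[i] * factors[i] ** gamma for i in G}
                S_try = _solve_cores(sys, G_try)
                obj = _objective(sys, G_try, S_try)
                if obj <= prev * (1 + 1e-12):
                    accepted = (G_try, S_try, obj)
                    break
                gamma /= 2.0
            if accepted is None:
                break  # no descent direction left: converged
            G, S, obj = accepted
            trace.append(obj)
            if prev > 0 and (prev - obj) / prev < tol:
                break
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = FusionFactors(G=G, S=S, objective_trace=trace)
    assert best is not None
    return best


def reconstruct_relation(fac: FusionFactors, sys: FusionSystem,
                         i: int, j: int) -> np.ndarray:
    """R̂_ij = G_i S_ij G_jᵀ."""
    if (i, j) not in sys.relations:
        raise ValueError(f"no relation between types {i} and {j}")
    return fac.G[i] @ fac.S[(i, j)] @ fac.G[j].T


def predict_associations(
    fac: FusionFactors,
    sys: FusionSystem,
    targets: Iterable[str] | None = None,
    relation: tuple[int, int] = (DRUG, PROTEIN),
) -> list[tuple[str, str, float, float]]:
    """Candidate new associations from the reconstructed drug–protein matrix.

    For each target column t (optionally restricted to ``targets``), the
    threshold τ_t is the mean reconstructed value over the column's
    known (nonzero) input entries — the global known-entry mean when the
    column has none.  An entry (d, t) is predicted iff R_ij[d,t] = 0 and
    R̂_ij[d,t] ≥ τ_t.  Returns (drug, target, score, tau) sorted by
    score descending.
    """
    i, j = relation
    R = sys.relations[(i, j)]
    R_hat = reconstruct_relation(fac, sys, i, j)
    row_labels = sys.labels[i]
    col_labels = sys.labels[j]
    known = R > 0
    if not known.any():
        raise ValueError("relation has no known entries to calibrate against")
    global_tau = float(R_hat[known].mean())

    col_idx = range(len(col_labels)) if targets is None else [
        col_labels.index(t) for t in targets
    ]
    out = []
    for c in col_idx:
        col_known = known[:, c]
        tau = float(R_hat[col_known, c].mean()) if col_known.any() else global_tau
        for r in np.where(~col_known & (R_hat[:, c] >= tau))[0]:
            out.append((row_labels[r], col_labels[c], float(R_hat[r, c]), tau))
    out.sort(key=lambda x: (-x[2], x[0], x[1]))
    return out


def merge_candidates(
    known: Mapping[str, Iterable[str]],
    predicted: Mapping[str, Iterable[str]],
    targets: Iterable[str] | None = None,
) -> list[dict]:
    """Per-target union of known and predicted drugs, provenance-tagged.

    A drug present in both lists appears once, tagged ``known``.
    Targets with no drug from either source get a ``"No drugs"`` row.
    """
    if targets is None:
        targets = sorted(set(known) | set(predicted))
    rows = []
    for t in targets:
        known_drugs = sorted(set(known.get(t, ())))
        pred_drugs = sorted(set(predicted.get(t, ())) - set(known_drugs))
        rows.append({
            "target": t,
            "known_drugs": known_drugs,
            "predicted_drugs": pred_drugs,
            "status": "ok" if known_drugs or pred_drugs else "No drugs",
        })
    return rows


def write_labeled_matrix(mat: np.ndarray, path: str | Path,
                         row_labels: Sequence[str],
                         col_labels: Sequence[str]) -> None:
    """Write a matrix as MatrixMarket plus .rows/.cols label files."""
    path = Path(path)
    mmwrite(str(path), sp.csr_matrix(mat))
    path.with_suffix(".rows").write_text("\n".join(row_labels) + "\n")
    path.with_suffix(".cols").write_text("\n".join(col_labels) + "\n")


def read_labeled_matrix(path: str | Path
                        ) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_labeled_matrix`."""
    path = Path(path)
    raw = mmread(str(path))
    mat = np.asarray(raw.todense() if sp.issparse(raw) else raw, dtype=float)
    rows = path.with_suffix(".rows").read_text().splitlines()
    cols = path.with_suffix(".cols").read_text().splitlines()
    return mat, rows, cols
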