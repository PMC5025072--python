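# Methods

## Disease network construction

The network is seeded on the disease-protein (DP) list and expanded
exactly one hop: the node set is the DPs plus every direct interactor
connected by a qualifying edge, and an edge is retained iff (i) its
combined confidence strictly exceeds the cutoff (default 0.7, the usual
high-confidence operating point of STRING-style scores; `>` not `≥`),
(ii) at least one of the required evidence channels (default
`experimental` or `database`) is positive, and (iii) both endpoints are
in the node set.  The evidence requirement is disjunctive: either
channel alone qualifies an edge.  Edge weights equal the combined
score.  DPs left without any qualifying edge are retained as isolated
nodes — they remain legitimate destinations for the synergy score even
when unreachable — and are reported.  Duplicate and reversed input rows
collapse onto one undirected edge (highest confidence wins), so record
order never affects the result.  A percentile mode reinterprets the
cutoff as a quantile of the input score distribution for users whose
exports are not on the STRING scale.

## Target selection

Degree is the unweighted neighbor count.  Random-walk betweenness B(i)
is Newman's current-flow betweenness with edge weights as conductances,
computed per connected component and normalized by (N−1)(N−2)/2 within
each component; components of fewer than three nodes carry no
through-flow and score 0.  The bridging coefficient is
BC(i) = D(i) / Σ_{v∈N(i)} 1/D(v) (undefined for isolated nodes, which
are excluded from the ranking) and BR(i) = BC(i)·B(i) exactly.

The hub set is the top ⌊0.20·N⌋ nodes by degree and the bridging set
the top ⌈0.25·N⌉ by BR: floor for hubs and ceiling for bridging is the
only convention pair consistent with 110 hubs and 139 bridging nodes
out of 554, the sizes the selection rules are expected to produce at
that network size.  Ties at either cut are broken lexicographically by
node ID so selections are reproducible; the realized cutoffs are
logged.  Druggability requires one association with confidence
strictly above 0.9 or one row from a curated source (default
`drugbank`, `ctd`), which is confidence-exempt.  The target set is
(bridging ∩ druggable) \ hubs.

## TSDS triplet ranking

Path strength between two nodes is the maximum product of edge
confidences over connecting paths, computed as exp(−L) for the Dijkstra
length L under edge length −ln(weight); a node to itself scores 1 and
disconnected pairs 0.  The triplet score is

TSDS(T) = (1/|DP|) Σ_{d∈DP} max_{t∈T} s(t, d) ∈ [0, 1],

i.e. every DP is credited with its best-connected triplet member, so a
high score requires coverage of the whole DP panel through confident
paths.  The scorer is injectable (`score_fn`) so a different synergy
functional can reuse the enumeration/null/significance machinery
unchanged.

The null distribution samples triplets uniformly from the TP set
(three distinct TPs per draw, draws independent): the observed
statistics are TP triplets, so the null must be exchangeable over the
same support; permuting DP labels instead is a plausible alternative
the package deliberately does not implement.  p-values use the add-one
estimator p = (1 + #{null ≥ score}) / (1 + n), which cannot return 0;
significance is strict p < α (default 0.01).  α ≥ 1 is treated as the
degenerate keep-everything setting because the add-one estimator can
return exactly 1.

## Data-fusion drug prediction

The fusion system carries three object types (disease, drug, protein)
with relation matrices R_13, R_21, R_23 and per-type symmetric penalty
matrices Θ_i.  The objective

Σ_(i,j) ‖R_ij − G_i S_ij G_jᵀ‖_F² + Σ_i Σ_t tr(G_iᵀ Θ_i^(t) G_i),
G_i ≥ 0,

is minimized by alternating an exact least-squares core step
S_ij = (G_iᵀG_i)⁻¹ G_iᵀ R_ij G_j (G_jᵀG_j)⁻¹ (ridge 1e-9 on
ill-conditioned Gram matrices) with multiplicative updates of each G_i
using positive/negative part splitting of every sign-indefinite term.
Two numerical safeguards matter in practice: the elementwise update
factor sqrt(num/den) is clipped to [0.01, 100] because rows without any
relation entry can have a vanishing denominator, and each sweep is
damped by exponent backtracking (γ = 1, 1/2, … 1/64), accepting the
first step that does not increase the objective.  The returned
objective trace is therefore monotone non-increasing by construction;
if no damped step descends, the fit is declared converged.  Default
rank k_i = ⌈√n_i / 2⌉ (capped at n_i − 1); initialization is seeded
uniform-random with 3 restarts keeping the best final objective.

Unobserved relation entries are treated as zeros in the loss (no
masking).  A zero entry (d, t) becomes a predicted association when its
reconstruction reaches τ_t, the mean reconstructed value of column t's
known entries (global known mean for empty columns).  This per-column
threshold is deliberately conservative: when the factorization fits the
inputs tightly, held-out entries reconstruct just below their column's
known mean even while ranking far above the other zeros, so the
*ranking* of candidate scores is the more robust signal and both score
and τ are reported per prediction.

Penalty matrices encode must-link structure as graph Laplacians
(D − A of the similarity graph).  A purely negative Θ makes the
objective unbounded below — rescaling S absorbs the reconstruction term
while the trace term diverges — which is why the generator emits the
bounded Laplacian form.

## Boolean pathway models

KGML entries of type `gene` become nodes (multi-gene entries fan out to
one node per gene sharing the entry's edges; groups expand to their
members); relation subtypes map onto Boolean contributions —
activation, expression, indirect effect, state change,
binding/association, phosphorylation, glycosylation, ubiquitination and
methylation contribute an AND term, while inhibition, repression,
dissociation and dephosphorylation contribute a negated term.  Unknown
subtypes default to AND with a warning; compound-mediated relations
collapse to direct edges with a warning.  A node with activators {A_i}
and inhibitors {I_j} updates as (⋀ A_i) ∧ (⋀ ¬I_j); a source that both
activates and inhibits the same target is treated as an inhibitor.
Nodes without regulators are inputs and hold their value, modeling a
sustained condition.  Two documented variants ship disabled by
default: conjoining the target itself ("A activates B" read literally
as next(B) = A ∧ B), which globally freezes all-zero states and is
therefore off unless requested, and OR-combination of activators,
which real pathways often need but which is not the default reading.

Expression calls count only experiments with fold change strictly
above 2; direction is the majority over counted experiments and exact
ties are discarded.  Up-regulated genes present in a pathway become
disease nodes at 1, down-regulated at 0.

For simulation, each rule is interpolated multilinearly over [0,1]^n
(BooleCube).  Because every compiled rule is a product of literal
blocks on disjoint variables, the interpolation factorizes into the
closed form Π x_a · Π (1−x_i) (OR blocks: 1 − Π(1−x_a)), which the ODE
uses; the generic corner-sum evaluator exists for verification and the
two agree to machine precision.  Inputs pass through the normalized
Hill transform H(x) = x^n/(x^n + k^n) · (1 + k^n) with n = 3, k = 0.5
(H(0) = 0, H(1) = 1 exactly, so Boolean corners are equilibria), and
states follow dx/dt = (B̄(H(x)) − x)/τ with τ = 1 to t_end = 50,
integrated with LSODA at rtol 1e-6 / atol 1e-8.  All Monte-Carlo runs
of a pathway integrate as one block system, which amortizes solver
overhead.  Trajectories remain in [0,1]^N; final states discretize at
0.5.

## Efficacy scoring

Per run, disease nodes start at their disease values, treatment targets
at the merged drug-action values (initial values only — never clamped
during integration), and every other node at an independent fair
Bernoulli draw (continuous U(0,1) is a config option).  The untreated
(noDrug) condition randomizes targets like free nodes.  Treated and
untreated runs of a pathway share the per-pathway seed (common random
numbers), so EFFECT comparisons are paired and a dynamically irrelevant
drug scores exactly 0.

A disease node is regularized when its discretized final state differs
from the disease value (TrP; unchanged → FN).  Free nodes that moved
from their initial draw are FP, unchanged TN; the drug's own targets
are excluded from FP/TN because changing them is the intervention, not
a side effect.  PathEFF is the F-measure (0 when TrP = 0), averaged
over the M runs.  DrugEFF aggregates PathEFF_MC over the pathways in
which the treatment has at least one target — mean by default, sum
available; EFFECT = 100·(DrugEFF − noDrugEFF)/noDrugEFF is invariant to
that choice whenever both conditions use the same pathway set, which
the implementation enforces.  For combinations built on a base drug,
the pathway set can be restricted to pathways containing the *added*
drugs' targets.

DPscore for a treatment is the median of the nonzero per-pathway
regularization probabilities Nr/M — the median deliberately favors DPs
that respond strongly in few pathways; all-zero DPs are excluded from
that treatment's ranking.  The Borda consensus gives the candidate at
rank r of m the score m − r, with tied scores sharing averaged points,
absentees earning 0 and lexicographic final tie-breaks.

## Synthetic data

The generators produce every input format the pipeline reads, with
ground truth sufficient to score all recovery tests offline:

- **PPI**: planted-partition communities (within-community edge
  probability p_in) joined only through designated bridge nodes, each
  wired to max(1, round(p_out·community_size)) members per side,
  always including a DP so bridges survive the one-hop expansion.
  Weights are Uniform(0.71, 1.0) — above the confidence cutoff — with
  an optional below-cutoff contamination fraction to exercise the
  filter.  Bridge labels are the ground truth for centrality tests.
- **KGML**: random DAGs (optional feedback edges) with subtypes drawn
  from the relation vocabulary at a controlled inhibition fraction; the
  generator also emits the rules a correct parser must compile.
- **Fusion**: block-membership factors with diagonal cores; relations
  are thresholded to binary at the requested density, n_masked true
  drug–protein entries are zeroed and recorded as the recovery key, and
  Θ_i are Laplacians of sampled same-block similarity graphs.
- **Expression**: designated clean-up, clean-down, exact-tie and
  sub-threshold genes with per-experiment fold changes.

These fixtures reproduce the structural features the algorithms exploit
— modular topology with bridges, confident weighted edges, typed
regulatory logic, low-rank association structure, majority-vote
expression evidence.  They do not mimic scale-free degree
distributions, annotation or ascertainment biases, correlated evidence
channels, or the noise character of real microarrays (a
preferential-attachment network mode exists but is not the default), so
passing tests demonstrate correctness of the computations and
recoverability of planted structure, not performance on real databases.

## Problem sizes and determinism

The default end-to-end fixture run uses a three-community network
(25 nodes per community, 3 bridges, 20% DPs), three 10-node pathways,
a 40/50/60 fusion system, 2 000 null samples and M = 200; the
acceptance script additionally runs the fusion recovery benchmark at
n = (100, 150, 200) over 10 seeds and the sham/flip EFFECT contrast at
M = 1000.  These sizes keep the whole suite in tens of seconds while
leaving every statistic away from its small-sample degeneracies.  All
randomness flows from a single master seed through per-step derived
seeds recorded in the run manifest; reruns are byte-identical.

## Known limitations

- The TSDS functional is one concrete realization of a
  weighted-shortest-path coverage score; other variants plug in via
  `score_fn` but none is endorsed as canonical.
- The τ_t prediction threshold is conservative under tight fits (see
  above); consumers ranking candidates should use the scores, not only
  the thresholded set.
- Boolean semantics are synchronous-deterministic through the
  continuous conversion; asynchronous or probabilistic update schemes
  and attractor analysis are out of scope.
- Hub exclusion is the only toxicity proxy; there is no
  pharmacokinetics, dosing or side-effect modeling.
- Identifier namespaces are opaque strings: no ortholog or ID mapping
  is performed, and mapping tables must be applied upstream.
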