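"""Synthetic generators for every input the pipeline consumes.

Emits STRING-style interaction TSVs with planted community/bridge
structure, disease-protein lists, drug–target tables, KGML pathway XML
with known ground-truth Boolean rules, per-experiment expression tables
with controllable majority/tie structure, and tri-factorization systems
with planted low-rank block structure and masked (held-out) true
associations.  Everything is deterministic given the seed and is
written in exactly the external format its consumer module reads, so
the full pipeline and all recovery tests run without any download.

These generators emulate the *structural* features the algorithms
exercise (bridges between modules, weighted high-confidence edges,
typed regulatory relations, majority-vote expression calls, low-rank
association structure); they make no attempt to mimic the degree
distributions or annotation biases of the real databases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .pathway_boolean import (
    ACTIVATING_RELATIONS,
    INHIBITING_RELATIONS,
    BooleanRule,
)

_REL_SYMBOL = {
    "activation": "-->", "expression": "-->", "indirect effect": "..>",
    "state change": "...", "binding/association": "--",
    "phosphorylation": "+p", "glycosylation": "+g", "ubiquitination": "+u",
    "methylation": "+m", "inhibition": "--|", "repression": "--|",
    "dissociation": "-+-", "dephosphorylation": "-p",
}


@dataclass
class NetworkSpec:
    """Planted-partition PPI fixture: communities joined by bridge nodes."""

    n_communities: int = 2
    community_size: int = 20
    p_in: float = 0.3
    p_out: float = 0.15
    n_bridges: int = 1
    weight_range: tuple[float, float] = (0.71, 1.0)
    dp_fraction: float = 0.25
    contamination: float = 0.0  # fraction of extra below-cutoff edges


@dataclass
class PathwaySpec:
    """Random-DAG KGML fixture with a controlled activation:inhibition mix."""

    pathway_id: str = "synthetic01"
    n_nodes: int = 10
    n_edges: int = 14
    inhibition_fraction: float = 0.3
    n_feedback_edges: int = 0


@dataclass
class FusionSpec:
    """Three-type fusion system with planted block structure."""

    sizes: dict[int, int] = field(default_factory=lambda: {1: 40, 2: 50, 3: 60})
    true_ranks: dict[int, int] = field(default_factory=lambda: {1: 3, 2: 3, 3: 3})
    density: float = 0.05
    noise: float = 0.0
    n_masked: int = 10


@dataclass
class ExpressionSpec:
    """Expression fixture with designated up/down/tie/sub-threshold genes."""

    n_genes: int = 100
    n_experiments: int = 3
    up_fraction: float = 0.3
    down_fraction: float = 0.3
    tie_fraction: float = 0.1
    fc_range: tuple[float, float] = (2.5, 6.0)


@dataclass
class FixtureSpec:
    """Bundle of all generator settings under one master seed."""

    seed: int = 0
    network: NetworkSpec = field(default_factory=NetworkSpec)
    pathway: PathwaySpec = field(default_factory=PathwaySpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)


# ---------------------------------------------------------------------------
# PPI network with planted bridges
# ---------------------------------------------------------------------------

def gen_ppi(spec: NetworkSpec, seed: int, out_dir: str | Path) -> dict:
    """Write a STRING-style TSV plus DP list with planted bridge structure.

    Communities are dense blocks; each bridge node links two adjacent
    communities through max(1, round(p_out·community_size)) edges per
    side (always including one DP per side, so bridges survive the
    DP-seeded one-hop expansion).  Edge weights are Uniform over
    ``weight_range`` (above the 0.7 cutoff by default); an optional
    contamination fraction adds below-cutoff edges to exercise the
    confidence filter.  Returns paths and the ground-truth bridge list.
    """
    if spec.p_out == 0 and spec.n_bridges > 0:
        raise ValueError("bridges need p_out > 0 to receive cross-community edges")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    communities = [
        [f"C{c}N{i:03d}" for i in range(spec.community_size)]
        for c in range(spec.n_communities)
    ]
    bridges = [f"BRIDGE{k}" for k in range(spec.n_bridges)]
    lo, hi = spec.weight_range

    dps: list[str] = []
    for members in communities:
        n_dp = max(1, round(spec.dp_fraction * len(members)))
        dps.extend(rng.choice(members, size=n_dp, replace=False).tolist())

    edges: list[tuple[str, str, float]] = []
    for members in communities:
        for a, b in itertools.combinations(members, 2):
            if rng.random() < spec.p_in:
                edges.append((a, b, float(rng.uniform(lo, hi))))
    dp_by_comm = [sorted(set(members) & set(dps)) for members in communities]
    m_side = max(1, round(spec.p_out * spec.community_size))
    for k, bridge in enumerate(bridges):
        for side in (k % spec.n_communities, (k + 1) % spec.n_communities):
            members = communities[side]
            anchor = dp_by_comm[side][int(rng.integers(len(dp_by_comm[side])))]
            chosen = {anchor}
            while len(chosen) < min(m_side, len(members)):
                chosen.add(members[int(rng.integers(len(members)))])
            for node in sorted(chosen):
                edges.append((bridge, node, float(rng.uniform(lo, hi))))

    n_contam = round(spec.contamination * len(edges))
    all_nodes = [n for c in communities for n in c] + bridges
    for _ in range(n_contam):
        a, b = rng.choice(all_nodes, size=2, replace=False)
        edges.append((str(a), str(b), float(rng.uniform(0.3, 0.69))))

    rows = [{"protein1": a, "protein2": b,
             "experimental": round(w * 0.9, 4), "database": round(w * 0.8, 4),
             "combined_score": round(w, 4)} for a, b, w in edges]
    interactions_path = out_dir / "interactions.tsv"
    pd.DataFrame(rows).to_csv(interactions_path, sep="\t", index=False)
    dp_path = out_dir / "disease_proteins.txt"
    dp_path.write_text("\n".join(sorted(set(dps))) + "\n")
    return {
        "interactions": interactions_path,
        "dp_list": dp_path,
        "bridges": bridges,
        "communities": communities,
        "dps": sorted(set(dps)),
    }


def gen_drug_table(
    druggable_nodes: list[str],
    seed: int,
    out_path: str | Path,
    drugs_per_node: int = 2,
    curated_fraction: float = 0.3,
) -> Path:
    """Drug–target TSV giving every listed node a qualifying association.

    Associations are high-confidence (score in (0.9, 1.0], STITCH-like)
    or curated rows without a confidence (DrugBank/CTD-like), so the
    listed nodes all pass the druggability filter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    drug_counter = itertools.count()
    for node in sorted(druggable_nodes):
        for _ in range(drugs_per_node):
            drug = f"D{next(drug_counter):04d}"
            if rng.random() < curated_fraction:
                rows.append({"drug_id": drug, "target_id": node,
                             "confidence": "", "source": "drugbank",
                             "action": "increases expression"})
            else:
                rows.append({"drug_id": drug, "target_id": node,
                             "confidence": round(float(rng.uniform(0.901, 1.0)), 3),
                             "source": "stitch",
                             "action": "decreases expression"})
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return out_path


# ---------------------------------------------------------------------------
# KGML pathways
# ---------------------------------------------------------------------------

def gen_kgml(spec: PathwaySpec, seed: int, out_path: str | Path
             ) -> tuple[Path, dict[str, BooleanRule]]:
    """Write a random-DAG KGML file and its ground-truth Boolean rules.

    Edges run from lower to higher node index (plus optional feedback
    edges in the reverse direction); each relation draws one subtype
    from the activating or inhibiting vocabulary according to the
    requested inhibition fraction.  The returned rules are what a
    correct parser+compiler must reproduce (default compile settings).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(spec.n_nodes)]
    possible = [(i, j) for i in range(spec.n_nodes)
                for j in range(i + 1, spec.n_nodes)]
    n_edges = min(spec.n_edges, len(possible))
    chosen = [possible[i] for i in
              rng.choice(len(possible), size=n_edges, replace=False)]
    if spec.n_feedback_edges:
        back = [(j, i) for i, j in possible if (i, j) not in chosen]
        for idx in rng.choice(len(back), size=min(spec.n_feedback_edges,
                                                  len(back)), replace=False):
            chosen.append(back[idx])

    act_vocab = sorted(ACTIVATING_RELATIONS)
    inh_vocab = sorted(INHIBITING_RELATIONS)
    typed_edges = []
    for i, j in chosen:
        if rng.random() < spec.inhibition_fraction:
            subtype = inh_vocab[int(rng.integers(len(inh_vocab)))]
        else:
            subtype = act_vocab[int(rng.integers(len(act_vocab)))]
        typed_edges.append((i, j, subtype))

    root = etree.Element("pathway", name=f"path:{spec.pathway_id}",
                         org="syn", number="00001", title=spec.pathway_id)
    for idx, gene in enumerate(genes):
        entry = etree.SubElement(root, "entry", id=str(idx + 1),
                                 name=f"syn:{idx + 1}", type="gene")
        etree.SubElement(entry, "graphics", name=gene, type="rectangle")
    for i, j, subtype in typed_edges:
        rel = etree.SubElement(root, "relation", entry1=str(i + 1),
                               entry2=str(j + 1), type="PPrel")
        etree.SubElement(rel, "subtype", name=subtype,
                         value=_REL_SYMBOL[subtype])

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_bytes(etree.tostring(root, pretty_print=True,
                                        xml_declaration=True, encoding="UTF-8"))

    activators: dict[str, set[str]] = {g: set() for g in genes}
    inhibitors: dict[str, set[str]] = {g: set() for g in genes}
    for i, j, subtype in typed_edges:
        if subtype in INHIBITING_RELATIONS:
            inhibitors[genes[j]].add(genes[i])
        else:
            activators[genes[j]].add(genes[i])
    truth = {}
    for g in genes:
        acts = activators[g] - inhibitors[g]  # inhibitor wins on contradictions
        truth[g] = BooleanRule(target=g, activators=tuple(sorted(acts)),
                               inhibitors=tuple(sorted(inhibitors[g])))
    return out_path, truth


# ---------------------------------------------------------------------------
# Fusion systems with planted structure
# ---------------------------------------------------------------------------

def gen_fusion(spec: FusionSpec, seed: int) -> dict:
    """Planted-block fusion system with masked held-out associations.

    Each object belongs to one latent block; relation matrices are
    block-consistent binary matrices obtained by thresholding
    G_i S_ij G_jᵀ (plus optional noise) at the quantile matching the
    requested density.  ``n_masked`` true drug–protein entries are
    zeroed out and recorded as the recovery key; constraint matrices
    Θ_i are must-link penalties (−1) between objects sharing a block.
    """
    rng = np.random.default_rng(seed)
    labels = {i: [f"T{i}O{r:03d}" for r in range(n)]
              for i, n in spec.sizes.items()}
    G = {}
    blocks = {}
    for i, n in spec.sizes.items():
        k = spec.true_ranks[i]
        assign = rng.integers(0, k, size=n)
        blocks[i] = assign
        g = rng.uniform(0.0, 0.1, size=(n, k))
        g[np.arange(n), assign] = rng.uniform(0.8, 1.2, size=n)
        G[i] = g

    pairs = [(1, 3), (2, 1), (2, 3)]
    relations = {}
    full = {}
    for (i, j) in pairs:
        S = np.diag(rng.uniform(0.8, 1.2, size=min(spec.true_ranks[i],
                                                   spec.true_ranks[j])))
        core = np.zeros((spec.true_ranks[i], spec.true_ranks[j]))
        core[:S.shape[0], :S.shape[1]] = S
        R_cont = G[i] @ core @ G[j].T
        if spec.noise > 0:
            R_cont = R_cont + rng.normal(0.0, spec.noise, size=R_cont.shape)
        cut = np.quantile(R_cont, 1.0 - spec.density)
        R_bin = (R_cont > cut).astype(float)
        full[(i, j)] = R_bin.copy()
        relations[(i, j)] = R_bin

    masked = []
    R23 = relations[(2, 3)]
    ones = np.argwhere(full[(2, 3)] > 0)
    rng.shuffle(ones)
    for r, c in ones[: spec.n_masked]:
        R23[r, c] = 0.0
        masked.append((labels[2][r], labels[3][c]))

    constraints = {}
    for i, n in spec.sizes.items():
        same = blocks[i][:, None] == blocks[i][None, :]
        # sparse must-link sample among same-block pairs
        prob = rng.random((n, n)) < 0.1
        adj = (same & prob).astype(float)
        adj = np.maximum(adj, adj.T)
        np.fill_diagonal(adj, 0.0)
        # Laplacian penalty: tr(Gᵀ(D−A)G) pulls same-block rows together
        # while staying bounded below
        constraints[i] = [np.diag(adj.sum(axis=1)) - adj]

    return {
        "relations": {pair: (relations[pair], labels[pair[0]], labels[pair[1]])
                      for pair in pairs},
        "constraints": {i: [(constraints[i][0], labels[i])]
                        for i in spec.sizes},
        "labels": labels,
        "masked": masked,
        "full": full,
        "blocks": blocks,
    }


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def gen_expression(spec: ExpressionSpec, seed: int, out_path: str | Path
                   ) -> tuple[Path, dict[str, str]]:
    """Expression TSV with ground-truth up/down/tie/sub-threshold labels.

    Clean up/down genes carry a strict majority of above-threshold
    experiments in one direction; tie genes have exactly balanced
    above-threshold up and down experiments (and are therefore
    discarded by the majority rule); the remainder stays strictly below
    the fold-change threshold and is never called.
    """
    rng = np.random.default_rng(seed)
    n_up = round(spec.up_fraction * spec.n_genes)
    n_down = round(spec.down_fraction * spec.n_genes)
    n_tie = round(spec.tie_fraction * spec.n_genes)
    if n_up + n_down + n_tie > spec.n_genes:
        raise ValueError("up/down/tie fractions exceed 1")
    lo, hi = spec.fc_range
    truth: dict[str, str] = {}
    rows = []

    def fc_above() -> float:
        return round(float(rng.uniform(lo, hi)), 3)

    def fc_below() -> float:
        return round(float(rng.uniform(1.05, 1.9)), 3)

    gene_id = (f"GENE{i:04d}" for i in range(spec.n_genes))
    for label, count in (("up", n_up), ("down", n_down), ("tie", n_tie)):
        for _ in range(count):
            gene = next(gene_id)
            truth[gene] = label
            if label == "tie":
                rows.append({"gene": gene, "experiment": "E1",
                             "fc": fc_above(), "direction": "up"})
                rows.append({"gene": gene, "experiment": "E2",
                             "fc": fc_above(), "direction": "down"})
            else:
                minority = "down" if label == "up" else "up"
                n_min = (spec.n_experiments - 1) // 2
                for e in range(spec.n_experiments - n_min):
                    rows.append({"gene": gene, "experiment": f"E{e + 1}",
                                 "fc": fc_above(), "direction": label})
                for e in range(n_min):
                    rows.append({"gene": gene, "experiment": f"EX{e + 1}",
                                 "fc": fc_above(), "direction": minority})
    for gene in gene_id:
        truth[gene] = "subthreshold"
        for e in range(spec.n_experiments):
            rows.append({"gene": gene, "experiment": f"E{e + 1}",
                         "fc": fc_below(),
                         "direction": "up" if rng.random() < 0.5 else "down"})

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return out_path, truth


def gen_drug_actions(
    targets: list[str],
    seed: int,
    out_path: str | Path | None = None,
    n_drugs: int = 3,
    targets_per_drug: int = 2,
) -> pd.DataFrame:
    """Curated drug–gene action rows for the simulation layer."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_drugs):
        drug = f"DRUG{d:02d}"
        chosen = rng.choice(sorted(targets),
                            size=min(targets_per_drug, len(targets)),
                            replace=False)
        for t in chosen:
            verb = "decreases" if rng.random() < 0.5 else "increases"
            noun = "expression" if rng.random() < 0.5 else "activity"
            rows.append({"drug_id": drug, "target_id": str(t),
                         "action": f"{verb} {noun}"})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
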