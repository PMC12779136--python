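"""Multi-level feature-importance analysis over flux features.

Reactions: impurity-based random-forest importances plus Spearman rank
correlation of each flux column against the disease state.  Pathways: the
mean importance of member reactions, normalized to percentage shares.
Genes: reaction importances are rolled up through the GPRs with a sigmoid
weight ``0.5 + 0.5 * sigmoid(k (n_reactions - n0))`` that gives extra weight
to genes spanning many reactions while preserving at least half weight for
single-reaction genes; family scores sum over member genes and the top
families are tiered by quartiles (Very High / High / Medium / Low).
Clustering and rolling-activity summaries back the reaction-level figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as average_linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .classify import FeatureMatrix
from .core_model import MetabolicNetwork

TIERS = ("Very High", "High", "Medium", "Low")


@dataclass(frozen=True)
class ImportanceConfig:
    sigmoid_k: float = 1.0
    sigmoid_n0: float | None = None  # None -> median reaction count over genes
    top_k_genes: int = 15
    cluster_top_n: int = 70
    activity_window: int = 10
    activity_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigmoid_k <= 0:
            raise ValueError("sigmoid_k must be positive")
        if self.top_k_genes < 4:
            raise ValueError("top_k_genes must be >= 4 (four tiers)")
        if self.activity_window < 1:
            raise ValueError("activity_window must be >= 1")


@dataclass
class ImportanceLedger:
    reaction_importance: dict[str, float]
    spearman_rho: dict[str, float]
    constant_features: set[str] = field(default_factory=set)
    pathway: dict[str, tuple[float, float]] = field(default_factory=dict)
    gene_scores: dict[str, float] = field(default_factory=dict)
    family_scores: dict[str, float] = field(default_factory=dict)
    family_tiers: dict[str, str] = field(default_factory=dict)


def reaction_importance(model, fm: FeatureMatrix) -> dict[str, float]:
    """Impurity-decrease importances per feature, normalized to sum 1."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not a fitted forest")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return dict(zip(fm.feature_ids, map(float, imp)))


def spearman_vs_state(fm: FeatureMatrix) -> tuple[dict[str, float], set[str]]:
    """Spearman rho of each imputed flux column against the binary label
    (healthy=0, cancer=1); constant columns get rho=0 and are flagged."""
    y = fm.label_vector()
    rhos: dict[str, float] = {}
    constant: set[str] = set()
    for col in fm.feature_ids:
        x = fm.values[col].to_numpy()
        if np.all(x == x[0]):
            rhos[col] = 0.0
            constant.add(col)
            continue
        rho = spearmanr(x, y).statistic
        rhos[col] = float(rho) if math.isfinite(rho) else 0.0
    return rhos, constant


def pathway_importance(
    importances: dict[str, float], net: MetabolicNetwork
) -> dict[str, tuple[float, float]]:
    """pathway -> (mean importance over member reactions in the feature
    union, share % normalized over reported pathways)."""
    members: dict[str, list[float]] = {}
    subsystem = {r.id: (r.subsystem or "Unassigned") for r in net.reactions}
    for rxn, imp in importances.items():
        members.setdefault(subsystem.get(rxn, "Unassigned"), []).append(imp)
    means = {p: float(np.mean(v)) for p, v in members.items()}
    total = sum(means.values())
    return {
        p: (m, 100.0 * m / total if total > 0 else 0.0) for p, m in means.items()
    }


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def sigmoid_weight(n_reactions: int, k: float, n0: float) -> float:
    """Gene weight in (0.5, 1): 0.5 + 0.5 * sigmoid(k (n - n0))."""
    return 0.5 + 0.5 * _logistic(k * (n_reactions - n0))


def gene_importance(
    importances: dict[str, float],
    net: MetabolicNetwork,
    cfg: ImportanceConfig = ImportanceConfig(),
    family_map: dict[str, str] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Gene scores raw(g) * weight(g) and the family rollup (sum over member
    genes; a gene maps to itself when absent from the family map)."""
    reaction_sets: dict[str, set[str]] = {}
    for r in net.reactions:
        if r.gpr is None:
            continue
        for g in r.gpr.genes():
            reaction_sets.setdefault(g, set()).add(r.id)

    counts = [len(s) for s in reaction_sets.values()]
    n0 = cfg.sigmoid_n0 if cfg.sigmoid_n0 is not None else float(np.median(counts))

    scores: dict[str, float] = {}
    for g, rxns in reaction_sets.items():
        raw = sum(importances.get(r, 0.0) for r in rxns)
        scores[g] = raw * sigmoid_weight(len(rxns), cfg.sigmoid_k, n0)

    family_map = family_map or {}
    for g in family_map:
        if g not in reaction_sets:
            scores.setdefault(g, 0.0)
    families: dict[str, float] = {}
    for g, s in scores.items():
        fam = family_map.get(g, g)
        families[fam] = families.get(fam, 0.0) + s
    return scores, families


def tier_genes(scores: dict[str, float], top_k: int = 15) -> dict[str, str]:
    """Quartile tiers over the top_k scores (type-7 quantiles); a score on a
    boundary takes the higher tier."""
    if len(scores) < 4:
        raise ValueError("need >= 4 scored families to tier")
    top = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    vals = np.array([v for _, v in top])
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    tiers = {}
    for name, v in top:
        if v >= q3:
            tiers[name] = "Very High"
        elif v >= q2:
            tiers[name] = "High"
        elif v >= q1:
            tiers[name] = "Medium"
        else:
            tiers[name] = "Low"
    return tiers


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def cluster_reactions(
    fm: FeatureMatrix,
    importances: dict[str, float],
    top_n: int = 70,
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage clustering of the top_n reactions by importance under
    the distance 1 - |Spearman rho| between imputed flux columns.

    Returns (scipy linkage matrix, leaf reaction ids, Newick string).
    """
    ranked = sorted(
        (r for r in fm.feature_ids),
        key=lambda r: (-importances.get(r, 0.0), r),
    )
    top = sorted(ranked[: min(top_n, len(ranked))])
    X = fm.values[top].to_numpy()
    n = len(top)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[:, i], X[:, j]
            if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                rho = 0.0
            else:
                rho = spearmanr(xi, xj).statistic
                if not math.isfinite(rho):
                    rho = 0.0
            dist[i, j] = dist[j, i] = 1.0 - abs(rho)
    Z = average_linkage(squareform(dist, checks=False))
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)
    newick = _newick(tree, top) + ";"
    return Z, top, newick


# ---------------------------------------------------------------------------
# flux activity summaries
# ---------------------------------------------------------------------------

def flux_activity_summary(
    fm: FeatureMatrix,
    reaction_id: str,
    cfg: ImportanceConfig = ImportanceConfig(),
) -> dict[str, dict[str, list[float]]]:
    """Per class (stable input order): trailing rolling mean of the imputed
    flux (window truncated at the start) and the activity ratio — the
    fraction of samples in the window with |flux| > activity_tol."""
    if reaction_id not in fm.feature_ids:
        raise KeyError(f"reaction {reaction_id!r} not in the feature union")
    out: dict[str, dict[str, list[float]]] = {}
    col = fm.values[reaction_id]
    for label in sorted(set(fm.labels.values())):
        samples = [s for s in fm.sample_ids if fm.labels[s] == label]
        x = col.loc[samples]
        rolling = x.rolling(cfg.activity_window, min_periods=1).mean()
        active = (x.abs() > cfg.activity_tol).astype(float)
        ratio = active.rolling(cfg.activity_window, min_periods=1).mean()
        out[label] = {
            "samples": samples,
            "rolling_mean": [float(v) for v in rolling],
            "activity_ratio": [float(v) for v in ratio],
        }
    return out


def build_ledger(
    model,
    fm: FeatureMatrix,
    net: MetabolicNetwork,
    cfg: ImportanceConfig = ImportanceConfig(),
    family_map: dict[str, str] | None = None,
) -> ImportanceLedger:
    """Full multi-level rollup for a fitted forest."""
    imp = reaction_importance(model, fm)
    rhos, constant = spearman_vs_state(fm)
    pathways = pathway_importance(imp, net)
    genes, families = gene_importance(imp, net, cfg, family_map)
    tiers = tier_genes(families, cfg.top_k_genes) if len(families) >= 4 else {}
    return ImportanceLedger(
        reaction_importance=imp,
        spearman_rho=rhos,
        constant_features=constant,
        pathway=pathways,
        gene_scores=genes,
        family_scores=families,
        family_tiers=tiers,
    )
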