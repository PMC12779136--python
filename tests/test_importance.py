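"""Multi-level importance: reactions, pathways, genes/families, clustering,
rolling flux-activity summaries."""

import numpy as np
import pandas as pd
import pytest

from fluxgan.classify import FeatureMatrix, RFConfig, train_rf
from fluxgan.core_model import Metabolite, MetabolicNetwork, Reaction
from fluxgan.gpr import parse_gpr
from fluxgan.importance import (
    ImportanceConfig,
    cluster_reactions,
    flux_activity_summary,
    gene_importance,
    pathway_importance,
    reaction_importance,
    sigmoid_weight,
    spearman_vs_state,
    tier_genes,
)


def matrix_from(X, y, prefix="R"):
    samples = [f"s{i}" for i in range(len(y))]
    labels = {s: ("healthy" if yi == 0 else "cancer") for s, yi in zip(samples, y)}
    values = pd.DataFrame(X, index=samples, columns=[f"{prefix}{j}" for j in range(X.shape[1])])
    return FeatureMatrix(values=values, labels=labels)


# ---------------------------------------------------------------------------
# reaction importance
# ---------------------------------------------------------------------------

def test_single_informative_feature_dominates():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 10))
        X[:, 4] = y * 3 + rng.normal(scale=0.2, size=60)
        fm = matrix_from(X, y)
        model, _ = train_rf(fm, RFConfig(seed=seed))
        imp = reaction_importance(model, fm)
        assert max(imp, key=imp.get) == "R4"
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)


def test_pure_noise_importances_are_flat():
    rng = np.random.default_rng(7)
    y = np.repeat([0, 1], 40)
    X = rng.normal(size=(80, 200))
    fm = matrix_from(X, y)
    model, _ = train_rf(fm, RFConfig(seed=7))
    imp = np.array(list(reaction_importance(model, fm).values()))
    assert imp.max() < 8 * imp.mean()  # flatness bound frozen after pilot runs


def test_untrained_model_rejected():
    fm = matrix_from(np.zeros((4, 2)), np.array([0, 0, 1, 1]))
    with pytest.raises(ValueError):
        reaction_importance(object(), fm)


# ---------------------------------------------------------------------------
# Spearman correlation against the class label
# ---------------------------------------------------------------------------

def max_attainable_binary_rho(n_per_class):
    """Brute ranking oracle: rho between a perfectly separating continuous
    feature and the binary label at equal group sizes."""
    from scipy.stats import spearmanr

    x = np.arange(2 * n_per_class, dtype=float)  # strictly increasing
    y = np.repeat([0, 1], n_per_class)
    return spearmanr(x, y).statistic


def test_perfectly_separating_feature_hits_binary_maximum():
    n = 5
    y = np.repeat([0, 1], n)
    X = np.zeros((2 * n, 2))
    X[:, 0] = np.arange(2 * n)  # strictly higher in every cancer sample
    X[:, 1] = 1.0  # constant column
    fm = matrix_from(X, y)
    rhos, constant = spearman_vs_state(fm)
    assert rhos["R0"] == pytest.approx(max_attainable_binary_rho(n))
    assert 0.86 < rhos["R0"] < 0.88  # ~sqrt(3/4) for equal binary groups
    assert rhos["R1"] == 0.0 and "R1" in constant


def test_independent_feature_has_small_rho():
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 40)
    X = rng.normal(size=(80, 50))
    fm = matrix_from(X, y)
    rhos, _ = spearman_vs_state(fm)
    assert max(abs(v) for v in rhos.values()) < 0.4  # 99% permutation bound


# ---------------------------------------------------------------------------
# pathway aggregation
# ---------------------------------------------------------------------------

def two_pathway_net():
    mets = [Metabolite("a_c", compartment="c")]
    rxns = [
        Reaction("R_A1", {"a_c": 1}, 0, 10, subsystem="PathA", gpr=parse_gpr("GA")),
        Reaction("R_B1", {"a_c": -1}, 0, 10, subsystem="PathB", gpr=parse_gpr("GB1")),
        Reaction("R_B2", {"a_c": -1}, 0, 10, subsystem="PathB", gpr=parse_gpr("GB1 or GB2")),
    ]
    return MetabolicNetwork(id="p", metabolites=mets, reactions=rxns, objective_reaction="R_A1")


def test_pathway_means_and_shares():
    net = two_pathway_net()
    shares = pathway_importance({"R_A1": 0.07}, net)
    assert shares["PathA"] == (pytest.approx(0.07), pytest.approx(100.0))
    # two pathways with means 0.03 and 0.01 -> shares 75 / 25
    shares = pathway_importance({"R_A1": 0.03, "R_B1": 0.012, "R_B2": 0.008}, net)
    assert shares["PathA"][0] == pytest.approx(0.03)
    assert shares["PathB"][0] == pytest.approx(0.01)
    assert shares["PathA"][1] == pytest.approx(75.0)
    assert shares["PathB"][1] == pytest.approx(25.0)
    assert sum(s for _, s in shares.values()) == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# gene scores, families, tiers
# ---------------------------------------------------------------------------

def test_sigmoid_weight_midpoint_and_monotonicity():
    assert sigmoid_weight(3, k=1.0, n0=3.0) == pytest.approx(0.75)
    assert 0.5 < sigmoid_weight(1, 1.0, 3.0) < sigmoid_weight(20, 1.0, 3.0) < 1.0


def test_gene_scores_roll_up_through_gprs():
    net = two_pathway_net()
    imp = {"R_A1": 0.5, "R_B1": 0.3, "R_B2": 0.2}
    scores, families = gene_importance(imp, net, ImportanceConfig(sigmoid_n0=1.0))
    # GB1 sits on two reactions: raw 0.5, weight sigmoid(k*(2-1))
    assert scores["GB1"] == pytest.approx(0.5 * sigmoid_weight(2, 1.0, 1.0))
    assert scores["GB2"] == pytest.approx(0.2 * sigmoid_weight(1, 1.0, 1.0))
    assert families["GB1"] == scores["GB1"]  # identity rollup by default
    _, fam2 = gene_importance(imp, net, ImportanceConfig(sigmoid_n0=1.0),
                              family_map={"GB1": "GB", "GB2": "GB"})
    assert fam2["GB"] == pytest.approx(scores["GB1"] + scores["GB2"])


def test_zero_raw_score_stays_zero():
    net = two_pathway_net()
    scores, _ = gene_importance({"R_A1": 0.0}, net)
    assert scores["GA"] == 0.0


def test_tiering_quartiles_of_one_to_fifteen():
    scores = {f"F{i:02d}": float(i) for i in range(1, 16)}
    tiers = tier_genes(scores, top_k=15)
    very_high = {f for f, t in tiers.items() if t == "Very High"}
    assert very_high == {"F12", "F13", "F14", "F15"}  # Q3 = 11.5
    assert tiers["F01"] == "Low"


def test_tiering_tie_and_small_cases():
    tiers = tier_genes({f"F{i}": 2.0 for i in range(8)}, top_k=8)
    assert set(tiers.values()) == {"Very High"}  # ties take the higher tier
    tiers = tier_genes({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}, top_k=4)
    assert [tiers[k] for k in "abcd"] == ["Very High", "High", "Medium", "Low"]
    with pytest.raises(ValueError):
        tier_genes({"a": 1.0, "b": 2.0}, top_k=4)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_correlated_columns_merge_first():
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 20)
    base = rng.normal(size=40)
    X = np.column_stack([base, base * 2 + 1e-9 * rng.normal(size=40), rng.normal(size=40)])
    fm = matrix_from(X, y)
    imp = {"R0": 0.5, "R1": 0.3, "R2": 0.2}
    Z, leaves, newick = cluster_reactions(fm, imp, top_n=3)
    assert len(leaves) == 3
    # first merge joins the perfectly correlated pair at distance ~0
    first = sorted(int(Z[0, i]) for i in (0, 1))
    assert [leaves[i] for i in first] == ["R0", "R1"]
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-6)
    # the Newick string parses and carries the right leaf set
    skbio = pytest.importorskip("skbio")
    tree = skbio.TreeNode.read([newick])
    assert {t.name for t in tree.tips()} == {"R0", "R1", "R2"}


def test_clustering_invariant_to_column_order():
    rng = np.random.default_rng(3)
    y = np.repeat([0, 1], 15)
    X = rng.normal(size=(30, 6))
    fm = matrix_from(X, y)
    imp = {f"R{j}": 1.0 / (j + 1) for j in range(6)}
    _, _, newick_a = cluster_reactions(fm, imp, top_n=6)
    perm = ["R3", "R0", "R5", "R1", "R4", "R2"]
    fm2 = FeatureMatrix(values=fm.values[perm], labels=dict(fm.labels))
    _, _, newick_b = cluster_reactions(fm2, imp, top_n=6)
    assert newick_a == newick_b  # leaves sorted, distances identical


# ---------------------------------------------------------------------------
# rolling flux activity
# ---------------------------------------------------------------------------

def activity_fixture(values, label="cancer"):
    y = np.ones(len(values), dtype=int)
    fm = matrix_from(np.array(values)[:, None], y)
    return fm


def test_activity_hand_windowing():
    fm = activity_fixture([0.0, 0.0, 5.0, 5.0, 5.0])
    out = flux_activity_summary(fm, "R0", ImportanceConfig(activity_window=2))
    assert out["cancer"]["activity_ratio"] == [0.0, 0.0, 0.5, 1.0, 1.0]
    assert out["cancer"]["rolling_mean"] == [0.0, 0.0, 2.5, 5.0, 5.0]


@pytest.mark.parametrize("values,expected", [([0.0] * 5, 0.0), ([2.0] * 5, 1.0)])
def test_activity_constant_series(values, expected):
    fm = activity_fixture(values)
    out = flux_activity_summary(fm, "R0", ImportanceConfig(activity_window=10))
    assert set(out["cancer"]["activity_ratio"]) == {expected}


def test_activity_unknown_reaction():
    fm = activity_fixture([1.0, 2.0])
    with pytest.raises(KeyError):
        flux_activity_summary(fm, "NOPE")
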