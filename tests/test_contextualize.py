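"""GPR mapping, discretization, iMAT (vs brute-force oracle), FBA, rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

import fluxgan as fg
from fluxgan.contextualize import (
    ContextModel,
    DiscretizationConfig,
    IMATConfig,
    ReactionExpressionVector,
    TernaryStateVector,
    contextualize_sample,
    discretize,
    imat_extract,
    imat_objective_value,
    map_expression_to_reactions,
    production_rate,
    run_fba,
)
from fluxgan.core_model import Metabolite, MetabolicNetwork, Reaction
from fluxgan.expression import ExpressionMatrix
from fluxgan.gpr import parse_gpr


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def mini_net(reactions, metabolites, objective):
    return MetabolicNetwork(
        id="mini", metabolites=metabolites, reactions=reactions, objective_reaction=objective
    )


def chain_network(n_internal=4, cap=10.0):
    """EX_in -> M1 -> M2 -> ... -> Mn -> BIOMASS sink chain."""
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(1, n_internal + 1)]
    rxns = [Reaction("EX_in", {"m1_c": -1}, -cap, 0, is_exchange=True)]
    for i in range(1, n_internal):
        rxns.append(Reaction(f"R{i}", {f"m{i}_c": -1, f"m{i+1}_c": 1}, 0, 1000))
    rxns.append(Reaction("BIOMASS", {f"m{n_internal}_c": -1}, 0, 1000))
    return mini_net(rxns, mets, "BIOMASS")


def imat_bruteforce(net, states, eps=1.0):
    """Enumeration oracle: every R_H reaction is off / forced forward /
    forced reverse, every R_L reaction free / pinned to zero; maximize the
    satisfied-state count over LP-feasible combinations."""
    rxn_ids = net.reaction_ids()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    lb = np.array([r.lower_bound for r in net.reactions], float)
    ub = np.array([r.upper_bound for r in net.reactions], float)
    S = net.stoichiometric_matrix()
    R_H = [r for r in rxn_ids if states.get(r, 0) == 1]
    R_L = [r for r in rxn_ids if states.get(r, 0) == -1]
    best = 0
    for h_modes in itertools.product(("off", "fwd", "rev"), repeat=len(R_H)):
        for l_modes in itertools.product((False, True), repeat=len(R_L)):
            score = sum(m != "off" for m in h_modes) + sum(l_modes)
            if score <= best:
                continue
            l2, u2 = lb.copy(), ub.copy()
            for r, mode in zip(R_H, h_modes):
                j = idx[r]
                if mode == "fwd":
                    l2[j] = max(l2[j], eps)
                elif mode == "rev":
                    u2[j] = min(u2[j], -eps)
            for r, pin in zip(R_L, l_modes):
                if pin:
                    l2[idx[r]] = u2[idx[r]] = 0.0
            if np.any(l2 > u2):
                continue
            res = linprog(
                np.zeros(len(rxn_ids)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(l2, u2)), method="highs",
            )
            if res.status == 0:
                best = score
    return float(best)


def random_small_network(rng):
    n_mets = rng.integers(2, 5)
    n_rxns = rng.integers(4, 9)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        size = rng.integers(1, min(3, n_mets) + 1)
        chosen = rng.choice(n_mets, size=size, replace=False)
        stoich = {f"m{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen}
        reversible = rng.random() < 0.4
        rxns.append(
            Reaction(
                f"r{j}", stoich,
                lower_bound=-10.0 if reversible else 0.0,
                upper_bound=10.0,
                is_exchange=len(stoich) == 1,
            )
        )
    net = mini_net(rxns, mets, "r0")
    states = {}
    hi = rng.choice(n_rxns, size=min(3, n_rxns), replace=False)
    lo = [j for j in rng.choice(n_rxns, size=min(3, n_rxns), replace=False) if j not in hi]
    for j in hi:
        states[f"r{j}"] = 1
    for j in lo[:3]:
        states[f"r{j}"] = -1
    return net, states


# ---------------------------------------------------------------------------
# expression -> reaction mapping
# ---------------------------------------------------------------------------

def expr_matrix(values_by_gene):
    df = pd.DataFrame({"S1": values_by_gene})
    return ExpressionMatrix(values=df, labels={"S1": "healthy"})


def gpr_net(gpr_text):
    mets = [Metabolite("a_c", compartment="c")]
    rxns = [
        Reaction("EX_a", {"a_c": -1}, -10, 0, is_exchange=True),
        Reaction("R1", {"a_c": -1}, 0, 10, gpr=parse_gpr(gpr_text)),
    ]
    return mini_net(rxns, mets, "R1")


@pytest.mark.parametrize(
    "gpr,levels,expected",
    [
        ("A or B", {"A": 5.0, "B": 2.0}, 5.0),
        ("A and B", {"A": 5.0, "B": 2.0}, 2.0),
        ("A and B", {"A": 5.0}, 5.0),  # absent operand skipped
    ],
)
def test_gpr_mapping_rules(gpr, levels, expected):
    net = gpr_net(gpr)
    m = expr_matrix(levels)
    vec = map_expression_to_reactions(m, net, "S1")
    assert vec.levels["R1"] == expected
    assert "EX_a" in vec.unmapped  # no GPR -> unmapped


def test_all_absent_gpr_is_unmapped():
    vec = map_expression_to_reactions(expr_matrix({"Z": 1.0}), gpr_net("A and B"), "S1")
    assert "R1" in vec.unmapped


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_hand_example():
    vec = ReactionExpressionVector(
        "S1", {f"r{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 10.0])}, {"u1"}
    )
    states = discretize(vec)
    assert states.states == {"r0": -1, "r1": -1, "r2": 0, "r3": 0, "r4": 1, "u1": 0}


def test_discretize_constant_vector_all_zero():
    vec = ReactionExpressionVector("S1", {"r0": 2.0, "r1": 2.0, "r2": 2.0}, set())
    assert set(discretize(vec).states.values()) == {0}


def test_discretize_zero_multiplier_limit():
    vec = ReactionExpressionVector("S1", {"r0": 1.0, "r1": 2.0, "r2": 3.0}, set())
    states = discretize(vec, DiscretizationConfig(sd_multiplier=0.0))
    assert states.states == {"r0": -1, "r1": 0, "r2": 1}


def test_discretize_high_fraction_matches_gaussian_tail():
    rng = np.random.default_rng(0)
    vec = ReactionExpressionVector(
        "S1", {f"r{i}": float(v) for i, v in enumerate(rng.normal(size=100_000))}, set()
    )
    states = discretize(vec)
    frac_high = np.mean([s == 1 for s in states.states.values()])
    from scipy.stats import norm

    assert abs(frac_high - norm.sf(0.3)) < 0.01  # P(Z > 0.3) ~ 0.382


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def test_imat_chain_all_high_fully_active():
    net = chain_network()
    states = TernaryStateVector("S1", {r: 1 for r in net.reaction_ids() if r != "EX_in"})
    assert imat_objective_value(net, states) == pytest.approx(4.0)
    cm = imat_extract(net, states)
    assert {"R1", "R2", "R3", "BIOMASS"} <= cm.active_reactions


def test_imat_low_reaction_on_only_path_is_sacrificed():
    net = chain_network()
    states = {r: 1 for r in net.reaction_ids() if r != "EX_in"}
    states["R2"] = -1  # silencing R2 would cut the only path
    t = TernaryStateVector("S1", states)
    assert imat_objective_value(net, t) == pytest.approx(3.0)  # |R_H| wins


def test_imat_empty_states_trivial():
    net = chain_network()
    t = TernaryStateVector("S1", {})
    assert imat_objective_value(net, t) == pytest.approx(0.0)
    cm = imat_extract(net, t)
    assert "BIOMASS" in cm.active_reactions  # objective always retained


def test_imat_matches_bruteforce_oracle_on_random_networks():
    rng = np.random.default_rng(42)
    trials = 0
    while trials < 50:
        net, states = random_small_network(rng)
        t = TernaryStateVector("S1", states)
        milp_obj = imat_objective_value(net, t)
        oracle = imat_bruteforce(net, states)
        assert milp_obj == pytest.approx(oracle, abs=1e-6), (
            f"trial {trials}: MILP {milp_obj} vs oracle {oracle}"
        )
        trials += 1


def test_imat_invalid_config():
    with pytest.raises(ValueError):
        IMATConfig(epsilon=1.0, activity_tol=2.0)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_fba_capacity_limited_chain():
    net = chain_network(n_internal=3, cap=10.0)
    cm = ContextModel("S1", net.id, set(net.reaction_ids()), net)
    fp = run_fba(cm)
    assert fp.objective_value == pytest.approx(10.0, abs=1e-6)
    assert fp.fluxes["R1"] == pytest.approx(10.0, abs=1e-6)
    assert fp.fluxes["R2"] == pytest.approx(10.0, abs=1e-6)


def test_fba_parallel_paths_resolved_to_minimal_total_flux():
    mets = [
        Metabolite("a_c", compartment="c"),
        Metabolite("b_c", compartment="c"),
        Metabolite("c_c", compartment="c"),
    ]
    rxns = [
        Reaction("EX_a", {"a_c": -1}, -10, 0, is_exchange=True),
        Reaction("P1", {"a_c": -1, "b_c": 1}, 0, 1000),
        # redundant two-step detour: same conversion, twice the flux
        Reaction("P2a", {"a_c": -1, "c_c": 1}, 0, 1000),
        Reaction("P2b", {"c_c": -1, "b_c": 1}, 0, 1000),
        Reaction("BIOMASS", {"b_c": -1}, 0, 1000),
    ]
    net = mini_net(rxns, mets, "BIOMASS")
    cm = ContextModel("S1", net.id, set(net.reaction_ids()), net)
    fp = run_fba(cm)
    total = sum(abs(v) for v in fp.fluxes.values())
    # independent check: single-path routing gives |EX|+|P1|+|BIOMASS| = 30
    assert fp.objective_value == pytest.approx(10.0, abs=1e-6)
    assert total == pytest.approx(30.0, abs=1e-6)


def test_fba_is_invariant_to_reaction_order(toy_net):
    rng = np.random.default_rng(5)
    cm = ContextModel("S1", toy_net.id, set(toy_net.reaction_ids()), toy_net)
    base = run_fba(cm)
    order = rng.permutation(len(toy_net.reactions))
    shuffled = MetabolicNetwork(
        id=toy_net.id,
        metabolites=list(toy_net.metabolites),
        reactions=[toy_net.reactions[i] for i in order],
        objective_reaction=toy_net.objective_reaction,
    )
    cm2 = ContextModel("S1", shuffled.id, set(shuffled.reaction_ids()), shuffled)
    fp2 = run_fba(cm2)
    assert abs(fp2.objective_value - base.objective_value) < 1e-8


def test_flux_profiles_satisfy_mass_balance(toy_net, toy_cohort):
    S = toy_net.stoichiometric_matrix()
    rxn_ids = toy_net.reaction_ids()
    for cm, fp in toy_cohort["models"][:10]:
        v = np.array([fp.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) < 1e-6


def test_end_to_end_sample_runs(toy_net, toy_cohort):
    m = toy_cohort["expr"]
    cm, fp = contextualize_sample(m, toy_net, m.sample_ids[0])
    assert cm.sample_id == m.sample_ids[0]
    assert toy_net.objective_reaction in cm.active_reactions


# ---------------------------------------------------------------------------
# production rates
# ---------------------------------------------------------------------------

def rate_net():
    mets = [Metabolite("atp_c", "ATP", "c"), Metabolite("x_c", compartment="c")]
    rxns = [
        Reaction("MAKE", {"x_c": -1, "atp_c": 2}, -10, 10),
        Reaction("BURN", {"atp_c": -1}, 0, 10),
        Reaction("EX_x", {"x_c": -1}, -10, 10, is_exchange=True),
    ]
    return mini_net(rxns, mets, "BURN")


def test_production_rate_gross_sum():
    net = rate_net()
    fp = fg.FluxProfile("S1", {"MAKE": 3.0, "BURN": 6.0, "EX_x": -3.0}, 6.0)
    assert production_rate(fp, net, "ATP") == pytest.approx(6.0)  # 2 * 3


def test_production_rate_ignores_consumption():
    net = rate_net()
    fp = fg.FluxProfile("S1", {"MAKE": 3.0, "BURN": 6.0, "EX_x": -3.0}, 6.0)
    # BURN consumes 6 ATP but gross production stays 6
    assert production_rate(fp, net, "ATP") == pytest.approx(6.0)


def test_production_rate_reversible_flux_sign():
    mets = [Metabolite("atp_c", "ATP", "c"), Metabolite("x_c", compartment="c")]
    rxns = [
        Reaction("REV", {"atp_c": -1, "x_c": 1}, -10, 10),
        Reaction("EX_x", {"x_c": -1}, -10, 10, is_exchange=True),
    ]
    net = mini_net(rxns, mets, "REV")
    fp = fg.FluxProfile("S1", {"REV": -4.0, "EX_x": 4.0}, 0.0)
    # coefficient -1 at flux -4 produces ATP at rate 4
    assert production_rate(fp, net, "ATP") == pytest.approx(4.0)


def test_production_rate_unknown_base_errors(toy_net):
    fp = fg.FluxProfile("S1", {}, 0.0)
    with pytest.raises(ValueError, match="NOBASE"):
        production_rate(fp, toy_net, "NOBASE")
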