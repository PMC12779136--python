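"""Per-sample context-specific model extraction and flux prediction.

Pipeline stage: expression -> reaction levels (GPR: AND=min, OR=max) ->
ternary states (mean +/- 0.3*SD within the sample) -> iMAT MILP (activate
highly expressed reactions above epsilon, silence lowly expressed ones) ->
context model -> FBA (biomass maximization, with a secondary total-flux
minimization so alternate optima resolve deterministically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .core_model import MetabolicNetwork, Reaction
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ReactionExpressionVector:
    """Continuous per-reaction expression for one sample; reactions whose
    GPR genes are entirely absent from the data are unmapped."""

    sample_id: str
    levels: dict[str, float]
    unmapped: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class DiscretizationConfig:
    sd_multiplier: float = 0.3

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


@dataclass
class TernaryStateVector:
    sample_id: str
    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {r: s for r, s in self.states.items() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"states outside {{-1,0,1}}: {bad}")

    def high(self) -> list[str]:
        return [r for r, s in self.states.items() if s == 1]

    def low(self) -> list[str]:
        return [r for r, s in self.states.items() if s == -1]


@dataclass(frozen=True)
class IMATConfig:
    epsilon: float = 1.0
    activity_tol: float = 1e-6
    mip_gap: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.activity_tol < self.epsilon):
            raise ValueError("need 0 < activity_tol < epsilon")


@dataclass
class ContextModel:
    sample_id: str
    parent_id: str
    active_reactions: set[str]
    network: MetabolicNetwork  # inactive reactions bound to (0, 0)


@dataclass
class FluxProfile:
    sample_id: str
    fluxes: dict[str, float]
    objective_value: float

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


class InfeasibleModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# expression -> reaction levels -> ternary states
# ---------------------------------------------------------------------------

def map_expression_to_reactions(
    m: ExpressionMatrix, net: MetabolicNetwork, sample_id: str
) -> ReactionExpressionVector:
    """Evaluate each reaction's GPR against one sample (AND=min, OR=max;
    absent genes are skipped, an all-absent GPR leaves the reaction unmapped)."""
    levels_by_gene = m.sample(sample_id)
    levels: dict[str, float] = {}
    unmapped: set[str] = set()
    for r in net.reactions:
        if r.gpr is None:
            unmapped.add(r.id)
            continue
        value = r.gpr.evaluate(levels_by_gene)
        if value is None:
            unmapped.add(r.id)
        else:
            levels[r.id] = float(value)
    return ReactionExpressionVector(sample_id=sample_id, levels=levels, unmapped=unmapped)


def discretize(
    v: ReactionExpressionVector, cfg: DiscretizationConfig = DiscretizationConfig()
) -> TernaryStateVector:
    """Ternary states from within-sample statistics: +1 above mean + k*SD,
    -1 below mean - k*SD, else 0; unmapped reactions are 0."""
    if len(v.levels) < 2:
        raise ValueError("need >= 2 mapped reactions to discretize")
    values = np.array(list(v.levels.values()))
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    states = {r: 0 for r in v.unmapped}
    if sd == 0.0:
        log.warning("sample %s: constant reaction expression, all states 0", v.sample_id)
        states.update({r: 0 for r in v.levels})
        return TernaryStateVector(sample_id=v.sample_id, states=states)
    hi = mu + cfg.sd_multiplier * sd
    lo = mu - cfg.sd_multiplier * sd
    for r, x in v.levels.items():
        states[r] = 1 if x > hi else (-1 if x < lo else 0)
    return TernaryStateVector(sample_id=v.sample_id, states=states)


# ---------------------------------------------------------------------------
# iMAT MILP
# ---------------------------------------------------------------------------

def _solve_imat(
    net: MetabolicNetwork, t: TernaryStateVector, cfg: IMATConfig
) -> tuple[np.ndarray, float]:
    """Solve the iMAT MILP; returns (flux vector, agreement objective).

    maximize sum_{i in R_H} (y+_i + y-_i) + sum_{i in R_L} y0_i
    s.t.  S v = 0,  lb <= v <= ub,
          i in R_H:  v_i + y+_i (lb_i - eps) >= lb_i,
                     v_i + y-_i (ub_i + eps) <= ub_i,
          i in R_L:  lb_i (1 - y0_i) <= v_i <= ub_i (1 - y0_i).
    """
    rxn_ids = net.reaction_ids()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    R_H = [r for r in rxn_ids if t.states.get(r, 0) == 1]
    R_L = [r for r in rxn_ids if t.states.get(r, 0) == -1]
    nH, nL = len(R_H), len(R_L)
    eps = cfg.epsilon

    lb = np.array([r.lower_bound for r in net.reactions])
    ub = np.array([r.upper_bound for r in net.reactions])

    # variables: [v (n), y+ (nH), y- (nH), y0 (nL)]
    nvar = n + 2 * nH + nL
    c = np.zeros(nvar)
    c[n:] = -1.0  # maximize agreement

    S = sparse.csr_matrix(net.stoichiometric_matrix())
    blocks = [sparse.hstack([S, sparse.csr_matrix((S.shape[0], 2 * nH + nL))])]
    con_lb = [np.zeros(S.shape[0])]
    con_ub = [np.zeros(S.shape[0])]

    rows_A, cols_A, vals_A, a_lb, a_ub = [], [], [], [], []
    row = 0
    for k, r in enumerate(R_H):
        j = idx[r]
        # v + y+ (lb - eps) >= lb
        rows_A += [row, row]
        cols_A += [j, n + k]
        vals_A += [1.0, lb[j] - eps]
        a_lb.append(lb[j])
        a_ub.append(np.inf)
        row += 1
        # v + y- (ub + eps) <= ub
        rows_A += [row, row]
        cols_A += [j, n + nH + k]
        vals_A += [1.0, ub[j] + eps]
        a_lb.append(-np.inf)
        a_ub.append(ub[j])
        row += 1
    for k, r in enumerate(R_L):
        j = idx[r]
        # v + lb*y0 >= lb  and  v + ub*y0 <= ub
        rows_A += [row, row]
        cols_A += [j, n + 2 * nH + k]
        vals_A += [1.0, lb[j]]
        a_lb.append(lb[j])
        a_ub.append(np.inf)
        row += 1
        rows_A += [row, row]
        cols_A += [j, n + 2 * nH + k]
        vals_A += [1.0, ub[j]]
        a_lb.append(-np.inf)
        a_ub.append(ub[j])
        row += 1

    constraints = [LinearConstraint(blocks[0], con_lb[0], con_ub[0])]
    if row:
        A = sparse.csr_matrix((vals_A, (rows_A, cols_A)), shape=(row, nvar))
        constraints.append(LinearConstraint(A, np.array(a_lb), np.array(a_ub)))

    var_lb = np.concatenate([lb, np.zeros(2 * nH + nL)])
    var_ub = np.concatenate([ub, np.ones(2 * nH + nL)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nH + nL)])

    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
        options={"mip_rel_gap": cfg.mip_gap},
    )
    if not res.success:
        raise InfeasibleModelError(
            f"iMAT MILP failed for sample {t.sample_id!r}: {res.message}"
        )
    agreement = float(-res.fun)

    # The MILP optimum is generally degenerate in v: many flux vectors attain
    # the same agreement.  To make the extracted context reproducible and
    # functionally meaningful, fix the binary states and resolve the flux
    # degeneracy deterministically: first maximize the objective (biomass)
    # flux, then minimize total flux at that optimum.  With fixed binaries
    # the big-M rows reduce to tightened variable bounds.
    y = np.round(res.x[n:]).astype(int)
    lb2, ub2 = lb.copy(), ub.copy()
    for k, r in enumerate(R_H):
        j = idx[r]
        if y[k] == 1:  # forced active, forward
            lb2[j] = max(lb2[j], eps)
        if y[nH + k] == 1:  # forced active, reverse
            ub2[j] = min(ub2[j], -eps)
    for k, r in enumerate(R_L):
        j = idx[r]
        if y[2 * nH + k] == 1:  # silenced
            lb2[j] = ub2[j] = 0.0
    j_obj = idx[net.objective_reaction]
    v = _biomass_then_minflux(S, lb2, ub2, j_obj)
    if v is None:
        raise InfeasibleModelError(
            f"iMAT flux resolution failed for sample {t.sample_id!r}"
        )
    return v, agreement


def imat_extract(
    net: MetabolicNetwork,
    t: TernaryStateVector,
    cfg: IMATConfig = IMATConfig(),
) -> ContextModel:
    """Solve the iMAT MILP and reduce the network to its active reactions.

    The context model keeps reactions with |v| > activity_tol in the
    deterministically resolved optimum plus the objective reaction; all
    others get bounds (0, 0).
    """
    rxn_ids = net.reaction_ids()
    v, _ = _solve_imat(net, t, cfg)
    active = {r for j, r in enumerate(rxn_ids) if abs(v[j]) > cfg.activity_tol}
    active.add(net.objective_reaction)

    reduced = [
        r if r.id in active else r.with_bounds(0.0, 0.0) for r in net.reactions
    ]
    reduced_net = MetabolicNetwork(
        id=f"{net.id}::{t.sample_id}",
        metabolites=list(net.metabolites),
        reactions=reduced,
        objective_reaction=net.objective_reaction,
    )
    return ContextModel(
        sample_id=t.sample_id,
        parent_id=net.id,
        active_reactions=active,
        network=reduced_net,
    )


def imat_objective_value(
    net: MetabolicNetwork, t: TernaryStateVector, cfg: IMATConfig = IMATConfig()
) -> float:
    """Agreement score of the iMAT optimum (number of satisfied states)."""
    _, agreement = _solve_imat(net, t, cfg)
    return agreement


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def _solve_lp(c, A_eq, b_eq, bounds_list, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds_list,
        method="highs",
    )


def _biomass_then_minflux(S, lb, ub, j_obj, two_stage: bool = True):
    """Maximize v[j_obj] s.t. S v = 0 and bounds; then (optionally) minimize
    sum |v| at the pinned optimum.  Returns the flux vector or None."""
    n = S.shape[1]
    c = np.zeros(n)
    c[j_obj] = -1.0
    res = _solve_lp(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    if res.status != 0:
        return None
    if not two_stage:
        return res.x
    opt = float(res.x[j_obj])

    # min sum t with t >= v, t >= -v, objective flux pinned at its optimum
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    S2 = sparse.hstack([S, sparse.csr_matrix(S.shape)])
    I = sparse.identity(n, format="csr")
    A_ub = sparse.vstack([sparse.hstack([I, -I]), sparse.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    lb2, ub2 = np.array(lb, dtype=float), np.array(ub, dtype=float)
    lb2[j_obj] = max(lb2[j_obj], opt - 1e-9)
    bounds2 = list(zip(lb2, ub2)) + [(0.0, None)] * n
    res2 = _solve_lp(c2, S2, np.zeros(S.shape[0]), bounds2, A_ub=A_ub, b_ub=b_ub)
    if res2.status != 0:  # fall back to the single-stage solution
        return res.x
    return res2.x[:n]


def run_fba(cm: ContextModel, minimize_total_flux: bool = True) -> FluxProfile:
    """Maximize biomass on the retained network; a second stage minimizes
    sum |v| at the fixed optimum so profiles are reproducible."""
    net = cm.network
    rxn_ids = net.reaction_ids()
    S = sparse.csr_matrix(net.stoichiometric_matrix())
    lb = np.array([r.lower_bound for r in net.reactions])
    ub = np.array([r.upper_bound for r in net.reactions])
    j_obj = rxn_ids.index(net.objective_reaction)

    v = _biomass_then_minflux(S, lb, ub, j_obj, two_stage=minimize_total_flux)
    if v is None:
        raise InfeasibleModelError(f"FBA infeasible for sample {cm.sample_id!r}")
    return FluxProfile(cm.sample_id, dict(zip(rxn_ids, map(float, v))), float(v[j_obj]))


def contextualize_sample(
    m: ExpressionMatrix,
    net: MetabolicNetwork,
    sample_id: str,
    disc_cfg: DiscretizationConfig = DiscretizationConfig(),
    imat_cfg: IMATConfig = IMATConfig(),
) -> tuple[ContextModel, FluxProfile]:
    """Full per-sample chain: map -> discretize -> iMAT -> FBA."""
    vec = map_expression_to_reactions(m, net, sample_id)
    states = discretize(vec, disc_cfg)
    cm = imat_extract(net, states, imat_cfg)
    fp = run_fba(cm)
    return cm, fp


# ---------------------------------------------------------------------------
# production rates
# ---------------------------------------------------------------------------

def production_rate(
    fp: FluxProfile, net: MetabolicNetwork, metabolite_base: str
) -> float:
    """Gross production rate of a metabolite base (e.g. "ATP") summed over
    compartments: sum over reactions/metabolites of max(0, coeff * flux)."""
    base = metabolite_base.lower()
    matching = {
        m.id for m in net.metabolites if m.name.lower() == base or m.id.lower().startswith(base.lower() + "_")
    }
    if not matching:
        raise ValueError(f"no metabolite matches base {metabolite_base!r}")
    total = 0.0
    for r in net.reactions:
        v = fp.fluxes.get(r.id)
        if v is None:
            continue
        for met, coef in r.stoichiometry.items():
            if met in matching:
                total += max(0.0, coef * v)
    return total
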