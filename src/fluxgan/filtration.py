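"""Three-step biological validation of synthetic minority-class flux profiles.

Stage 1 (energy): ATP/NADH/NADPH gross production must fall inside the
envelope spanned by the real minority profiles (inclusive bounds).
Stage 2 (GDI): the Glycolysis Disorder Index — lactate secretion divided by
glucose uptake — must be zero (<= a numerical tolerance); a Warburg-like
positive GDI marks a cancer-like, hence invalid, "healthy" model.
Stage 3 (gluconeogenesis): flux through any gluconeogenesis marker reaction
in its gluconeogenic direction disqualifies the candidate, since the process
is ATP-consuming and typically absent in well-nourished cells.

Exchange fluxes follow the COBRA convention: negative = uptake,
positive = secretion; the GDI sign logic depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contextualize import FluxProfile
from .core_model import MetabolicNetwork

ENERGY_BASES = ("ATP", "NADH", "NADPH")


@dataclass(frozen=True)
class GDIConfig:
    lactate_exchange_id: str
    glucose_exchange_id: str
    zero_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.zero_tol <= 0:
            raise ValueError("zero_tol must be positive")


@dataclass
class HealthyReferenceEnvelope:
    """Per-metabolite-base (min, max) gross production over real profiles."""

    ranges: dict[str, tuple[float, float]]

    def contains(self, rates: dict[str, float]) -> str | None:
        """None if inside for every base, else the first failing base."""
        for base in ENERGY_BASES:
            lo, hi = self.ranges[base]
            if not (lo <= rates[base] <= hi):
                return base
        return None


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_removed: int
    n_out: int
    removed: dict[str, str] = field(default_factory=dict)  # sample -> reason

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_removed:
            raise ValueError("inconsistent filter report counts")

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_in if self.n_in else 0.0


def build_envelope(
    real_profiles: list[FluxProfile], net: MetabolicNetwork
) -> HealthyReferenceEnvelope:
    """Component-wise production-rate min/max over the real profiles."""
    from .contextualize import production_rate

    if not real_profiles:
        raise ValueError("cannot build an envelope from zero real profiles")
    ranges = {}
    for base in ENERGY_BASES:
        rates = [production_rate(fp, net, base) for fp in real_profiles]
        ranges[base] = (min(rates), max(rates))
    return HealthyReferenceEnvelope(ranges=ranges)


def filter_energy(
    cands: list[FluxProfile],
    env: HealthyReferenceEnvelope,
    net: MetabolicNetwork,
) -> tuple[list[FluxProfile], FilterReport]:
    from .contextualize import production_rate

    survivors, removed = [], {}
    for fp in cands:
        rates = {base: production_rate(fp, net, base) for base in ENERGY_BASES}
        failing = env.contains(rates)
        if failing is None:
            survivors.append(fp)
        else:
            removed[fp.sample_id] = failing
    return survivors, FilterReport("energy", len(cands), len(removed), len(survivors), removed)


class UndefinedGDIError(ValueError):
    pass


def compute_gdi(fp: FluxProfile, cfg: GDIConfig) -> float:
    """Lactate secretion / glucose uptake (both as non-negative magnitudes).

    Secretion is the positive part of the lactate exchange flux; uptake is
    the magnitude of the negative glucose exchange flux.  Raises when glucose
    uptake is numerically zero (the index is undefined).
    """
    lac = fp.fluxes[cfg.lactate_exchange_id]
    glc = fp.fluxes[cfg.glucose_exchange_id]
    uptake = -glc if glc < 0 else 0.0
    if uptake <= cfg.zero_tol:
        raise UndefinedGDIError(f"sample {fp.sample_id!r}: no glucose uptake")
    return max(0.0, lac) / uptake


def filter_gdi(
    cands: list[FluxProfile], cfg: GDIConfig
) -> tuple[list[FluxProfile], FilterReport]:
    survivors, removed = [], {}
    for fp in cands:
        try:
            gdi = compute_gdi(fp, cfg)
        except UndefinedGDIError:
            removed[fp.sample_id] = "no glucose uptake"
            continue
        if gdi <= cfg.zero_tol:
            survivors.append(fp)
        else:
            removed[fp.sample_id] = f"GDI={gdi:.3g}"
    return survivors, FilterReport("gdi", len(cands), len(removed), len(survivors), removed)


def filter_gluconeogenesis(
    cands: list[FluxProfile],
    marker_reaction_ids: list[str],
    flux_tol: float = 1e-6,
    net: MetabolicNetwork | None = None,
) -> tuple[list[FluxProfile], FilterReport]:
    """Remove candidates whose marker reactions carry gluconeogenic
    (positive-direction) flux above the tolerance."""
    if net is not None:
        known = set(net.reaction_ids())
        unknown = [m for m in marker_reaction_ids if m not in known]
        if unknown:
            raise ValueError(f"unknown gluconeogenesis marker reactions: {unknown}")
    survivors, removed = [], {}
    for fp in cands:
        bad = [m for m in marker_reaction_ids if fp.fluxes.get(m, 0.0) > flux_tol]
        if bad:
            removed[fp.sample_id] = f"gluconeogenesis via {bad[0]}"
        else:
            survivors.append(fp)
    return survivors, FilterReport(
        "gluconeogenesis", len(cands), len(removed), len(survivors), removed
    )


def run_filtration(
    cands: list[FluxProfile],
    real_profiles: list[FluxProfile],
    net: MetabolicNetwork,
    gdi_cfg: GDIConfig,
    marker_reaction_ids: list[str],
    flux_tol: float = 1e-6,
) -> tuple[list[FluxProfile], list[FilterReport]]:
    """energy -> GDI -> gluconeogenesis, reporting per-stage counts."""
    env = build_envelope(real_profiles, net)
    s1, r1 = filter_energy(cands, env, net)
    s2, r2 = filter_gdi(s1, gdi_cfg)
    s3, r3 = filter_gluconeogenesis(s2, marker_reaction_ids, flux_tol, net=net)
    return s3, [r1, r2, r3]


def reports_to_rows(reports: list[FilterReport]) -> list[dict]:
    return [
        {
            "stage": r.stage,
            "n_in": r.n_in,
            "n_removed": r.n_removed,
            "n_out": r.n_out,
            "pct_removed": round(r.pct_removed, 4),
        }
        for r in reports
    ]
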