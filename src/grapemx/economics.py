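"""Sensor-adoption investment appraisal.

The optical sensor replaces destructive ripening/harvest sampling plus wet
chemistry for anthocyanins. The annual benefit of owning it is therefore the
cost *avoided*:

* the market value of grape destroyed by sampling,
* the labor-time difference between destructive collection and an optical
  reading, and
* the anthocyanin lab fee per sample

while the costs are the purchase price ``I`` and periodic maintenance. The
net present value over a lifetime of ``T`` years at discount rate ``r`` is

    NPV = -I - Σ_m M/(1+r)^m + Σ_{t=1..T} C_t/(1+r)^t

with maintenance ``M`` charged at every ``maintenance_interval_y``-th year up
to and including ``T`` and a constant annual net cash flow ``C``. The
breakeven lifetime is the smallest integer ``T`` with positive NPV.

Grape sample weight, bunch weight and grape price are specified as ranges;
the ``lower`` / ``upper`` / ``average`` scenarios evaluate the cash flow at
the corresponding bound of every range. Monte Carlo draws perturb the
stochastic inputs (labor rate and the three sampling times) with symmetric
uniform distributions around their nominal values.

TSS is assumed to be read with a refractometer the grower already owns, so
its lab fee is recorded but excluded from the savings: only the anthocyanin
analyses are avoided, which is why the appraisal concerns red cultivars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InvalidDistributionError,
    InvalidLifetimeError,
)

SCENARIOS = ("lower", "upper", "average")

#: Lifetime assumed in the headline appraisal (years).
DEFAULT_LIFETIME = 7


# ---------------------------------------------------------------------------
# configuration records


@dataclass(frozen=True)
class SamplingPlan:
    """Season-long sampling protocol and per-operation times (minutes)."""

    n_cultivars: int
    n_dates: int = 6
    samples_per_date_per_cultivar: int = 5
    vines_per_cultivar: int = 4
    bunches_per_vine: int = 3
    t_ripening_min: float = 11.0  # destructive ripening sample
    t_harvest_min: float = 4.5  # destructive harvest bunch
    t_mx_min: float = 5.0  # one optical measurement point

    def __post_init__(self):
        for name in ("n_cultivars", "n_dates", "samples_per_date_per_cultivar",
                     "vines_per_cultivar", "bunches_per_vine"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("t_ripening_min", "t_harvest_min", "t_mx_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CostParameters:
    """Cost model: value ranges, unit rates and the investment schedule."""

    sample_weight_kg: tuple[float, float] = (0.05, 0.2)
    bunch_weight_kg: tuple[float, float] = (0.1, 0.4)
    grape_price_eur_kg: tuple[float, float] = (0.45, 0.60)
    labor_eur_h: float = 8.0
    anth_lab_eur_sample: float = 20.0
    tss_lab_eur_sample: float = 5.0  # recorded; excluded from savings
    purchase_eur: float = 13_900.0
    maintenance_eur: float = 1_000.0
    maintenance_interval_y: int = 3
    discount_rate: float = 0.02

    def __post_init__(self):
        for name in ("sample_weight_kg", "bunch_weight_kg", "grape_price_eur_kg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} range is inverted: {lo} > {hi}")
        if self.discount_rate <= -1:
            raise ConfigError("discount_rate must exceed -1")
        if self.maintenance_interval_y < 1:
            raise ConfigError("maintenance_interval_y must be >= 1")


def two_hectare_plan(n_cultivars: int) -> SamplingPlan:
    """Average-sized Italian vineyard: 11 / 4.5 min destructive, 5 min optical."""
    return SamplingPlan(n_cultivars=n_cultivars)


def mossi_plan(n_cultivars: int = 6) -> SamplingPlan:
    """30-hectare estate preset: 20 / 9 min destructive, 9.5 min optical."""
    return SamplingPlan(n_cultivars=n_cultivars, t_ripening_min=20.0,
                        t_harvest_min=9.0, t_mx_min=9.5)


PRESET_PLANS = {"two-hectare": two_hectare_plan, "mossi": mossi_plan}


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class SampleCounts:
    ripening_samples: int  # per year
    harvest_bunches: int  # per year
    total_anth_samples: int  # per year
    per_date_samples: int


@dataclass(frozen=True)
class CashFlow:
    """Annual net cash flow (EUR/year) and its three components."""

    grape_value_eur: float
    labor_saving_eur: float
    lab_saving_eur: float

    @property
    def total_eur(self) -> float:
        return self.grape_value_eur + self.labor_saving_eur + self.lab_saving_eur


@dataclass(frozen=True)
class MonteCarloSummary:
    mean: float
    sd: float
    n_draws: int
    t_statistic: float
    seed: int


@dataclass(frozen=True)
class NPVResult:
    npv_eur: float
    lifetime_y: int
    cash_flows: tuple[float, ...]  # C_t, t = 1..T
    scenario: str = "average"
    mc_summary: MonteCarloSummary | None = None


# ---------------------------------------------------------------------------
# operations


def sample_counts(plan: SamplingPlan) -> SampleCounts:
    """Yearly sample arithmetic implied by the protocol."""
    ripening = plan.n_dates * plan.samples_per_date_per_cultivar * plan.n_cultivars
    harvest = plan.vines_per_cultivar * plan.bunches_per_vine * plan.n_cultivars
    return SampleCounts(
        ripening_samples=ripening,
        harvest_bunches=harvest,
        total_anth_samples=ripening + harvest,
        per_date_samples=plan.samples_per_date_per_cultivar * plan.n_cultivars,
    )


def _bound(value_range: tuple[float, float], scenario: str) -> float:
    lo, hi = value_range
    if scenario == "lower":
        return lo
    if scenario == "upper":
        return hi
    if scenario == "average":
        return (lo + hi) / 2.0
    raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def annual_net_cash_flow(
    plan: SamplingPlan,
    costs: CostParameters,
    scenario: str = "average",
    labor_eur_h: float | None = None,
    times_min: tuple[float, float, float] | None = None,
) -> CashFlow:
    """Annual cost avoided by owning the sensor, by component.

    ``labor_eur_h`` and ``times_min`` (ripening, harvest, optical minutes)
    override the nominal values — the hook the Monte Carlo and sensitivity
    analyses use.
    """
    counts = sample_counts(plan)
    w_sample = _bound(costs.sample_weight_kg, scenario)
    w_bunch = _bound(costs.bunch_weight_kg, scenario)
    price = _bound(costs.grape_price_eur_kg, scenario)
    rate = costs.labor_eur_h if labor_eur_h is None else labor_eur_h
    t_rip, t_har, t_mx = times_min if times_min is not None else (
        plan.t_ripening_min, plan.t_harvest_min, plan.t_mx_min)

    grape = (counts.ripening_samples * w_sample + counts.harvest_bunches * w_bunch) * price
    destructive_min = counts.ripening_samples * t_rip + counts.harvest_bunches * t_har
    optical_min = counts.total_anth_samples * t_mx
    labor = (destructive_min - optical_min) * rate / 60.0
    lab = counts.total_anth_samples * costs.anth_lab_eur_sample
    return CashFlow(grape_value_eur=grape, labor_saving_eur=labor, lab_saving_eur=lab)


def _maintenance_years(lifetime: int, interval: int):
    return range(interval, lifetime + 1, interval)


def npv(
    cash_flow: float,
    lifetime: int,
    costs: CostParameters,
    scenario: str = "average",
) -> NPVResult:
    """Discounted appraisal of a constant annual cash flow over ``lifetime`` years."""
    if not isinstance(lifetime, (int, np.integer)) or lifetime < 1:
        raise InvalidLifetimeError(f"lifetime must be an integer >= 1, got {lifetime!r}")
    r = costs.discount_rate
    flows = tuple(float(cash_flow) for _ in range(lifetime))
    discounted = sum(c / (1.0 + r) ** t for t, c in enumerate(flows, start=1))
    maintenance = sum(
        costs.maintenance_eur / (1.0 + r) ** m
        for m in _maintenance_years(lifetime, costs.maintenance_interval_y)
    )
    value = -costs.purchase_eur - maintenance + discounted
    return NPVResult(npv_eur=value, lifetime_y=int(lifetime), cash_flows=flows,
                     scenario=scenario)


def npv_for_plan(plan: SamplingPlan, costs: CostParameters,
                 scenario: str = "average",
                 lifetime: int = DEFAULT_LIFETIME) -> NPVResult:
    flow = annual_net_cash_flow(plan, costs, scenario).total_eur
    return npv(flow, lifetime, costs, scenario=scenario)


def breakeven_lifetime(
    plan: SamplingPlan,
    costs: CostParameters,
    scenario: str = "average",
    max_lifetime: int = 50,
) -> int | None:
    """Smallest integer lifetime with positive NPV, or None within ``max_lifetime``."""
    if max_lifetime < 1:
        raise InvalidLifetimeError("max_lifetime must be >= 1")
    flow = annual_net_cash_flow(plan, costs, scenario).total_eur
    for lifetime in range(1, max_lifetime + 1):
        if npv(flow, lifetime, costs, scenario=scenario).npv_eur > 0:
            return lifetime
    return None


def monte_carlo_npv(
    plan: SamplingPlan,
    costs: CostParameters,
    scenario: str = "average",
    lifetime: int = DEFAULT_LIFETIME,
    rel_width: float = 0.2,
    n_draws: int = 1000,
    seed: int = 0,
) -> NPVResult:
    """NPV distribution under uncertain labor cost and sampling times.

    Each draw samples the labor rate and the three per-operation times from
    symmetric uniform distributions of relative half-width ``rel_width``
    around their nominal values, then recomputes cash flow and NPV. With
    ``rel_width = 0`` every draw collapses onto the deterministic NPV.
    """
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    if rel_width < 0:
        raise InvalidDistributionError(f"rel_width must be >= 0, got {rel_width}")
    rng = np.random.default_rng(seed)

    def draw(nominal: float) -> float:
        if rel_width == 0:
            return nominal
        return float(rng.uniform(nominal * (1 - rel_width), nominal * (1 + rel_width)))

    values = np.empty(n_draws)
    for i in range(n_draws):
        rate = draw(costs.labor_eur_h)
        times = (draw(plan.t_ripening_min), draw(plan.t_harvest_min),
                 draw(plan.t_mx_min))
        flow = annual_net_cash_flow(plan, costs, scenario,
                                    labor_eur_h=rate, times_min=times).total_eur
        values[i] = npv(flow, lifetime, costs, scenario=scenario).npv_eur
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n_draws > 1 else 0.0
    if sd > 0:
        t_stat = mean / (sd / math.sqrt(n_draws))
    else:
        t_stat = math.copysign(math.inf, mean) if mean != 0 else 0.0
    nominal_flow = annual_net_cash_flow(plan, costs, scenario).total_eur
    return NPVResult(
        npv_eur=mean, lifetime_y=lifetime,
        cash_flows=tuple(nominal_flow for _ in range(lifetime)),
        scenario=scenario,
        mc_summary=MonteCarloSummary(mean=mean, sd=sd, n_draws=n_draws,
                                     t_statistic=t_stat, seed=seed),
    )


def sensitivity_sampling_time(
    plan: SamplingPlan,
    costs: CostParameters,
    scenario: str = "average",
    scale_grid: tuple[float, ...] = (0.5, 1.0, 2.0),
    equalized_grid: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    lifetime: int = DEFAULT_LIFETIME,
    max_lifetime: int = 50,
) -> pd.DataFrame:
    """Robustness of the appraisal to the sampling-time assumptions.

    Two families of settings: scaling all three times by a common factor
    (destructive and optical alike), and equalizing the optical time with the
    destructive times at a single value τ (killing the labor component
    entirely). One row per setting with the NPV at ``lifetime`` and the
    breakeven.
    """
    if len(scale_grid) == 0 or len(equalized_grid) == 0:
        raise ConfigError("sensitivity grids must be non-empty")
    if any(k < 0 for k in scale_grid) or any(t < 0 for t in equalized_grid):
        raise ConfigError("sensitivity grid values must be non-negative")
    rows = []
    for k in scale_grid:
        varied = replace(plan, t_ripening_min=plan.t_ripening_min * k,
                         t_harvest_min=plan.t_harvest_min * k,
                         t_mx_min=plan.t_mx_min * k)
        rows.append(("scale", k, varied))
    for tau in equalized_grid:
        varied = replace(plan, t_ripening_min=tau, t_harvest_min=tau, t_mx_min=tau)
        rows.append(("equalized", tau, varied))
    out = []
    for setting, value, varied in rows:
        result = npv_for_plan(varied, costs, scenario, lifetime)
        out.append({
            "setting": setting,
            "value": value,
            f"npv_at_{lifetime}y_eur": result.npv_eur,
            "breakeven_y": breakeven_lifetime(varied, costs, scenario, max_lifetime),
            "npv_positive": result.npv_eur > 0,
        })
    return pd.DataFrame(out)


def appraisal_grid(
    plan: SamplingPlan,
    costs: CostParameters,
    lifetime: int = DEFAULT_LIFETIME,
    max_lifetime: int = 50,
) -> pd.DataFrame:
    """Scenario × {NPV at lifetime, breakeven} grid for one sampling plan."""
    rows = []
    for scenario in SCENARIOS:
        result = npv_for_plan(plan, costs, scenario, lifetime)
        rows.append({
            "scenario": scenario,
            f"npv_{lifetime}y_eur": round(result.npv_eur, 2),
            "breakeven_y": breakeven_lifetime(plan, costs, scenario, max_lifetime),
        })
    return pd.DataFrame(rows)


def reference_cases() -> dict[str, SamplingPlan]:
    """The three appraisal cases of the headline analysis."""
    return {
        "two-hectare, 2 cultivars": two_hectare_plan(2),
        "two-hectare, 3 cultivars": two_hectare_plan(3),
        "mossi, 6 cultivars": mossi_plan(6),
    }


def full_report(costs: CostParameters | None = None,
                lifetime: int = DEFAULT_LIFETIME) -> pd.DataFrame:
    """NPV/breakeven grid over the three reference cases and three scenarios."""
    costs = costs or CostParameters()
    frames = []
    for case, plan in reference_cases().items():
        grid = appraisal_grid(plan, costs, lifetime)
        grid.insert(0, "case", case)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)
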