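"""Synthetic inputs and independent validation oracles.

Everything the pipeline needs can be generated offline: a parametric
Gompertz life table standing in for the national period life table, random
valid parameter sets for property testing, a geometric-series closed form
for a two-state survival chain, and a patient-level microsimulation that
replays the decision tree and transition process by direct random draws —
an estimator that is independent of the cohort engine's matrix algebra and
therefore serves as its validation oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .decision_tree import BRANCH_SPECS, branch_entry_cost
from .lifetable import LifeTable, fit_gompertz_scale, life_expectancy, synthesize_life_table
from .markov import (
    STANDARD,
    HealthState,
    Topology,
    _cost_vector,
    _qaly_vector,
    build_transition_matrix,
    default_horizon_months,
    discount_factor,
)
from .parameters import (
    DiagnosticTestProfile,
    ParameterSet,
    default_parameter_set,
    default_psa_distributions,
    serialize_parameter_set,
)

__all__ = [
    "MicrosimEstimate",
    "default_life_table",
    "random_parameter_set",
    "microsim_oracle",
    "toy_closed_form",
    "write_fixtures",
]

logger = logging.getLogger(__name__)

#: Residual life expectancy (years) at the cohort starting age that the
#: default synthetic life table is fitted to; matches the published
#: both-sex national figure for a 62-year-old (~21 years).
DEFAULT_LE_TARGET = 21.0
DEFAULT_LE_AGE = 62
DEFAULT_GOMPERTZ_B = 0.09


@lru_cache(maxsize=8)
def default_life_table(
    target_le: float = DEFAULT_LE_TARGET,
    at_age: int = DEFAULT_LE_AGE,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
) -> LifeTable:
    """Gompertz life table fitted so residual life expectancy at ``at_age``
    equals ``target_le`` years.

    This is a parametric stand-in for a national period life table; exact
    reproduction of published numbers that used the real US Life Tables 2015
    requires loading that external table instead.
    """
    a = fit_gompertz_scale(target_le, at_age, gompertz_b)
    lt = synthesize_life_table(a, gompertz_b)
    logger.info(
        "using synthetic Gompertz life table (a=%.3e, b=%.3f, e%d=%.2f); "
        "load the real US Life Tables 2015 for exact reproduction of published values",
        a, gompertz_b, at_age, life_expectancy(lt, at_age),
    )
    return lt


# ---------------------------------------------------------------------------
# Random valid parameter sets
# ---------------------------------------------------------------------------

#: Default sampling ranges per parameter id; every draw passes validation.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "pretest_malignant": (0.05, 0.95),
    "annual_discount": (0.0, 0.08),
    "cost_biopsy": (200.0, 4000.0),
    "cost_timely_treatment": (1000.0, 12000.0),
    "cost_delayed_treatment": (1500.0, 18000.0),
    "cost_unnecessary_biopsy": (200.0, 4000.0),
    "cost_no_action": (0.0, 200.0),
    "monthly_cost_no_tumor": (20.0, 400.0),
    "monthly_cost_localized_y1": (400.0, 6000.0),
    "monthly_cost_localized_later": (50.0, 800.0),
    "monthly_cost_metastatic_y1": (400.0, 6000.0),
    "monthly_cost_metastatic_later": (150.0, 2500.0),
    "utility_no_tumor": (0.85, 1.0),
    "utility_localized": (0.5, 0.9),
    "utility_metastatic": (0.3, 0.8),
    "p_non_r0": (0.0, 0.3),
    "p_local_recurrence": (0.0, 0.4),
    "p_metastases_no_tumor": (0.0, 0.1),
    "p_metastases_localized": (0.0, 0.4),
    "p_successful_recurrence_surgery": (0.1, 0.9),
    "excess_death_metastatic": (0.05, 0.6),
    "excess_death_localized": (0.0, 0.15),
}
_TEST_BOUNDS = {"sensitivity": (0.5, 0.999), "specificity": (0.5, 0.999), "exam_cost": (50.0, 1500.0)}


def random_parameter_set(
    rng: np.random.Generator,
    bounds_profile: dict[str, tuple[float, float]] | None = None,
) -> ParameterSet:
    """Draw a random, valid parameter set (uniform within per-field bounds).

    ``bounds_profile`` overrides individual sampling ranges; ranges must lie
    within the type invariants.  The output always passes
    :func:`renalcea.parameters.validate_parameter_set` and encodes the
    clinical ordering that metastatic disease is valued no better, and
    carries no lower excess mortality, than localized disease.
    """
    bounds = dict(DEFAULT_BOUNDS)
    test_bounds = dict(_TEST_BOUNDS)
    if bounds_profile:
        for key, rng_pair in bounds_profile.items():
            if key in test_bounds:
                test_bounds[key] = rng_pair
            else:
                bounds[key] = rng_pair

    def u(pid: str, cap: float | None = None, floor: float | None = None) -> float:
        lo, hi = bounds[pid]
        if cap is not None:
            hi = min(hi, cap)
        if floor is not None:
            lo = max(lo, floor)
        if hi <= lo:
            return lo
        return float(rng.uniform(lo, hi))

    base = default_parameter_set(with_psa=False)
    utility_localized = u("utility_localized")
    utility_metastatic = u("utility_metastatic", cap=utility_localized)
    excess_death_metastatic = u("excess_death_metastatic")
    excess_death_localized = u("excess_death_localized", cap=excess_death_metastatic)
    tests = tuple(
        DiagnosticTestProfile(
            t.name,
            sensitivity=float(rng.uniform(*test_bounds["sensitivity"])),
            specificity=float(rng.uniform(*test_bounds["specificity"])),
            exam_cost=float(rng.uniform(*test_bounds["exam_cost"])),
        )
        for t in base.tests
    )
    ps = replace(
        base,
        pretest_malignant=u("pretest_malignant"),
        annual_discount=u("annual_discount"),
        tests=tests,
        cost_biopsy=u("cost_biopsy"),
        cost_timely_treatment=u("cost_timely_treatment"),
        cost_delayed_treatment=u("cost_delayed_treatment"),
        cost_unnecessary_biopsy=u("cost_unnecessary_biopsy"),
        cost_no_action=u("cost_no_action"),
        monthly_cost_no_tumor=u("monthly_cost_no_tumor"),
        monthly_cost_localized_y1=u("monthly_cost_localized_y1"),
        monthly_cost_localized_later=u("monthly_cost_localized_later"),
        monthly_cost_metastatic_y1=u("monthly_cost_metastatic_y1"),
        monthly_cost_metastatic_later=u("monthly_cost_metastatic_later"),
        utility_no_tumor=u("utility_no_tumor"),
        utility_localized=utility_localized,
        utility_metastatic=utility_metastatic,
        p_non_r0=u("p_non_r0"),
        p_local_recurrence=u("p_local_recurrence"),
        p_metastases_no_tumor=u("p_metastases_no_tumor"),
        p_metastases_localized=u("p_metastases_localized"),
        p_successful_recurrence_surgery=u("p_successful_recurrence_surgery"),
        excess_death_metastatic=excess_death_metastatic,
        excess_death_localized=excess_death_localized,
    )
    return replace(ps, psa_dist=default_psa_distributions(ps))


# ---------------------------------------------------------------------------
# Patient-level microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte-Carlo estimate of a strategy's expected cost and QALYs."""

    n_patients: int
    mean_cost: float
    mean_qalys: float
    se_cost: float
    se_qalys: float


def microsim_oracle(
    ps: ParameterSet,
    lt: LifeTable,
    test: DiagnosticTestProfile,
    n_patients: int,
    seed: int,
    horizon_months: int | None = None,
    topology: Topology = STANDARD,
) -> MicrosimEstimate:
    """Estimate a strategy's expected cost/QALYs by simulating individual
    patients with direct random draws (no cohort matrix propagation).

    Each patient is assigned a disease status and a test result, charged the
    branch entry cost, placed in the branch entry state, and then walked
    month by month through the same transition probabilities the cohort
    engine uses, accruing discounted rewards at cycle start.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    if horizon_months is None:
        horizon_months = default_horizon_months(ps, lt)

    diseased = rng.random(n_patients) < ps.pretest_malignant
    positive = np.where(
        diseased,
        rng.random(n_patients) < test.sensitivity,
        rng.random(n_patients) < (1.0 - test.specificity),
    )
    branch = np.where(
        diseased,
        np.where(positive, 0, 1),  # TP / FN
        np.where(positive, 3, 2),  # FP / TN
    )
    branch_names = np.array(["TP", "FN", "TN", "FP"])
    entry_costs = np.array([branch_entry_cost(b, test, ps) for b in branch_names])
    entry_states = np.array([BRANCH_SPECS[b].entry_state for b in branch_names], dtype=np.int8)

    cost = entry_costs[branch].astype(float)
    qalys = np.zeros(n_patients)
    states = entry_states[branch].copy()
    qaly_vec = _qaly_vector(ps)
    start_months = ps.start_age_years * 12

    for t in range(horizon_months):
        alive = states != HealthState.DEAD
        if not alive.any():
            break
        disc = discount_factor(t, ps.annual_discount)
        cvec = _cost_vector(ps, t, topology)
        cost += disc * cvec[states]
        qalys += disc * qaly_vec[states]
        m = build_transition_matrix(ps, lt, start_months + t, topology)
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_patients)
        states = (u[:, None] > cum[states]).sum(axis=1).astype(np.int8)

    ddof = 1 if n_patients > 1 else 0
    return MicrosimEstimate(
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        mean_qalys=float(qalys.mean()),
        se_cost=float(cost.std(ddof=ddof) / np.sqrt(n_patients)),
        se_qalys=float(qalys.std(ddof=ddof) / np.sqrt(n_patients)),
    )


# ---------------------------------------------------------------------------
# Two-state closed form
# ---------------------------------------------------------------------------

def toy_closed_form(
    q_monthly: float,
    utility: float,
    monthly_cost: float,
    discount: float,
    horizon: int | None = None,
) -> tuple[float, float]:
    """Geometric-series totals for a two-state alive/dead chain.

    With constant monthly death probability q, rewards accrued at cycle
    start (cycle 0 included) and discounting (1+r)^(-t/12), the survivors'
    discounted reward stream is a geometric series with ratio
    rho = (1-q) * (1+r)^(-1/12):

        total = reward * (1 - rho^H) / (1 - rho)

    ``horizon=None`` takes the infinite-horizon limit.
    """
    if not 0.0 < q_monthly <= 1.0:
        raise ValueError("q_monthly must be in (0, 1]")
    rho = (1.0 - q_monthly) * (1.0 + discount) ** (-1.0 / 12.0)
    if horizon is None:
        series = 1.0 / (1.0 - rho)
    else:
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        series = (1.0 - rho**horizon) / (1.0 - rho) if rho != 1.0 else float(horizon)
    return monthly_cost * series, (utility / 12.0) * series


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixtures(directory) -> dict[str, Path]:
    """Write the baseline config and the synthetic life-table CSV.

    Returns the paths keyed as ``config`` and ``life_table``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config_path = directory / "baseline.yaml"
    config_path.write_text(serialize_parameter_set(default_parameter_set()))
    lt = default_life_table()
    lt_path = directory / "synthetic_gompertz_lifetable.csv"
    lines = ["age,qx"] + [f"{a},{q:.10g}" for a, q in zip(lt.ages, lt.qx)]
    lt_path.write_text("\n".join(lines) + "\n")
    return {"config": config_path, "life_table": lt_path}
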