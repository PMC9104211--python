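"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way deterministic SA re-runs the full pipeline with a single parameter
pinned at the ends of its range and reports the span of a decision metric
(default: the net-monetary-benefit gap between the reference strategy and
its best alternative at the willingness-to-pay; an ICER metric is
available).  Probabilistic SA redraws every uncertain parameter from its
assigned distribution (beta for probabilities/utilities, gamma for costs,
method-of-moments from mean and coefficient of variation), re-evaluates all
strategies per iteration, and summarizes decision uncertainty as
cost-effectiveness acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import icer as _icer
from .cea import net_monetary_benefit
from .decision_tree import evaluate_all_strategies
from .lifetable import LifeTable, monthly_background_death_prob
from .markov import STANDARD, HealthState, Topology, default_horizon_months
from .parameters import (
    FIRST_YEAR_MONTHS,
    DistributionSpec,
    ParameterSet,
    get_parameter,
    parameter_ids,
    parameter_kind,
    set_parameter,
)

__all__ = [
    "ModelContext",
    "TornadoEntry",
    "PSAResult",
    "one_way_dsa",
    "tornado",
    "default_dsa_ranges",
    "sample_parameter",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

#: Willingness-to-pay grid for acceptability curves: 0 to 200,000 USD/QALY.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 200_001, 10_000))

#: Default relative half-width of one-way DSA ranges when none are given.
DEFAULT_DSA_RELATIVE = 0.2


@dataclass(frozen=True)
class ModelContext:
    """Everything needed to re-evaluate the model besides the parameters.

    ``metric`` selects the tornado outcome: ``"nmb_gap"`` is the net
    monetary benefit of the reference strategy minus the best alternative's
    at the willingness-to-pay (positive = reference remains preferred);
    ``"icer"`` is the ICER of the reference strategy versus its best
    alternative (NaN when effects tie).
    """

    life_table: LifeTable
    horizon_months: int | None = None
    topology: Topology = STANDARD
    reference: str = "CEUS"
    wtp: float | None = None  # None: use the parameter set's WTP
    metric: str = "nmb_gap"

    def outcome(self, ps: ParameterSet) -> float:
        results = evaluate_all_strategies(ps, self.life_table, self.horizon_months, self.topology)
        wtp = self.wtp if self.wtp is not None else ps.wtp
        ref = next(r for r in results if r.strategy.lower() == self.reference.lower())
        others = [r for r in results if r.strategy != ref.strategy]
        if not others:
            return net_monetary_benefit(ref, wtp)
        best_other = max(others, key=lambda r: net_monetary_benefit(r, wtp))
        if self.metric == "nmb_gap":
            return net_monetary_benefit(ref, wtp) - net_monetary_benefit(best_other, wtp)
        if self.metric == "icer":
            ratio = _icer(ref, best_other)
            return float("nan") if not ratio.is_ratio else ratio.value
        raise ValueError(f"unknown metric {self.metric!r}")


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """Outcome of one parameter swept to the ends of its range."""

    parameter: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def span(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _check_domain(param_id: str, value: float) -> None:
    kind = parameter_kind(param_id)
    if kind in ("probability", "utility") and not 0.0 <= value <= 1.0:
        raise ValueError(f"{param_id}={value} outside [0,1]")
    if kind == "cost" and value < 0:
        raise ValueError(f"{param_id}={value} must be >= 0")


def one_way_dsa(
    ps: ParameterSet,
    parameter_id: str,
    low: float,
    high: float,
    model_context: ModelContext,
) -> TornadoEntry:
    """Re-run the base-case pipeline with one parameter pinned at ``low``
    and at ``high`` and record the decision metric at both ends."""
    if low > high:
        raise ValueError(f"low {low} exceeds high {high} for {parameter_id}")
    _check_domain(parameter_id, low)
    _check_domain(parameter_id, high)
    out_low = model_context.outcome(set_parameter(ps, parameter_id, low))
    out_high = model_context.outcome(set_parameter(ps, parameter_id, high))
    return TornadoEntry(parameter_id, low, high, out_low, out_high)


def default_dsa_ranges(
    ps: ParameterSet, relative: float = DEFAULT_DSA_RELATIVE
) -> dict[str, tuple[float, float]]:
    """±`relative` ranges around the base value for every cost and every
    test sensitivity/specificity, clipped to [0,1] for probabilities."""
    ranges: dict[str, tuple[float, float]] = {}
    for pid in parameter_ids(ps):
        kind = parameter_kind(pid)
        swept = kind == "cost" or pid.startswith(("sensitivity_", "specificity_"))
        if not swept:
            continue
        base = get_parameter(ps, pid)
        lo, hi = base * (1.0 - relative), base * (1.0 + relative)
        if kind in ("probability", "utility"):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[pid] = (lo, hi)
    return ranges


def tornado(
    ps: ParameterSet,
    range_spec: Mapping[str, tuple[float, float]] | Sequence[tuple[str, float, float]] | None = None,
    model_context: ModelContext | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over a set of parameter ranges, sorted by descending span."""
    if model_context is None:
        raise ValueError("a ModelContext is required")
    if range_spec is None:
        items = list(default_dsa_ranges(ps).items())
    elif isinstance(range_spec, Mapping):
        items = [(pid, (lo, hi)) for pid, (lo, hi) in range_spec.items()]
    else:
        items = [(pid, (lo, hi)) for pid, lo, hi in range_spec]
    seen: set[str] = set()
    for pid, _ in items:
        if pid in seen:
            raise ValueError(f"duplicated parameter {pid!r} in range specification")
        seen.add(pid)
    entries = [one_way_dsa(ps, pid, lo, hi, model_context) for pid, (lo, hi) in items]
    return sorted(entries, key=lambda e: e.span, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "outcome_at_low": [e.outcome_at_low for e in entries],
            "outcome_at_high": [e.outcome_at_high for e in entries],
            "span": [e.span for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_parameter(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None, name: str = "parameter"
) -> float | np.ndarray:
    """Draw from a distribution spec via method of moments.

    beta: with m = mean and v = (cv*m)^2, alpha = m*(m(1-m)/v - 1),
    beta = (1-m)*(m(1-m)/v - 1); requires v < m(1-m).
    gamma: shape = 1/cv^2, scale = mean*cv^2.  fixed: the mean itself.
    """
    if spec.family == "fixed":
        return spec.mean if size is None else np.full(size, spec.mean)
    m, cv = spec.mean, spec.cv
    v = (cv * m) ** 2
    if spec.family == "beta":
        vmax = m * (1.0 - m)
        if v >= vmax:
            raise ValueError(
                f"infeasible beta moments for {name}: cv {cv} gives variance {v:.3g} "
                f">= m(1-m) = {vmax:.3g}"
            )
        nu = m * (1.0 - m) / v - 1.0
        draw = rng.beta(m * nu, (1.0 - m) * nu, size=size)
    else:  # gamma
        shape = 1.0 / cv**2
        scale = m * cv**2
        draw = rng.gamma(shape, scale, size=size)
    return float(draw) if size is None else draw


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Per-iteration (cost, effect) pairs per strategy from a seeded PSA."""

    n_iterations: int
    seed: int
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iterations, n_strategies) USD
    effects: np.ndarray  # (n_iterations, n_strategies) QALYs

    def iteration_frame(self) -> pd.DataFrame:
        """Long-format iteration table (iteration, strategy, cost, effect)."""
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "strategy": list(self.strategies) * n,
                "cost": self.costs.ravel(),
                "effect": self.effects.ravel(),
            }
        )

    def acceptance_at(self, wtp: float) -> dict[str, float]:
        """Fraction of iterations each strategy maximizes NMB at one WTP."""
        curve = ceac(self, [wtp])
        return {s: float(curve.loc[wtp, s]) for s in self.strategies}


def _monthly_from_annual(p: np.ndarray) -> np.ndarray:
    return 1.0 - (1.0 - p) ** (1.0 / 12.0)


def _draw_parameter_matrix(
    ps: ParameterSet, n_iterations: int, seed: int
) -> dict[str, np.ndarray]:
    """Per-iteration substreams: one spawned generator per iteration, each
    drawing every sampled parameter in a fixed (sorted) order, so results
    do not depend on how iterations might be distributed."""
    ids = sorted(ps.psa_dist)
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    draws = {pid: np.empty(n_iterations) for pid in ids}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for pid in ids:
            spec = ps.psa_dist[pid]
            val = sample_parameter(spec, rng, name=pid)
            if parameter_kind(pid) in ("probability", "utility"):
                val = min(max(val, 0.0), 1.0)
            draws[pid][i] = val
    return draws


def _col(draws: dict[str, np.ndarray], ps: ParameterSet, pid: str, n: int) -> np.ndarray:
    if pid in draws:
        return draws[pid]
    return np.full(n, get_parameter(ps, pid))


def _batched_pathway_totals(
    draws: dict[str, np.ndarray],
    ps: ParameterSet,
    lt: LifeTable,
    n: int,
    horizon_months: int,
    topology: Topology,
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (cost, QALY) totals per iteration for cohorts entering in
    each alive state.  Returns arrays of shape (n, 3) ordered NO_TUMOR,
    LOCALIZED, METASTATIC, mirroring the scalar engine's arithmetic."""
    g = lambda pid: _col(draws, ps, pid, n)  # noqa: E731

    if topology.disease_transitions:
        p_met_nt = _monthly_from_annual(g("p_metastases_no_tumor"))
        p_rec = _monthly_from_annual(g("p_local_recurrence"))
        p_met_loc = _monthly_from_annual(g("p_metastases_localized"))
        p_cure_ep = (1.0 - g("p_non_r0")) * g("p_successful_recurrence_surgery")
        p_cure = 1.0 - (1.0 - p_cure_ep) ** (1.0 / 12.0)
    else:
        p_met_nt = p_rec = p_met_loc = p_cure = np.zeros(n)
    if topology.excess_mortality:
        mexc_loc = _monthly_from_annual(g("excess_death_localized"))
        mexc_met = _monthly_from_annual(g("excess_death_metastatic"))
    else:
        mexc_loc = mexc_met = np.zeros(n)

    start_months = ps.start_age_years * 12
    bg = np.array(
        [monthly_background_death_prob(lt, start_months + t) for t in range(horizon_months)]
    )
    disc = (1.0 + ps.annual_discount) ** (-np.arange(horizon_months) / 12.0)

    u_nt, u_loc, u_met = g("utility_no_tumor"), g("utility_localized"), g("utility_metastatic")
    qaly_vec = np.stack([u_nt, u_loc, u_met, np.zeros(n)], axis=1) / 12.0  # (n, 4)

    c_nt = g("monthly_cost_no_tumor")
    c_loc_y1 = c_nt if topology.localized_first_year_cost == "maintenance" else g("monthly_cost_localized_y1")
    c_loc_later = g("monthly_cost_localized_later")
    c_met_y1 = g("monthly_cost_metastatic_y1")
    c_met_later = g("monthly_cost_metastatic_later")
    zeros = np.zeros(n)
    cost_y1 = np.stack([c_nt, c_loc_y1, c_met_y1, zeros], axis=1)
    cost_later = np.stack([c_nt, c_loc_later, c_met_later, zeros], axis=1)

    occ = np.zeros((n, 3, 4))
    occ[:, 0, HealthState.NO_TUMOR] = 1.0
    occ[:, 1, HealthState.LOCALIZED] = 1.0
    occ[:, 2, HealthState.METASTATIC] = 1.0
    tot_cost = np.zeros((n, 3))
    tot_qaly = np.zeros((n, 3))

    m = np.zeros((n, 4, 4))
    for t in range(horizon_months):
        cvec = cost_y1 if t < FIRST_YEAR_MONTHS else cost_later
        if topology.cost_window_months is not None and t >= topology.cost_window_months:
            cvec = None
        if cvec is not None:
            tot_cost += disc[t] * np.einsum("nsj,nj->ns", occ, cvec)
        tot_qaly += disc[t] * np.einsum("nsj,nj->ns", occ, qaly_vec)

        b = bg[t]
        d_loc = 1.0 - (1.0 - b) * (1.0 - mexc_loc)
        d_met = 1.0 - (1.0 - b) * (1.0 - mexc_met)
        m[:] = 0.0
        # no-tumor row
        m[:, 0, 3] = b
        m[:, 0, 2] = (1.0 - b) * p_met_nt
        m[:, 0, 1] = (1.0 - b) * p_rec
        m[:, 0, 0] = (1.0 - b) * (1.0 - p_met_nt - p_rec)
        # localized row
        m[:, 1, 3] = d_loc
        m[:, 1, 2] = (1.0 - d_loc) * p_met_loc
        m[:, 1, 0] = (1.0 - d_loc) * p_cure
        m[:, 1, 1] = (1.0 - d_loc) * (1.0 - p_met_loc - p_cure)
        # metastatic row
        m[:, 2, 3] = d_met
        m[:, 2, 2] = 1.0 - d_met
        m[:, 3, 3] = 1.0
        occ = occ @ m
    return tot_cost, tot_qaly


def run_psa(
    ps: ParameterSet,
    lt: LifeTable,
    n_iterations: int,
    seed: int,
    horizon_months: int | None = None,
    topology: Topology = STANDARD,
) -> PSAResult:
    """Monte-Carlo PSA: redraw every uncertain parameter independently per
    iteration, re-evaluate all strategies, and collect (cost, effect) pairs.

    Fully reproducible for a given seed.  Parameters with a ``fixed``
    distribution (and any parameter without an entry in ``ps.psa_dist``)
    stay at their base value.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if horizon_months is None:
        horizon_months = default_horizon_months(ps, lt)
    n = n_iterations
    draws = _draw_parameter_matrix(ps, n, seed)
    path_cost, path_qaly = _batched_pathway_totals(draws, ps, lt, n, horizon_months, topology)

    g = lambda pid: _col(draws, ps, pid, n)  # noqa: E731
    prev = g("pretest_malignant")
    costs = np.empty((n, len(ps.tests)))
    effects = np.empty((n, len(ps.tests)))
    for k, test in enumerate(ps.tests):
        key = test.name.lower()
        se, sp = g(f"sensitivity_{key}"), g(f"specificity_{key}")
        exam = g(f"exam_cost_{key}")
        tp, fn = prev * se, prev * (1.0 - se)
        tn, fp = (1.0 - prev) * sp, (1.0 - prev) * (1.0 - sp)
        entry_tp = exam + g("cost_timely_treatment")
        entry_fn = exam + g("cost_delayed_treatment")
        entry_tn = exam + g("cost_no_action")
        entry_fp = exam + g("cost_unnecessary_biopsy")
        costs[:, k] = (
            tp * (entry_tp + path_cost[:, 1])
            + fn * (entry_fn + path_cost[:, 2])
            + tn * (entry_tn + path_cost[:, 0])
            + fp * (entry_fp + path_cost[:, 0])
        )
        effects[:, k] = (
            tp * path_qaly[:, 1] + fn * path_qaly[:, 2] + (tn + fp) * path_qaly[:, 0]
        )
    return PSAResult(
        n_iterations=n,
        seed=seed,
        strategies=ps.strategy_names,
        costs=costs,
        effects=effects,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay, the fraction of iterations in which each
    strategy attains the maximal net monetary benefit.  NMB ties go to the
    cheaper strategy; exact (NMB and cost) ties are split equally, so the
    fractions sum to 1 at every grid point.
    """
    grid = [float(w) for w in wtp_grid]
    if not grid:
        raise ValueError("wtp_grid must be non-empty")
    rows = np.empty((len(grid), len(psa.strategies)))
    for i, wtp in enumerate(grid):
        nmb = wtp * psa.effects - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        cost_of_best = np.where(is_best, psa.costs, np.inf)
        cheapest = cost_of_best.min(axis=1, keepdims=True)
        winner = is_best & (cost_of_best == cheapest)
        weights = winner / winner.sum(axis=1, keepdims=True)
        rows[i] = weights.mean(axis=0)
    return pd.DataFrame(rows, index=pd.Index(grid, name="wtp"), columns=list(psa.strategies))
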