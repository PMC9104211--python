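"""Diagnostic decision tree: from a test's accuracy to the four branches.

Each strategy classifies the cohort into true positive (timely treatment),
false negative (delayed treatment), true negative (no action) and false
positive (unnecessary biopsy).  Every branch carries a one-off entry cost
and seeds a Markov cohort run from a branch-specific health state:

* TP -> localized malignancy, acute in-time surgery + treatment expense;
* FN -> metastatic malignancy, acute delayed surgery + treatment expense
  charged at model start (the missed tumor follows the untreated disease
  trajectory; the long-term metastatic expense and utility rows are the
  published delayed-therapy values);
* TN -> no malignancy, no further action;
* FP -> no malignancy, unnecessary biopsy expense.

The strategy's expected cost and effectiveness are the branch-probability-
weighted sums of entry costs and discounted Markov accruals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cea import StrategyResult
from .lifetable import LifeTable
from .markov import STANDARD, HealthState, Topology, run_cohort
from .parameters import FIRST_YEAR_MONTHS, DiagnosticTestProfile, ParameterSet

__all__ = [
    "Branch",
    "BranchProbabilities",
    "BranchSpec",
    "BRANCH_SPECS",
    "branch_probabilities",
    "branch_entry_cost",
    "evaluate_strategy",
    "evaluate_all_strategies",
    "first_year_additive_expenses",
]

Branch = str  # "TP" | "FN" | "TN" | "FP"


@dataclass(frozen=True)
class BranchProbabilities:
    """Probability of each initial classification branch."""

    tp: float
    fn: float
    tn: float
    fp: float

    def as_dict(self) -> dict[str, float]:
        return {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp}


@dataclass(frozen=True)
class BranchSpec:
    """Structural description of one branch: entry state and pathway."""

    branch: Branch
    entry_state: HealthState
    pathway: str  # "timely" | "delayed" | "none"


BRANCH_SPECS: dict[Branch, BranchSpec] = {
    "TP": BranchSpec("TP", HealthState.LOCALIZED, "timely"),
    "FN": BranchSpec("FN", HealthState.METASTATIC, "delayed"),
    "TN": BranchSpec("TN", HealthState.NO_TUMOR, "none"),
    "FP": BranchSpec("FP", HealthState.NO_TUMOR, "none"),
}


def branch_probabilities(prevalence: float, test: DiagnosticTestProfile) -> BranchProbabilities:
    """Split a cohort with the given disease prevalence by test outcome."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence out of [0,1]: {prevalence}")
    se, sp = test.sensitivity, test.specificity
    return BranchProbabilities(
        tp=prevalence * se,
        fn=prevalence * (1.0 - se),
        tn=(1.0 - prevalence) * sp,
        fp=(1.0 - prevalence) * (1.0 - sp),
    )


def branch_entry_cost(branch: Branch, test: DiagnosticTestProfile, ps: ParameterSet) -> float:
    """One-off cost charged at model entry on the given branch (exam plus
    the branch's acute expense)."""
    acute = {
        "TP": ps.cost_timely_treatment,
        "FN": ps.cost_delayed_treatment,
        "TN": ps.cost_no_action,
        "FP": ps.cost_unnecessary_biopsy,
    }
    if branch not in acute:
        raise ValueError(f"unknown branch {branch!r}")
    return test.exam_cost + acute[branch]


def evaluate_strategy(
    test: DiagnosticTestProfile,
    ps: ParameterSet,
    lt: LifeTable,
    horizon_months: int | None = None,
    topology: Topology = STANDARD,
) -> StrategyResult:
    """Expected discounted lifetime cost and QALYs of one diagnostic strategy.

    Runs one cohort per distinct branch pathway and weights entry costs and
    Markov totals by the branch probabilities.
    """
    probs = branch_probabilities(ps.pretest_malignant, test).as_dict()
    cost = 0.0
    effect = 0.0
    traces: dict[str, tuple[float, float]] = {}
    for branch, p in probs.items():
        spec = BRANCH_SPECS[branch]
        key = spec.entry_state.name
        if key not in traces:
            entry = [0.0] * 4
            entry[spec.entry_state] = 1.0
            tr = run_cohort(entry, ps, lt, spec.pathway, horizon_months, topology)
            traces[key] = (tr.total_cost, tr.total_qalys)
        run_cost, run_qalys = traces[key]
        cost += p * (branch_entry_cost(branch, test, ps) + run_cost)
        effect += p * run_qalys
    return StrategyResult(strategy=test.name, expected_cost=cost, expected_effect=effect)


def evaluate_all_strategies(
    ps: ParameterSet,
    lt: LifeTable,
    horizon_months: int | None = None,
    topology: Topology = STANDARD,
) -> list[StrategyResult]:
    """Evaluate every strategy in the parameter set."""
    return [evaluate_strategy(t, ps, lt, horizon_months, topology) for t in ps.tests]


def first_year_additive_expenses(ps: ParameterSet) -> dict[str, float]:
    """Worked-example quantities for the healthy branches.

    A true-negative patient accrues twelve undiscounted monthly cycles of
    the without-tumor expense during the model's first year; a false
    positive additionally pays only the unnecessary biopsy.  Returned on
    top of the exam cost.
    """
    return {
        "TN": FIRST_YEAR_MONTHS * ps.monthly_cost_no_tumor,
        "FP": ps.cost_unnecessary_biopsy,
    }
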