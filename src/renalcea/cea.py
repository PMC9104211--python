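"""Cost-effectiveness comparison: ICERs, dominance and net monetary benefit.

For two strategies with expected costs E1, E0 and effects O1, O0 the
incremental cost-effectiveness ratio is

    ICER = (E1 - E0) / (O1 - O0)   [USD per QALY]

Strategy A *strictly dominates* B when A costs no more and yields no fewer
QALYs, with at least one strict inequality; a strategy is *extended
dominated* when it is outperformed by a mixture of two others, detected as
a non-monotone ICER sequence along the cost-sorted frontier.  The net
monetary benefit at willingness-to-pay lambda is ``lambda * effect - cost``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StrategyResult",
    "Icer",
    "StrategyFlags",
    "CEAResult",
    "icer",
    "net_monetary_benefit",
    "rank_and_dominance",
]


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted cost (USD) and effectiveness (QALYs) of a strategy."""

    strategy: str
    expected_cost: float
    expected_effect: float

    def __post_init__(self) -> None:
        if self.expected_cost < 0 or self.expected_effect < 0:
            raise ValueError("expected cost and effect must be >= 0")


@dataclass(frozen=True)
class Icer:
    """An ICER value or a flag when the ratio is undefined.

    ``flag`` is ``None`` for a finite ratio, ``"equal_effect"`` when the two
    strategies have identical effectiveness (a cost-only comparison) and
    ``"identical"`` when both cost and effect coincide.
    """

    value: float | None
    flag: str | None = None
    delta_cost: float = 0.0
    delta_effect: float = 0.0

    @property
    def is_ratio(self) -> bool:
        return self.flag is None


def icer(a: StrategyResult, b: StrategyResult, effect_tol: float = 0.0) -> Icer:
    """ICER of strategy ``a`` versus ``b``: (Ea - Eb) / (Oa - Ob)."""
    d_cost = a.expected_cost - b.expected_cost
    d_eff = a.expected_effect - b.expected_effect
    if abs(d_eff) <= effect_tol:
        flag = "identical" if d_cost == 0 else "equal_effect"
        return Icer(None, flag, d_cost, d_eff)
    return Icer(d_cost / d_eff, None, d_cost, d_eff)


def net_monetary_benefit(r: StrategyResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (USD/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * r.expected_effect - r.expected_cost


@dataclass(frozen=True)
class StrategyFlags:
    """Dominance classification of one strategy."""

    dominated: bool = False
    extended_dominated: bool = False
    on_frontier: bool = False
    dominated_by: tuple[str, ...] = ()
    equivalent_to: tuple[str, ...] = ()


@dataclass(frozen=True)
class CEAResult:
    """Ranked strategies with dominance flags and ICER tables."""

    results: tuple[StrategyResult, ...]  # sorted by expected cost
    flags: dict[str, StrategyFlags]
    pairwise_icers: dict[tuple[str, str], Icer]
    frontier_icers: tuple[tuple[str, str, Icer], ...]  # (strategy, comparator, icer)

    @property
    def frontier(self) -> tuple[str, ...]:
        return tuple(r.strategy for r in self.results if self.flags[r.strategy].on_frontier)

    def optimal_at(self, wtp: float) -> str:
        """Frontier strategy with the highest net monetary benefit at ``wtp``."""
        best = max(
            (r for r in self.results if self.flags[r.strategy].on_frontier),
            key=lambda r: (net_monetary_benefit(r, wtp), -r.expected_cost),
        )
        return best.strategy


def _strictly_dominates(a: StrategyResult, b: StrategyResult) -> bool:
    return (
        a.expected_cost <= b.expected_cost
        and a.expected_effect >= b.expected_effect
        and (a.expected_cost < b.expected_cost or a.expected_effect > b.expected_effect)
    )


def rank_and_dominance(results: list[StrategyResult]) -> CEAResult:
    """Sort by cost, flag strict and extended dominance, and compute ICERs.

    Cost-and-effect ties are kept on the frontier together and flagged as
    equivalent.  Frontier ICERs are computed between adjacent frontier
    members after removing dominated strategies.
    """
    if not results:
        raise ValueError("at least one strategy required")
    ordered = tuple(sorted(results, key=lambda r: (r.expected_cost, -r.expected_effect)))
    by_name = {r.strategy: r for r in ordered}
    if len(by_name) != len(ordered):
        raise ValueError("strategy labels must be unique")

    dominated_by: dict[str, list[str]] = {r.strategy: [] for r in ordered}
    equivalent: dict[str, list[str]] = {r.strategy: [] for r in ordered}
    for a in ordered:
        for b in ordered:
            if a.strategy == b.strategy:
                continue
            if (
                a.expected_cost == b.expected_cost
                and a.expected_effect == b.expected_effect
            ):
                equivalent[a.strategy].append(b.strategy)
            elif _strictly_dominates(b, a):
                dominated_by[a.strategy].append(b.strategy)

    # Extended dominance: walk the cost-sorted non-dominated set and drop
    # strategies whose incremental ICER exceeds that of the next step up
    # (a mixture of its neighbours would do better), until ICERs increase
    # monotonically along the frontier.
    candidates = [r for r in ordered if not dominated_by[r.strategy]]
    extended: set[str] = set()
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_lo = icer(mid, lo)
            icer_hi = icer(hi, mid)
            if icer_lo.is_ratio and icer_hi.is_ratio and icer_lo.value > icer_hi.value:
                extended.add(mid.strategy)
                candidates.pop(i)
                changed = True
                break

    frontier_names = {r.strategy for r in candidates}
    flags = {
        r.strategy: StrategyFlags(
            dominated=bool(dominated_by[r.strategy]),
            extended_dominated=r.strategy in extended,
            on_frontier=r.strategy in frontier_names,
            dominated_by=tuple(dominated_by[r.strategy]),
            equivalent_to=tuple(equivalent[r.strategy]),
        )
        for r in ordered
    }

    pairwise = {
        (a.strategy, b.strategy): icer(a, b)
        for a in ordered
        for b in ordered
        if a.strategy != b.strategy
    }
    frontier_icers = tuple(
        (hi.strategy, lo.strategy, icer(hi, lo))
        for lo, hi in zip(candidates, candidates[1:])
    )
    return CEAResult(ordered, flags, pairwise, frontier_icers)
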