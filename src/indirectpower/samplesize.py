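"""Exact two-sample t-test power and minimal per-group sample size.

Power for the two-sided, equal-allocation, pooled-variance t-test is computed
from the noncentral t distribution: with n per group, df = 2n - 2 and
noncentrality delta / (sigma * sqrt(2/n)),

    power = P(T > t_{1-alpha/2, df}) + P(T < -t_{1-alpha/2, df}),

including the (negligible but exact) opposite-tail rejection mass.  The
minimal n is found by a normal-approximation start followed by a unit-step
search, so the returned n always satisfies power(n) >= target > power(n - 1).

The study's effect-size convention: the control group's mean change is half
the treated group's, so the between-group difference equals half the treated
change.  Table-style scenario grids support two variance conventions — the
simulated change SD used as the common per-group SD, or that variance doubled
(SD scaled by sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._rng import substream
from .propagation import PropagationResult

__all__ = [
    "PowerQuery",
    "ScenarioCell",
    "analytic_power",
    "required_sample_size",
    "monte_carlo_power",
    "effect_size_from_change",
    "build_scenario_grid",
]

VARIANCE_CONVENTIONS = ("common_sd", "double_variance")


@dataclass(frozen=True)
class PowerQuery:
    """One two-sided, 1:1-allocation two-sample t-test design question."""

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("delta must be non-zero")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (self.alpha < self.power < 1):
            raise ValueError("power must lie in (alpha, 1)")


@dataclass(frozen=True)
class ScenarioCell:
    """One sample-size result in the scenario grid."""

    biomarker_name: str
    power: float
    alpha: float
    rho: float
    variance_convention: str
    sd_used: float
    delta_used: float
    n_per_group: int | None
    note: str = ""

    def __post_init__(self) -> None:
        if self.variance_convention not in VARIANCE_CONVENTIONS:
            raise ValueError(
                f"unknown variance convention {self.variance_convention!r}; "
                f"valid: {VARIANCE_CONVENTIONS}"
            )
        if self.n_per_group is not None and self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def analytic_power(n_per_group: int, query: PowerQuery) -> float:
    """Exact power of the two-sided two-sample t-test with n per group."""
    n = int(n_per_group)
    if n < 2:
        raise ValueError("need n >= 2 per group (df = 2n - 2)")
    df = 2 * n - 2
    ncp = query.delta / (query.sd * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1.0 - query.alpha / 2.0, df)
    # lower tail via the mirrored upper tail, P(T < -t | ncp) = P(T > t | -ncp):
    # numerically stable where the direct deep-lower-tail cdf is not
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.sf(tcrit, df, -ncp))


def required_sample_size(query: PowerQuery) -> int:
    """Smallest per-group n with ``analytic_power(n) >= query.power``.

    Starts from the normal-approximation n and steps by one in either
    direction, so minimality is guaranteed, not assumed.
    """
    za = stats.norm.ppf(1.0 - query.alpha / 2.0)
    zb = stats.norm.ppf(query.power)
    n = max(2, math.ceil(2.0 * ((za + zb) * query.sd / query.delta) ** 2))
    while n > 2 and analytic_power(n - 1, query) >= query.power:
        n -= 1
    while analytic_power(n, query) < query.power:
        n += 1
    return n


def monte_carlo_power(
    n_per_group: int,
    query: PowerQuery,
    reps: int = 200_000,
    seed: int = 0,
) -> float:
    """Simulated power of the pooled two-sample t-test.

    Independent oracle for :func:`analytic_power`: each replicate draws the
    sufficient statistics directly — group means from their normal laws and
    group variances from scaled chi-square laws — which is distributionally
    identical to simulating 2n raw observations.
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError("need n >= 2 per group")
    rng = substream(seed, f"mcpower:{n}:{query.delta}:{query.sd}:{query.alpha}")
    se = query.sd / math.sqrt(n)
    m1 = rng.normal(query.delta, se, size=reps)
    m2 = rng.normal(0.0, se, size=reps)
    v1 = query.sd**2 * rng.chisquare(n - 1, size=reps) / (n - 1)
    v2 = query.sd**2 * rng.chisquare(n - 1, size=reps) / (n - 1)
    sp2 = 0.5 * (v1 + v2)
    tstat = (m1 - m2) / np.sqrt(sp2 * 2.0 / n)
    tcrit = stats.t.ppf(1.0 - query.alpha / 2.0, 2 * n - 2)
    return float(np.mean(np.abs(tstat) > tcrit))


def effect_size_from_change(treated_change_mean: float) -> float:
    """Between-group difference implied by the half-change control convention.

    With the control group's mean change assumed half the treated group's,
    the group difference is |treated change| / 2.
    """
    if treated_change_mean == 0:
        raise ValueError("treated change is zero: no effect to size")
    return abs(treated_change_mean) / 2.0


def build_scenario_grid(
    results: Iterable[PropagationResult],
    powers: Sequence[float] = (0.80, 0.90),
    alphas: Sequence[float] = (0.05, 0.01),
) -> list[ScenarioCell]:
    """One sample-size cell per (result, power, alpha, variance convention).

    ``sd_used`` is the simulated change SD (``common_sd``) or that SD times
    sqrt(2) (``double_variance``); ``delta_used`` is half the simulated
    treated mean change.  A result with zero mean change yields flagged,
    non-computable cells rather than an error.
    """
    results = list(results)
    if not results:
        raise ValueError("no propagation results supplied")
    cells: list[ScenarioCell] = []
    for res in results:
        for power in powers:
            for alpha in alphas:
                for convention in VARIANCE_CONVENTIONS:
                    sd = res.change_sd * (math.sqrt(2.0) if convention == "double_variance" else 1.0)
                    if res.change_mean == 0:
                        cells.append(
                            ScenarioCell(
                                biomarker_name=res.biomarker_name,
                                power=power,
                                alpha=alpha,
                                rho=res.rho_mri,
                                variance_convention=convention,
                                sd_used=sd,
                                delta_used=float("nan"),
                                n_per_group=None,
                                note="not computable: zero mean change",
                            )
                        )
                        continue
                    delta = effect_size_from_change(res.change_mean)
                    n = required_sample_size(
                        PowerQuery(delta=delta, sd=sd, alpha=alpha, power=power)
                    )
                    cells.append(
                        ScenarioCell(
                            biomarker_name=res.biomarker_name,
                            power=power,
                            alpha=alpha,
                            rho=res.rho_mri,
                            variance_convention=convention,
                            sd_used=sd,
                            delta_used=delta,
                            n_per_group=n,
                        )
                    )
    return cells


def desk_check_cell(cell: ScenarioCell) -> bool:
    """Would a reader reproduce this cell from table-rounded inputs?

    Recomputes n using delta from the 1-decimal-rounded mean change and the
    3-decimal-rounded SD, as printed in report tables.  Returns True when the
    rounded-input n matches the pipeline's unrounded-input n; a False flags a
    cell that depends on unrounded simulated values.
    """
    from ._format import round_half_up

    if cell.n_per_group is None:
        return False
    delta_r = round_half_up(2.0 * cell.delta_used, 1) / 2.0
    sd_r = round_half_up(cell.sd_used, 3)
    if delta_r == 0 or sd_r <= 0:
        return False
    n_r = required_sample_size(
        PowerQuery(delta=delta_r, sd=sd_r, alpha=cell.alpha, power=cell.power)
    )
    return n_r == cell.n_per_group
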