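"""Principal-stratum estimation of the complier-average causal effect.

A two-arm trial that offers an incentive to quit smoking partitions mothers
into three latent strata (no defiers, by assumption):

* hardened smokers (HS) — never quit, offered or not (never-takers, pi_n);
* independent quitters (IQ) — quit either way (always-takers, pi_a);
* potential quitters (PQ) — quit only when offered (compliers, pi_c).

Because randomization is independent of stratum, the incentives-arm
continuing smokers identify the HS stratum and the control-arm quitters the
IQ stratum — both their prevalence and their mean outcome.  The remaining
two unobservable means, the potential quitters' outcome with the offer
(w_pqq = mu_c1) and without it (w_pqs = mu_c0), follow by inverting the
weighted-mean decompositions of the incentives-arm quitter cell and the
control-arm smoker cell:

    w_pqq = (w1 * (p_iq + p_pq) - p_iq * w_iq) / p_pq
    w_pqs = (w0 * (p_hs + p_pq) - p_hs * w_hs) / p_pq

Their difference is the CACE.  Algebraically the same number is the Wald /
instrumental-variable ratio (mu1 - mu0) / p_pq — the intention-to-treat
outcome difference scaled up by the compliance gap — and the two routes
agree to machine precision whenever all inputs are computed from one
complete-case record set.  Both are provided, and their identity is the
central internal consistency check of the package.

Assumptions (hard-coded, untestable from the data, always reported):
no defiers (pi_d = 0); exclusion restriction (randomization moves birth
weight only through quitting, so HS and IQ means are arm-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .trial_data import Arm, CrossTab, TrialCohort, TrialDataError, cross_tab

__all__ = [
    "StrataProportions",
    "ObservedCellMeans",
    "StrataMeans",
    "CACEEstimate",
    "EquivalenceReport",
    "EstimationError",
    "strata_proportions",
    "observed_means",
    "solve_potential_quitter_means",
    "cace_intuitive",
    "cace_wald",
    "equivalence_report",
    "estimate_chain",
    "chain_from_cell_stats",
    "ChainStats",
]

#: compliance-gap threshold below which a (re)sampled chain is unidentified
P_PQ_MIN = 1e-6


class EstimationError(ValueError):
    """Raised when an estimator's preconditions fail irrecoverably."""


@dataclass(frozen=True)
class StrataProportions:
    """Latent stratum prevalences; p_defier is fixed at zero by assumption.

    ``p_pq`` can be non-positive in resampled data (control quit rate above
    the incentives quit rate); such instances are flagged invalid and must
    never be fed to the mean inversion.
    """

    p_hs: float  # never-quitters, pi_n
    p_iq: float  # always-quitters, pi_a
    p_pq: float  # compliers, pi_c
    p_defier: float = 0.0

    def __post_init__(self) -> None:
        total = self.p_hs + self.p_iq + self.p_pq + self.p_defier
        if abs(total - 1.0) > 1e-9:
            raise EstimationError(f"stratum proportions sum to {total}, not 1")

    @property
    def valid(self) -> bool:
        return self.p_pq > 0.0


@dataclass(frozen=True)
class ObservedCellMeans:
    """Directly observed cell and arm means entering the inversion."""

    w0: float  # control-arm continuing smokers
    w1: float  # incentives-arm quitters
    mu0: float  # control-arm overall
    mu1: float  # incentives-arm overall


@dataclass(frozen=True)
class StrataMeans:
    """Mean birth weight per latent stratum.

    ``w_hs``/``w_iq`` are observed directly (arm-invariant by the exclusion
    restriction); ``w_pqq``/``w_pqs`` come from the inversion and are
    ``None`` until solved.  A field is ``None`` when its stratum has zero
    estimated mass and no observed cell.
    """

    w_hs: float | None = None
    w_iq: float | None = None
    w_pqq: float | None = None
    w_pqs: float | None = None


@dataclass(frozen=True)
class CACEEstimate:
    """Point estimate of the complier-average causal effect, in grams.

    ``point`` is NaN when the estimate is invalid (``p_pq <= 0``); the
    optional ``interval`` is attached by the uncertainty module.
    """

    point: float
    method: str  # 'intuitive' or 'wald_ratio'
    proportions: StrataProportions | None = None
    interval: tuple[float, float] | None = None

    @property
    def valid(self) -> bool:
        return np.isfinite(self.point)


def strata_proportions(xtab: CrossTab) -> StrataProportions:
    """Estimate stratum prevalences from the arm x quit cross-tab.

    p_hs is the incentives-arm continuing-smoker fraction, p_iq the
    control-arm quitter fraction, p_pq the remainder.  A non-positive
    remainder is returned flagged invalid rather than raising, because the
    bootstrap must be able to count such replicates.
    """
    n1 = xtab.arm_totals[Arm.INCENTIVES].n
    n0 = xtab.arm_totals[Arm.CONTROL].n
    if n1 == 0 or n0 == 0:
        raise EstimationError("both arms need at least one analyzable record")
    p_hs = xtab.cell(Arm.INCENTIVES, False).n / n1
    p_iq = xtab.cell(Arm.CONTROL, True).n / n0
    return StrataProportions(p_hs=p_hs, p_iq=p_iq, p_pq=1.0 - p_hs - p_iq)


def observed_means(xtab: CrossTab) -> tuple[ObservedCellMeans, StrataMeans]:
    """Read the four cell means the inversion needs off the cross-tab.

    Raises naming the offending cell if any referenced cell is empty.
    """
    named = {
        "incentives-arm smokers (w_hs)": (Arm.INCENTIVES, False),
        "control-arm quitters (w_iq)": (Arm.CONTROL, True),
        "control-arm smokers (w0)": (Arm.CONTROL, False),
        "incentives-arm quitters (w1)": (Arm.INCENTIVES, True),
    }
    for name, key in named.items():
        if xtab.cells[key].n == 0:
            raise EstimationError(f"empty cell: {name}")
    cells = ObservedCellMeans(
        w0=xtab.cell(Arm.CONTROL, False).mean,
        w1=xtab.cell(Arm.INCENTIVES, True).mean,
        mu0=xtab.arm_totals[Arm.CONTROL].mean,
        mu1=xtab.arm_totals[Arm.INCENTIVES].mean,
    )
    partial = StrataMeans(
        w_hs=xtab.cell(Arm.INCENTIVES, False).mean,
        w_iq=xtab.cell(Arm.CONTROL, True).mean,
    )
    return cells, partial


def solve_potential_quitter_means(
    props: StrataProportions,
    cells: ObservedCellMeans,
    partial: StrataMeans,
) -> StrataMeans:
    """Invert the weighted-mean decompositions for w_pqq and w_pqs.

    With ``p_iq == 0`` (no always-quitters) the incentives-arm quitter cell
    is pure compliers, so ``w_pqq == w1`` and ``w_iq`` is not needed;
    symmetrically for ``p_hs == 0``.  An invalid ``props`` yields NaN
    sentinels, never an exception.
    """
    if not props.valid:
        return StrataMeans(
            w_hs=partial.w_hs, w_iq=partial.w_iq, w_pqq=np.nan, w_pqs=np.nan
        )
    if props.p_iq > 0 and partial.w_iq is None:
        raise EstimationError("w_iq required when p_iq > 0")
    if props.p_hs > 0 and partial.w_hs is None:
        raise EstimationError("w_hs required when p_hs > 0")
    iq_term = props.p_iq * partial.w_iq if props.p_iq > 0 else 0.0
    hs_term = props.p_hs * partial.w_hs if props.p_hs > 0 else 0.0
    w_pqq = (cells.w1 * (props.p_iq + props.p_pq) - iq_term) / props.p_pq
    w_pqs = (cells.w0 * (props.p_hs + props.p_pq) - hs_term) / props.p_pq
    return StrataMeans(
        w_hs=partial.w_hs, w_iq=partial.w_iq, w_pqq=float(w_pqq), w_pqs=float(w_pqs)
    )


def cace_intuitive(
    strata: StrataMeans, proportions: StrataProportions | None = None
) -> CACEEstimate:
    """CACE as the difference of the two inverted potential-quitter means."""
    if strata.w_pqq is None or strata.w_pqs is None:
        raise EstimationError("potential-quitter means not solved")
    point = strata.w_pqq - strata.w_pqs  # NaN propagates from invalid inputs
    return CACEEstimate(point=float(point), method="intuitive", proportions=proportions)


def cace_wald(xtab: CrossTab) -> CACEEstimate:
    """CACE as the Wald / instrumental-variable ratio (mu1 - mu0) / p_pq."""
    props = strata_proportions(xtab)
    mu1 = xtab.arm_totals[Arm.INCENTIVES].mean
    mu0 = xtab.arm_totals[Arm.CONTROL].mean
    if not props.valid:
        return CACEEstimate(point=float("nan"), method="wald_ratio", proportions=props)
    return CACEEstimate(
        point=(mu1 - mu0) / props.p_pq, method="wald_ratio", proportions=props
    )


@dataclass(frozen=True)
class EquivalenceReport:
    """Side-by-side comparison of the two algebraically identical routes."""

    intuitive: CACEEstimate
    wald: CACEEstimate
    abs_difference: float
    both_valid: bool


def estimate_chain(
    cohort: TrialCohort,
) -> tuple[CrossTab, StrataProportions, ObservedCellMeans, StrataMeans, CACEEstimate]:
    """Run the full estimator chain on one cohort (complete case throughout)."""
    xtab = cross_tab(cohort)
    props = strata_proportions(xtab)
    if not props.valid:
        nanmeans = StrataMeans(w_pqq=np.nan, w_pqs=np.nan)
        est = CACEEstimate(point=float("nan"), method="intuitive", proportions=props)
        return xtab, props, None, nanmeans, est
    cells, partial = observed_means(xtab)
    means = solve_potential_quitter_means(props, cells, partial)
    est = cace_intuitive(means, props)
    return xtab, props, cells, means, est


def equivalence_report(cohort: TrialCohort) -> EquivalenceReport:
    """Compute the CACE by both routes from the same complete-case records.

    When both are valid their absolute difference is asserted below 1e-6 g —
    the identity is exact algebra, so a larger gap indicates a defect.
    """
    xtab, props, _, means, intuitive = estimate_chain(cohort)
    wald = cace_wald(xtab)
    both_valid = intuitive.valid and wald.valid
    diff = abs(intuitive.point - wald.point) if both_valid else float("nan")
    if both_valid and diff >= 1e-6:
        raise EstimationError(
            f"intuitive and Wald estimates diverge by {diff} g on shared records"
        )
    return EquivalenceReport(
        intuitive=intuitive, wald=wald, abs_difference=diff, both_valid=both_valid
    )


# ---------------------------------------------------------------------------
# vectorized cell-statistics chain (bootstrap / jackknife fast path)


class ChainStats(NamedTuple):
    """Full estimator chain evaluated from sufficient cell statistics.

    Every field is an ndarray (or scalar) broadcast over replicates; entries
    are NaN wherever ``valid`` is False.
    """

    p_hs: np.ndarray
    p_iq: np.ndarray
    p_pq: np.ndarray
    w_hs: np.ndarray
    w_iq: np.ndarray
    w0: np.ndarray
    w1: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    w_pqq: np.ndarray
    w_pqs: np.ndarray
    cace: np.ndarray
    valid: np.ndarray


def chain_from_cell_stats(
    n0, nq0, sum0, sumq0, n1, nq1, sum1, sumq1, p_pq_min: float = P_PQ_MIN
) -> ChainStats:
    """Evaluate the whole chain from per-arm counts and weight sums.

    Inputs are (arrays of) the control-arm size ``n0``, its quitter count
    ``nq0``, its weight total ``sum0`` and quitter weight total ``sumq0``,
    and the same four for the incentives arm.  A replicate is valid when
    both arms and all four arm x quit cells are nonempty and the compliance
    gap exceeds ``p_pq_min``; elsewhere all estimates are NaN.

    This is the single code path the bootstrap and jackknife share; it is
    checked against the record-level dataclass chain in the test suite.
    """
    n0 = np.asarray(n0, dtype=float)
    nq0 = np.asarray(nq0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    nq1 = np.asarray(nq1, dtype=float)
    sum0 = np.asarray(sum0, dtype=float)
    sumq0 = np.asarray(sumq0, dtype=float)
    sum1 = np.asarray(sum1, dtype=float)
    sumq1 = np.asarray(sumq1, dtype=float)
    ns0, ns1 = n0 - nq0, n1 - nq1  # continuing smokers per arm
    with np.errstate(divide="ignore", invalid="ignore"):
        p_iq = np.where(n0 > 0, nq0 / n0, np.nan)
        p_hs = np.where(n1 > 0, ns1 / n1, np.nan)
        p_pq = 1.0 - p_hs - p_iq
        w_iq = np.where(nq0 > 0, sumq0 / nq0, np.nan)
        w0 = np.where(ns0 > 0, (sum0 - sumq0) / ns0, np.nan)
        w1 = np.where(nq1 > 0, sumq1 / nq1, np.nan)
        w_hs = np.where(ns1 > 0, (sum1 - sumq1) / ns1, np.nan)
        mu0 = np.where(n0 > 0, sum0 / n0, np.nan)
        mu1 = np.where(n1 > 0, sum1 / n1, np.nan)
        valid = (
            (n0 > 0)
            & (n1 > 0)
            & (nq0 > 0)
            & (ns0 > 0)
            & (nq1 > 0)
            & (ns1 > 0)
            & (p_pq > p_pq_min)
        )
        w_pqq = np.where(
            valid, (w1 * (p_iq + p_pq) - p_iq * w_iq) / p_pq, np.nan
        )
        w_pqs = np.where(
            valid, (w0 * (p_hs + p_pq) - p_hs * w_hs) / p_pq, np.nan
        )
        cace = w_pqq - w_pqs
    return ChainStats(
        p_hs=p_hs, p_iq=p_iq, p_pq=p_pq, w_hs=w_hs, w_iq=w_iq, w0=w0, w1=w1,
        mu0=mu0, mu1=mu1, w_pqq=w_pqq, w_pqs=w_pqs, cace=cace, valid=valid,
    )


def chain_from_arrays(arm: np.ndarray, quit: np.ndarray, weight: np.ndarray) -> ChainStats:
    """Chain evaluation from complete-case record arrays (scalar output)."""
    arm = np.asarray(arm, dtype=bool)
    quit = np.asarray(quit, dtype=bool)
    weight = np.asarray(weight, dtype=float)
    inc, ctl = arm, ~arm
    return chain_from_cell_stats(
        n0=ctl.sum(),
        nq0=(ctl & quit).sum(),
        sum0=weight[ctl].sum(),
        sumq0=weight[ctl & quit].sum(),
        n1=inc.sum(),
        nq1=(inc & quit).sum(),
        sum1=weight[inc].sum(),
        sumq1=weight[inc & quit].sum(),
    )
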