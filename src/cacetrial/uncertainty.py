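"""Nonparametric bootstrap and BCa intervals for the stratum-mean chain.

The whole estimator chain (four subgroup means plus the CACE) is recomputed
on every resample of the analyzable records, and 95% bias-corrected and
accelerated (BCa) intervals are formed from the replicate distributions.

Resampling schemes
------------------
``within_arm`` (default) resamples records with replacement separately
within each arm, preserving the randomized arm sizes; ``whole_cohort``
resamples the pooled analyzable records, so arm sizes vary binomially.
Replicates on which the chain is unidentified — an empty arm or arm x quit
cell, or a compliance gap at or below 1e-6 — are counted and excluded from
the stored draws; the ratio estimator is undefined there.

BCa
---
With B draws theta*_b and point estimate theta-hat, the bias-correction
constant is z0 = Phi^-1(#{theta*_b < theta-hat} / B) and the acceleration
a = sum(d_i^3) / (6 * (sum(d_i^2))^(3/2)) with d_i the deviations of the
leave-one-record-out (jackknife) estimates from their mean.  The nominal
tail probabilities are shifted to Phi(z0 + (z0 + z_alpha)/(1 - a(z0 +
z_alpha))), clipped to [1/(B+1), B/(B+1)], and read off the empirical draw
distribution by linear-interpolation quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .strata import P_PQ_MIN, EstimationError, chain_from_arrays, chain_from_cell_stats
from .trial_data import TrialCohort

log = logging.getLogger(__name__)

__all__ = [
    "BootstrapDraws",
    "BcaInterval",
    "bootstrap_estimates",
    "jackknife_estimates",
    "bca_interval",
    "subgroup_intervals",
    "QUANTITIES",
]

#: chain quantities tracked through the bootstrap, in report order
QUANTITIES = ("w_hs", "w_pqs", "w_pqq", "w_iq", "cace")


@dataclass(frozen=True)
class BootstrapDraws:
    """Per-replicate chain estimates, valid replicates only."""

    estimates: dict[str, np.ndarray]  # keyed by QUANTITIES, equal lengths
    n_replicates: int
    n_valid: int
    seed: int
    scheme: str

    def __post_init__(self) -> None:
        for name, arr in self.estimates.items():
            if arr.size != self.n_valid:
                raise EstimationError(f"draw array {name} length mismatch")
            if arr.size and not np.all(np.isfinite(arr)):
                raise EstimationError(f"non-finite stored draw in {name}")


def _resample_cell_stats(rngs, arm, quit, weight, n_rep, scheme):
    """Sufficient cell statistics for ``n_rep`` resamples (vectorized).

    ``rngs`` holds one generator per arm (within_arm) or a single one
    (whole_cohort), so batching never changes the draw stream.
    """
    qf = quit.astype(float)
    if scheme == "within_arm":
        out = {}
        for rng, (label, mask) in zip(rngs, (("0", ~arm), ("1", arm))):
            w, q = weight[mask], qf[mask]
            n = w.size
            idx = rng.integers(0, n, size=(n_rep, n))
            Q, W = q[idx], w[idx]
            out["n" + label] = np.full(n_rep, float(n))
            out["nq" + label] = Q.sum(axis=1)
            out["sum" + label] = W.sum(axis=1)
            out["sumq" + label] = (W * Q).sum(axis=1)
        return out
    elif scheme == "whole_cohort":
        n = weight.size
        idx = rngs[0].integers(0, n, size=(n_rep, n))
        A, Q, W = arm[idx], qf[idx], weight[idx]
        n1 = A.sum(axis=1, dtype=float)
        return {
            "n0": n - n1,
            "nq0": (Q * ~A).sum(axis=1),
            "sum0": (W * ~A).sum(axis=1),
            "sumq0": (W * Q * ~A).sum(axis=1),
            "n1": n1,
            "nq1": (Q * A).sum(axis=1),
            "sum1": (W * A).sum(axis=1),
            "sumq1": (W * Q * A).sum(axis=1),
        }
    raise ValueError(f"unknown scheme {scheme!r}")


def bootstrap_estimates(
    cohort: TrialCohort,
    n_replicates: int,
    seed: int,
    scheme: str = "within_arm",
    batch_size: int = 2000,
) -> BootstrapDraws:
    """Resample the analyzable records and recompute the chain per replicate.

    Bit-identical output for identical (cohort, n_replicates, seed, scheme).
    Batched to bound memory at ~batch_size x n intermediate arrays.
    """
    if n_replicates < 1:
        raise EstimationError("n_replicates must be >= 1")
    arm, quit, weight = cohort.analyzable_arrays()
    if arm.size == 0 or arm.all() or not arm.any():
        raise EstimationError("both arms need analyzable records to bootstrap")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(2)]
    kept: dict[str, list[np.ndarray]] = {q: [] for q in QUANTITIES}
    n_valid = 0
    done = 0
    while done < n_replicates:
        b = min(batch_size, n_replicates - done)
        stats = _resample_cell_stats(rngs, arm, quit, weight, b, scheme)
        chain = chain_from_cell_stats(**stats)
        ok = chain.valid
        n_valid += int(ok.sum())
        for q in QUANTITIES:
            kept[q].append(getattr(chain, q)[ok])
        done += b
    if n_valid == 0:
        raise EstimationError(
            "no valid bootstrap replicate (compliance gap never positive); "
            "a larger cohort or the within_arm scheme may help"
        )
    estimates = {q: np.concatenate(kept[q]) for q in QUANTITIES}
    return BootstrapDraws(
        estimates=estimates,
        n_replicates=n_replicates,
        n_valid=n_valid,
        seed=seed,
        scheme=scheme,
    )


def jackknife_estimates(cohort: TrialCohort) -> dict[str, np.ndarray]:
    """Leave-one-record-out chain estimates over the analyzable records.

    Computed in one vectorized pass by subtracting each record's
    contribution from the full-sample cell statistics.  Jackknife points on
    which the reduced chain is unidentified come back NaN and are dropped
    by :func:`bca_interval`'s caller.
    """
    arm, quit, weight = cohort.analyzable_arrays()
    inc, ctl = arm, ~arm
    q = quit
    N0, NQ0 = ctl.sum(), (ctl & q).sum()
    S0, SQ0 = weight[ctl].sum(), weight[ctl & q].sum()
    N1, NQ1 = inc.sum(), (inc & q).sum()
    S1, SQ1 = weight[inc].sum(), weight[inc & q].sum()
    chain = chain_from_cell_stats(
        n0=N0 - ctl,
        nq0=NQ0 - (ctl & q),
        sum0=S0 - weight * ctl,
        sumq0=SQ0 - weight * (ctl & q),
        n1=N1 - inc,
        nq1=NQ1 - (inc & q),
        sum1=S1 - weight * inc,
        sumq1=SQ1 - weight * (inc & q),
    )
    return {name: getattr(chain, name) for name in QUANTITIES}


@dataclass(frozen=True)
class BcaInterval:
    """BCa interval with its bias-correction and acceleration constants."""

    lower: float
    upper: float
    level: float
    z0: float
    a: float
    n_valid: int

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise EstimationError("interval endpoints out of order")


def _quantile(sorted_draws: np.ndarray, p: float) -> float:
    """Linear-interpolation empirical quantile on pre-sorted draws."""
    return float(np.quantile(sorted_draws, p, method="linear"))


def bca_interval(
    draws: np.ndarray,
    point: float,
    jackknife_values: np.ndarray,
    level: float = 0.95,
) -> BcaInterval:
    """Bias-corrected and accelerated interval from bootstrap draws.

    ``draws`` are the valid replicate estimates, ``point`` the full-sample
    estimate, ``jackknife_values`` the leave-one-out estimates of the same
    statistic (NaNs tolerated and dropped).  Degenerate draw distributions
    give a zero-width interval; a fraction-below of 0 or 1 is clamped to
    the clipping bound with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise EstimationError("no bootstrap draws")
    if not (0.0 < level < 1.0):
        raise EstimationError("level must be in (0, 1)")
    B = draws.size
    if np.all(draws == draws[0]):
        c = float(draws[0])
        return BcaInterval(lower=c, upper=c, level=level, z0=0.0, a=0.0, n_valid=B)
    lo_clip, hi_clip = 1.0 / (B + 1), B / (B + 1)
    frac_below = float(np.mean(draws < point))
    if frac_below <= 0.0 or frac_below >= 1.0:
        log.warning(
            "all bootstrap draws on one side of the point estimate "
            "(fraction below = %g); z0 clamped", frac_below,
        )
        frac_below = lo_clip if frac_below <= 0.0 else hi_clip
    z0 = float(norm.ppf(frac_below))
    jack = np.asarray(jackknife_values, dtype=float)
    jack = jack[np.isfinite(jack)]
    if jack.size >= 2:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2)) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    sorted_draws = np.sort(draws)
    alpha = (1.0 - level) / 2.0
    endpoints = []
    for tail in (alpha, 1.0 - alpha):
        z = norm.ppf(tail)
        denom = 1.0 - a * (z0 + z)
        if denom <= 0:
            # acceleration pathologically large: pin to the admissible bound
            p = hi_clip if z0 + z > 0 else lo_clip
            log.warning("BCa denominator nonpositive at tail %g; clipped", tail)
        else:
            p = float(norm.cdf(z0 + (z0 + z) / denom))
        p = min(max(p, lo_clip), hi_clip)
        endpoints.append(_quantile(sorted_draws, p))
    lower, upper = sorted(endpoints)
    return BcaInterval(lower=lower, upper=upper, level=level, z0=z0, a=a, n_valid=B)


def subgroup_intervals(
    cohort: TrialCohort,
    n_replicates: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    scheme: str = "within_arm",
) -> pd.DataFrame:
    """Point estimates and BCa intervals for the four subgroup means + CACE.

    One bootstrap run and one jackknife sweep feed all five rows; rows are
    ordered hardened smokers, potential quitters without / with the offer,
    independent quitters, then the causal difference.
    """
    arm, quit, weight = cohort.analyzable_arrays()
    points = chain_from_arrays(arm, quit, weight)
    if not bool(points.valid):
        raise EstimationError("chain unidentified on the full cohort")
    draws = bootstrap_estimates(cohort, n_replicates, seed=seed, scheme=scheme)
    jack = jackknife_estimates(cohort)
    log.info(
        "bootstrap: %d of %d replicates valid (scheme=%s, seed=%d)",
        draws.n_valid, draws.n_replicates, scheme, seed,
    )
    rows = []
    for qty in QUANTITIES:
        point = float(getattr(points, qty))
        ci = bca_interval(draws.estimates[qty], point, jack[qty], level=level)
        rows.append(
            {
                "quantity": qty,
                "point": point,
                "lower": ci.lower,
                "upper": ci.upper,
                "level": level,
                "n_valid": draws.n_valid,
                "z0": ci.z0,
                "a": ci.a,
            }
        )
    return pd.DataFrame(rows)
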