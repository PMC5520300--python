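"""Sample-size and power under compliance dilution.

A complier-level effect delta_c on birth weight shows up between randomized
arms only as the diluted intention-to-treat difference pi_c * delta_c, where
pi_c is the compliance gap (the fraction who quit only because of the
offer).  Designing a trial to detect the diluted difference with a
two-sided two-sample t test then drives the per-group sample size:

    n/group ~= 2 * (sd / (pi_c * delta_c))^2 * (z_{1-alpha/2} + z_{power})^2

The default solver iterates the exact noncentral-t power (degrees of
freedom 2n - 2, noncentrality (pi_c * delta_c)/sd * sqrt(n/2)) and returns
the smallest n meeting the target; the closed-form normal approximation is
available as a cross-check and typically agrees within a participant or
two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import nct, norm
from scipy.stats import t as t_dist

__all__ = [
    "PowerSpec",
    "PowerResult",
    "itt_effect",
    "power_at_n",
    "sample_size_two_sample_t",
    "design",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs: complier effect (g), compliance gap, outcome SD (g)."""

    delta_complier: float
    pi_c: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.delta_complier <= 0 or self.sd <= 0:
            raise ValueError("effect size and SD must be positive")
        if not (0.0 < self.pi_c <= 1.0):
            raise ValueError("pi_c must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    delta_itt: float
    n_per_group: int
    n_total: int
    achieved_power: float

    def __post_init__(self) -> None:
        if self.n_total != 2 * self.n_per_group:
            raise ValueError("n_total must equal 2 * n_per_group")


def itt_effect(delta_complier: float, pi_c: float) -> float:
    """Diluted between-arm effect: pi_c * delta_complier."""
    if pi_c <= 0:
        raise ValueError("pi_c must be positive")
    return pi_c * delta_complier


def power_at_n(n_per_group: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t test at equal group sizes.

    Noncentral-t alternative with noncentrality delta/sd * sqrt(n/2) and
    2n - 2 degrees of freedom.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    df = 2 * n_per_group - 2
    ncp = (delta / sd) * math.sqrt(n_per_group / 2.0)
    t_crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - nct.cdf(t_crit, df, ncp) + nct.cdf(-t_crit, df, ncp))


def _n_normal_approx(delta: float, sd: float, alpha: float, power: float) -> int:
    z = norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)
    return math.ceil(2.0 * (sd / delta) ** 2 * z**2)


def sample_size_two_sample_t(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "t",
) -> int:
    """Smallest per-group n reaching the target power (two-sided test).

    ``method='t'`` (default) solves the noncentral-t power iteratively,
    seeded by the normal approximation; ``method='normal'`` returns the
    closed form directly.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    n = max(2, _n_normal_approx(delta, sd, alpha, power))
    if method == "normal":
        return n
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    while power_at_n(n, delta, sd, alpha) < power:
        n += 1
    while n > 2 and power_at_n(n - 1, delta, sd, alpha) >= power:
        n -= 1
    return n


def design(spec: PowerSpec, method: str = "t") -> PowerResult:
    """Full diluted design: ITT effect, required n, achieved power."""
    delta_itt = itt_effect(spec.delta_complier, spec.pi_c)
    n = sample_size_two_sample_t(delta_itt, spec.sd, spec.alpha, spec.power, method)
    return PowerResult(
        delta_itt=delta_itt,
        n_per_group=n,
        n_total=2 * n,
        achieved_power=power_at_n(n, delta_itt, spec.sd, spec.alpha),
    )
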