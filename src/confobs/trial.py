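"""Power-based sample-size calculation for a paired design.

The paired design is analysed as a one-sample t-test on within-patient
changes (null: mean change 0). Power uses the exact noncentral t
distribution: with effect size d = mean/SD and n pairs, the test
statistic under the alternative is noncentral t with n-1 degrees of
freedom and noncentrality d*sqrt(n), and one-tailed power is
P(T' > t_{1-alpha, n-1}). The exact t-based computation matters: the
normal approximation systematically understates n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TrialDesign:
    """Paired-change design: expected mean change, its SD, alpha, the
    target power and tail count (1 or 2)."""

    mean: float
    sd: float
    alpha: float = 0.05
    power: float = 0.90
    tails: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")

    @property
    def effect_size(self) -> float:
        """Standardised effect d = mean / SD."""
        return self.mean / self.sd


def power_paired_t(design: TrialDesign, n: int) -> float:
    """Exact power of the paired t-test at n pairs.

    One-tailed: P(T' > t_{1-alpha, n-1}) with T' noncentral t, ncp
    d*sqrt(n). Two-tailed adds the (negligible for positive effects)
    opposite-tail rejection mass at alpha/2 per tail.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    df = n - 1
    ncp = design.effect_size * np.sqrt(n)
    if design.tails == 1:
        tcrit = stats.t.ppf(1.0 - design.alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    tcrit = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def minimal_n(design: TrialDesign, n_max: int = 100_000) -> int:
    """Smallest n with power >= the design target, by upward scan from 2."""
    if design.mean == 0:
        raise ValueError("zero effect: target power unreachable")
    for n in range(2, n_max + 1):
        if power_paired_t(design, n) >= design.power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


def normal_approx_n(design: TrialDesign) -> float:
    """Normal-approximation sample size ((z_{1-a} + z_{power})/d)^2.

    A lower bound on the exact t-based n; exposed for sanity checks.
    """
    alpha = design.alpha / design.tails if design.tails == 2 else design.alpha
    za = stats.norm.ppf(1.0 - alpha)
    zb = stats.norm.ppf(design.power)
    return float(((za + zb) / design.effect_size) ** 2)
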