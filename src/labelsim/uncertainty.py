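"""Uncertain scalar parameters and their Monte Carlo sampling rule.

Every uncertain model input (label effect sizes, label coverage, relative
risks per BMI unit, mortality trend slopes) is carried as an
:class:`UncertainQuantity`: a point estimate with a 95% confidence interval
and a declared sampling scale.  Monte Carlo draws are normal on that scale,
centred at the point estimate, with the standard deviation recovered from
the interval width (``(hi - lo) / (2 * 1.96)``), optionally truncated to
hard bounds (e.g. coverage fractions live in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
from scipy import stats

from .errors import ConfigurationError

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class UncertainQuantity:
    """Point estimate + 95% CI + sampling rule.

    Parameters
    ----------
    point : float
        Central estimate.
    ci_low, ci_high : float
        95% confidence interval endpoints (on the natural scale of the
        quantity, whatever the sampling scale).
    scale : {"natural", "log"}
        Scale on which Monte Carlo draws are normal.  "log" is used for
        relative risks (multiplicative quantities).
    bounds : tuple[float, float] | None
        Optional hard truncation interval for draws.
    """

    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    scale: str = "natural"
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo = self.point if self.ci_low is None else self.ci_low
        hi = self.point if self.ci_high is None else self.ci_high
        object.__setattr__(self, "ci_low", float(lo))
        object.__setattr__(self, "ci_high", float(hi))
        if self.ci_high < self.ci_low:
            raise ConfigurationError(
                f"ci_high < ci_low ({self.ci_high} < {self.ci_low})"
            )
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ConfigurationError(
                f"point {self.point} outside CI [{self.ci_low}, {self.ci_high}]"
            )
        if self.scale not in ("natural", "log"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.ci_low <= 0:
            raise ConfigurationError("log-scale quantity needs a positive CI")
        if self.bounds is not None:
            lo_b, hi_b = self.bounds
            if not (lo_b <= self.point <= hi_b):
                raise ConfigurationError("truncation bounds must contain the point")

    @property
    def sd(self) -> float:
        """Implied normal standard deviation on the sampling scale."""
        if self.scale == "log":
            return (log(self.ci_high) - log(self.ci_low)) / (2.0 * _Z95)
        return (self.ci_high - self.ci_low) / (2.0 * _Z95)

    @property
    def is_degenerate(self) -> bool:
        return self.ci_low == self.ci_high

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the quantity's sampling distribution.

        Degenerate intervals (lo == hi) always return the point estimate but
        still consume one uniform from ``rng`` so that draw streams stay
        aligned whether or not a parameter is uncertain.
        """
        u = rng.random(size)
        if self.is_degenerate:
            return self.point if size is None else np.full(size, self.point)
        if self.scale == "log":
            mu, sd = log(self.point), self.sd
        else:
            mu, sd = self.point, self.sd
        if self.bounds is not None:
            lo, hi = self.bounds
            if self.scale == "log":
                lo = log(lo) if lo > 0 else -np.inf
                hi = log(hi) if np.isfinite(hi) else np.inf
            a, b = (lo - mu) / sd, (hi - mu) / sd
            x = mu + sd * stats.truncnorm.ppf(u, a, b)
        else:
            x = mu + sd * stats.norm.ppf(u)
        if self.scale == "log":
            x = np.exp(x)
        return float(x) if size is None else x


def sample_quantity(q: UncertainQuantity, rng: np.random.Generator, size=None):
    """Functional alias for :meth:`UncertainQuantity.sample`."""
    return q.sample(rng, size)


def exact(value: float, **kwargs) -> UncertainQuantity:
    """An UncertainQuantity with zero sampling uncertainty."""
    return UncertainQuantity(point=value, ci_low=value, ci_high=value, **kwargs)
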