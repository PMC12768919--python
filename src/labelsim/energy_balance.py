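"""Energy-conservation body-weight dynamics.

A sustained change ``dE`` (kcal/day) in energy intake moves body weight
toward a new equilibrium because total energy expenditure rises roughly
linearly with body mass: with marginal expenditure ``k`` (kcal/day per kg)
and an energy density of tissue change ``rho`` (kcal per kg), the gap
``G = W_scenario - W_baseline`` obeys

    dG/dt = (dE - k * G) / rho,

a first-order relaxation toward ``G* = dE / k`` with time constant
``tau = rho / k`` (about 0.88 years at the defaults ``k = 24``,
``rho = 7700``).  The update used here is the exact exponential solution of
that ODE, so annual discrete time introduces no integration error.
Scenario dynamics are expressed as a gap superimposed on the baseline
secular weight trajectory, so policy effects and background BMI trends
compose cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, EmptyDenominatorError

DAYS_PER_YEAR = 365.25
OBESITY_BMI = 30.0  # BMI >= 30 kg/m2 counts as obese (inclusive boundary)


@dataclass(frozen=True)
class EnergyBalanceParams:
    """Coefficients of the weight-change prediction formula.

    k : kcal/day of extra expenditure per kg of body mass.
    rho : kcal stored/released per kg of body-mass change.
    """

    k: float = 24.0
    rho: float = 7700.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError("marginal expenditure k must be positive")
        if self.rho <= 0:
            raise ConfigurationError("tissue energy density rho must be positive")

    @property
    def tau_years(self) -> float:
        """Relaxation time constant in years."""
        return self.rho / (self.k * DAYS_PER_YEAR)


def equilibrium_weight_change(delta_e, params: EnergyBalanceParams):
    """Asymptotic weight change (kg) under a sustained intake change."""
    return np.asarray(delta_e, dtype=float) / params.k if np.ndim(delta_e) \
        else delta_e / params.k


def gap_step(gap, delta_e, params: EnergyBalanceParams, dt: float = 1.0):
    """Advance the scenario-baseline weight gap by ``dt`` years (exact)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    decay = np.exp(-dt / params.tau_years)
    return gap * decay + (np.asarray(delta_e, dtype=float) / params.k) * (1.0 - decay)


def weight_step(current_weight, baseline_weight_this_year, delta_e,
                params: EnergyBalanceParams, dt: float = 1.0):
    """Next weight after ``dt`` years of sustained intake change ``delta_e``.

    The gap from the baseline trajectory relaxes toward ``delta_e / k``;
    the caller supplies the baseline weight so secular drift is carried by
    the baseline, not by this update.
    """
    gap = np.asarray(current_weight, dtype=float) - baseline_weight_this_year
    return baseline_weight_this_year + gap_step(gap, delta_e, params, dt)


def bmi_from_weight(weight, height):
    """BMI (kg/m2) from weight (kg) and height (m)."""
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise DomainError("height must be positive")
    out = np.asarray(weight, dtype=float) / height**2
    return float(out) if out.ndim == 0 else out


def obesity_prevalence(bmi, mask=None, threshold: float = OBESITY_BMI) -> float:
    """Fraction of the (masked) group with BMI at or above the threshold."""
    bmi = np.asarray(bmi, dtype=float)
    if mask is not None:
        bmi = bmi[np.asarray(mask, dtype=bool)]
    if bmi.size == 0:
        raise EmptyDenominatorError("obesity prevalence over an empty group")
    return float(np.mean(bmi >= threshold))
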