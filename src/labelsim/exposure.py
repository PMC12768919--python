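"""Packaged-food energy and policy-induced daily energy changes.

The causal chain starts from total daily energy intake.  A fixed share of
it comes from at-home food purchases (55%), of which a fixed share is
packaged (80%); label effects act only on the labelled fraction of that
packaged energy (the coverage).  The consumer-behaviour and reformulation
effects compose multiplicatively on labelled energy — reformulation trims
the energy content of what the (already label-responsive) consumer still
buys — so the combined relative reduction is ``1 - (1-e_cons)(1-e_ref)``.

All functions are vectorised: ``total_intake`` may be a scalar or an array
of per-individual intakes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .scenarios import LabelPolicy, PolicyDraw, coverage_at


@dataclass(frozen=True)
class PackagedShareParams:
    """Shares routing total intake to in-store packaged food."""

    at_home_share: float = 0.55
    packaged_share: float = 0.80

    def __post_init__(self) -> None:
        for name in ("at_home_share", "packaged_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class EnergyDelta:
    """Per-day energy change vs the same-year baseline intake (kcal/day).

    ``delta_total`` composes the components sequentially: consumer response
    first, reformulation applied to the energy the consumer still buys, so
    ``delta_total = delta_consumer + delta_reformulation`` holds exactly
    under the declared composition rule.
    """

    delta_consumer: np.ndarray | float
    delta_reformulation: np.ndarray | float
    delta_total: np.ndarray | float


def packaged_energy(total_intake, params: PackagedShareParams = PackagedShareParams()):
    """Daily energy (kcal/day) from packaged in-store food."""
    total_intake = np.asarray(total_intake, dtype=float)
    if np.any(total_intake < 0):
        raise DomainError("total intake must be non-negative")
    out = total_intake * params.at_home_share * params.packaged_share
    return float(out) if out.ndim == 0 else out


def combined_relative_reduction(e_consumer: float, e_reformulation: float) -> float:
    """Relative reduction on labelled energy when both pathways act."""
    return 1.0 - (1.0 - e_consumer) * (1.0 - e_reformulation)


def policy_energy_delta(total_intake, e_consumer: float, e_reformulation: float,
                        coverage: float, components: str = "both",
                        params: PackagedShareParams = PackagedShareParams(),
                        ) -> EnergyDelta:
    """Energy change (kcal/day) induced by a sampled policy.

    Labelled energy ``L = packaged_energy * coverage``; the consumer effect
    removes ``L * e_consumer``; reformulation removes ``e_reformulation`` of
    the remaining labelled energy when both components act, or ``L *
    e_reformulation`` alone.  Deltas are negative for energy reductions.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ConfigurationError("sampled coverage must lie in [0, 1]")
    labelled = packaged_energy(total_intake, params) * coverage
    if components == "consumer":
        d_cons = -labelled * e_consumer
        d_ref = np.zeros_like(np.asarray(labelled)) if np.ndim(labelled) else 0.0
    elif components == "reformulation":
        d_cons = np.zeros_like(np.asarray(labelled)) if np.ndim(labelled) else 0.0
        d_ref = -labelled * e_reformulation
    elif components == "both":
        d_cons = -labelled * e_consumer
        d_ref = -labelled * (1.0 - e_consumer) * e_reformulation
    else:
        raise ConfigurationError(f"unknown components {components!r}")
    return EnergyDelta(delta_consumer=d_cons, delta_reformulation=d_ref,
                       delta_total=d_cons + d_ref)


def intake_trajectory(baseline_intake_by_year, policy: LabelPolicy,
                      draw: PolicyDraw, years, implementation_year: int = 2024,
                      params: PackagedShareParams = PackagedShareParams()):
    """Post-policy intake per year for one individual (or intake vector).

    The label has an immediate effect from the implementation year onward
    and the relative effect stays constant thereafter (apart from coverage
    schedule steps), tracking the baseline's own secular trajectory.
    """
    years = list(years)
    out = []
    for y, base in zip(years, baseline_intake_by_year):
        if y < implementation_year or policy.is_null:
            out.append(np.asarray(base, dtype=float) + 0.0)
            continue
        cov = coverage_at(policy, y - implementation_year, draw)
        delta = policy_energy_delta(base, draw.consumer_effect,
                                    draw.reformulation_effect, cov,
                                    policy.components, params)
        out.append(np.asarray(base, dtype=float) + delta.delta_total)
    return np.asarray(out)
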