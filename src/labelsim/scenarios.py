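"""Front-of-pack label policy scenarios and Monte Carlo parameter draws.

A :class:`LabelPolicy` bundles the three levers through which a label
changes diet: the consumer-behaviour effect (relative reduction in energy
purchased from labelled packaged food), the reformulation effect (relative
reduction in the energy content of labelled products), and a label-coverage
schedule (the fraction of packaged products actually carrying the label,
possibly stepping over time).  Effects are stored as positive reduction
fractions, so 0.065 means "6.5% less energy".

:func:`builtin_scenarios` provides the evaluated policy presets: mandatory
traffic-light labelling (TLL), mandatory nutrient-warning labelling (NWL),
and the one-way sensitivity variants (NWL coverage drop, Chile's black
octagon, low TLL reformulation, Nutri-Score).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .uncertainty import UncertainQuantity, exact, sample_quantity

__all__ = [
    "CoverageSchedule", "LabelPolicy", "ScenarioSet", "PolicyDraw",
    "ParameterDraw", "builtin_scenarios", "coverage_at", "sample_policy",
    "sample_quantity", "scenario_rng",
]

COMPONENT_CHOICES = ("consumer", "reformulation", "both")


@dataclass(frozen=True)
class CoverageSchedule:
    """Step function of label coverage vs years since implementation."""

    steps: tuple  # ((from_year_offset, UncertainQuantity), ...)

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.steps]
        if not offsets or offsets[0] != 0:
            raise ConfigurationError("coverage schedule must start at offset 0")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ConfigurationError("coverage offsets must be strictly increasing")
        for _, q in self.steps:
            if not (0.0 <= q.ci_low and q.ci_high <= 1.0):
                raise ConfigurationError("coverage CIs must lie within [0, 1]")

    @classmethod
    def constant(cls, q: UncertainQuantity) -> "CoverageSchedule":
        return cls(steps=((0, q),))

    def step_index(self, years_since_implementation: int) -> int:
        idx = 0
        for i, (offset, _) in enumerate(self.steps):
            if offset <= years_since_implementation:
                idx = i
        return idx


def _coverage_uq(point, lo=None, hi=None) -> UncertainQuantity:
    return UncertainQuantity(point, lo, hi, bounds=(0.0, 1.0))


@dataclass(frozen=True)
class LabelPolicy:
    """One policy scenario: effect sizes plus a coverage schedule."""

    name: str
    consumer_effect: UncertainQuantity
    reformulation_effect: UncertainQuantity
    coverage: CoverageSchedule
    components: str = "both"

    def __post_init__(self) -> None:
        if self.components not in COMPONENT_CHOICES:
            raise ConfigurationError(
                f"components must be one of {COMPONENT_CHOICES}"
            )

    @property
    def is_null(self) -> bool:
        return (self.consumer_effect.is_degenerate
                and self.consumer_effect.point == 0.0
                and self.reformulation_effect.is_degenerate
                and self.reformulation_effect.point == 0.0)

    def component_variant(self, components: str) -> "LabelPolicy":
        """Same policy evaluated with only one causal pathway enabled."""
        if components == self.components:
            return self
        return replace(self, name=f"{self.name}:{components}",
                       components=components)


class ScenarioSet(dict):
    """Named collection of scenarios (a dict with an ``add`` helper)."""

    def add(self, policy: LabelPolicy) -> None:
        if policy.name in self:
            raise ConfigurationError(f"duplicate scenario name {policy.name!r}")
        self[policy.name] = policy

    def subset(self, names) -> "ScenarioSet":
        out = ScenarioSet()
        for n in names:
            out.add(self[n])
        return out


def builtin_scenarios() -> ScenarioSet:
    """The evaluated label policies and sensitivity variants.

    Effect sizes are the headline estimates: mandatory TLL cuts energy
    purchased from labelled products by 6.5% [1.9; 11.1] and mandatory NWL
    by 12.9% [8.0; 17.9]; reformulation trims labelled-product energy
    content by 3.9% [-5.0; 12.5] for either label (the interval crosses
    zero, so reformulation draws may increase energy).  Mandatory TLL adds
    25 percentage points of coverage on top of the 75% voluntary baseline;
    NWL labels 51% [49; 52] of packaged products.
    """
    reformulation = UncertainQuantity(0.039, -0.050, 0.125)
    s = ScenarioSet()
    s.add(LabelPolicy(
        name="baseline",
        consumer_effect=exact(0.0),
        reformulation_effect=exact(0.0),
        coverage=CoverageSchedule.constant(_coverage_uq(0.0)),
    ))
    s.add(LabelPolicy(
        name="mandatory_TLL",
        consumer_effect=UncertainQuantity(0.065, 0.019, 0.111),
        reformulation_effect=reformulation,
        coverage=CoverageSchedule.constant(_coverage_uq(0.25)),
    ))
    s.add(LabelPolicy(
        name="mandatory_NWL",
        consumer_effect=UncertainQuantity(0.129, 0.080, 0.179),
        reformulation_effect=reformulation,
        coverage=CoverageSchedule.constant(_coverage_uq(0.51, 0.49, 0.52)),
    ))
    s.add(LabelPolicy(
        name="NWL_coverage_drop",
        consumer_effect=UncertainQuantity(0.129, 0.080, 0.179),
        reformulation_effect=reformulation,
        coverage=CoverageSchedule(steps=(
            (0, _coverage_uq(0.51, 0.49, 0.52)),
            (1, _coverage_uq(0.44, 0.42, 0.45)),  # first-year rule; offset is config
        )),
    ))
    s.add(LabelPolicy(
        name="chile_octagon",
        consumer_effect=UncertainQuantity(0.083, 0.050, 0.116),
        reformulation_effect=reformulation,
        coverage=CoverageSchedule.constant(_coverage_uq(0.51, 0.49, 0.52)),
    ))
    s.add(LabelPolicy(
        name="TLL_low_reformulation",
        consumer_effect=UncertainQuantity(0.065, 0.019, 0.111),
        reformulation_effect=UncertainQuantity(0.009, -0.031, 0.049),
        coverage=CoverageSchedule.constant(_coverage_uq(0.25)),
    ))
    # Nutri-Score does not differ measurably from the traffic light on energy
    # purchased, so the preset reuses the TLL effect structure.
    s.add(LabelPolicy(
        name="nutri_score",
        consumer_effect=UncertainQuantity(0.065, 0.019, 0.111),
        reformulation_effect=reformulation,
        coverage=CoverageSchedule.constant(_coverage_uq(0.25)),
    ))
    return s


# ---------------------------------------------------------------------------
# Monte Carlo draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolicyDraw:
    """Sampled parameters of one policy for one iteration."""

    consumer_effect: float
    reformulation_effect: float
    coverages: tuple  # sampled value per schedule step


@dataclass(frozen=True)
class ParameterDraw:
    """Everything random that one Monte Carlo iteration needs.

    Reproducible from (master seed, iteration): policy effect draws, the
    sampled relative risks per BMI unit, the sampled mortality trend slopes,
    plus the derived seeds for population generation and the shared
    person-year uniforms (common random numbers across scenarios).
    """

    iteration: int
    policies: dict  # name -> PolicyDraw
    rr: dict  # cause -> sampled RR per BMI unit
    mortality_trend: np.ndarray  # per-cause log slope
    population_seed: int
    uniform_seed: int


def scenario_rng(master_seed: int, iteration: int, name: str) -> np.random.Generator:
    """Per-scenario RNG keyed by name, so a scenario's draws do not depend
    on which other scenarios are in the run or on evaluation order."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration, 1, key))
    )


def sample_policy(policy: LabelPolicy, rng: np.random.Generator) -> PolicyDraw:
    return PolicyDraw(
        consumer_effect=sample_quantity(policy.consumer_effect, rng),
        reformulation_effect=sample_quantity(policy.reformulation_effect, rng),
        coverages=tuple(sample_quantity(q, rng) for _, q in policy.coverage.steps),
    )


def point_draw(policy: LabelPolicy) -> PolicyDraw:
    """Degenerate draw at the point estimates (no sampling)."""
    return PolicyDraw(
        consumer_effect=policy.consumer_effect.point,
        reformulation_effect=policy.reformulation_effect.point,
        coverages=tuple(q.point for _, q in policy.coverage.steps),
    )


def coverage_at(policy: LabelPolicy, years_since_implementation: int,
                draw: PolicyDraw) -> float:
    """Sampled coverage applying at a given policy age (step function)."""
    if years_since_implementation < 0:
        raise ConfigurationError("years_since_implementation must be >= 0")
    return draw.coverages[policy.coverage.step_index(years_since_implementation)]
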