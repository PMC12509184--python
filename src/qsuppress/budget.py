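"""Monte Carlo and quadrature combination of qNMR uncertainty components.

Each component is a named relative standard uncertainty (percent) tied
to one factor of the internal-standard measurement model (analyte area,
internal-standard area, weighed mass, purity, molar masses,
repeatability) or to the excitation-profile allowance a suppression
scheme introduces.  Because the measurement model is a pure product of
factors, relative perturbations propagate multiplicatively: each Monte
Carlo draw perturbs every factor by its own relative deviate and the
relative standard deviation of the simulated measurand is the combined
relative standard uncertainty.  The expanded uncertainty uses coverage
factor k = 2 (~95%).

The excitation allowance applies once per suppressed signal entering the
area ratio — analyte and internal standard each get their own,
independent, component.  A root-sum-of-squares (GUM-style) combination
is provided as the analytic cross-check of the Monte Carlo engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "BudgetComponent",
    "BudgetResult",
    "mc_combine",
    "gum_combine",
]

#: applies_to descriptors mapped to the exponent of their factor in the
#: measurement model (IS area divides the product).
_FACTOR_EXPONENT = {
    "analyte signal": +1,
    "IS signal": -1,
    "mass": +1,
    "purity": +1,
    "molar mass": +1,
    "repeatability": +1,
    "excitation": +1,
}


@dataclass(frozen=True)
class BudgetComponent:
    """A named relative uncertainty component (percent).

    For ``distribution="normal"`` the value is the relative standard
    uncertainty.  For ``distribution="rectangular"`` (balance-resolution
    style terms) the value is the relative half-width of the rectangle;
    its standard uncertainty is the half-width divided by sqrt 3, and
    both the Monte Carlo sampler and :func:`gum_combine` apply that
    convention consistently.
    """

    name: str
    relative_std_uncertainty: float
    distribution: str = "normal"
    applies_to: str = "repeatability"

    def __post_init__(self) -> None:
        if self.relative_std_uncertainty < 0:
            raise InvalidParameterError("relative_std_uncertainty must be >= 0")
        if self.distribution not in ("normal", "rectangular"):
            raise InvalidParameterError(
                f"unknown distribution {self.distribution!r}"
            )
        if self.applies_to not in _FACTOR_EXPONENT:
            raise InvalidParameterError(
                f"unknown applies_to {self.applies_to!r}; "
                f"expected one of {sorted(_FACTOR_EXPONENT)}"
            )


@dataclass
class BudgetResult:
    """Combined and expanded relative uncertainties from Monte Carlo."""

    combined_relative_std_uncertainty: float
    expanded_uncertainty_k2: float
    draws: int
    seed: int | None
    component_contributions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "combined_relative_std_uncertainty_percent":
                self.combined_relative_std_uncertainty,
            "expanded_uncertainty_k2_percent": self.expanded_uncertainty_k2,
            "draws": self.draws,
            "seed": self.seed,
            "component_contributions_percent": self.component_contributions,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def report(self) -> str:
        lines = [
            "Uncertainty budget (Monte Carlo)",
            "=" * 44,
            f"{'component':<26}{'u_rel (%)':>12}",
            "-" * 44,
        ]
        for name, u in self.component_contributions.items():
            lines.append(f"{name:<26}{u:>12.3f}")
        lines.append("-" * 44)
        lines.append(
            f"{'combined u_rel':<26}"
            f"{self.combined_relative_std_uncertainty:>12.3f}"
        )
        lines.append(
            f"{'expanded U (k=2)':<26}{self.expanded_uncertainty_k2:>12.3f}"
        )
        lines.append(f"draws = {self.draws}, seed = {self.seed}")
        return "\n".join(lines)


def _sample_factor(
    comp: BudgetComponent, draws: int, rng: np.random.Generator
) -> np.ndarray:
    u = comp.relative_std_uncertainty / 100.0
    if comp.distribution == "normal":
        dev = rng.normal(0.0, u, draws)
    else:  # rectangular: the quoted value is the half-width
        dev = rng.uniform(-u, u, draws)
    return 1.0 + dev


def mc_combine(
    components: list[BudgetComponent],
    draws: int = 10_000,
    seed: int | None = None,
) -> BudgetResult:
    """Combine components by seeded Monte Carlo through the ratio model.

    Each draw multiplies independently perturbed factors (IS-area
    components enter with exponent -1); the combined relative standard
    uncertainty is ``100 * sd / mean`` of the simulated measurand.
    """
    if not components:
        raise InvalidParameterError("component list is empty")
    if draws < 1000:
        raise InvalidParameterError("need at least 1000 draws")
    rng = np.random.default_rng(seed)
    measurand = np.ones(draws)
    for comp in components:
        factor = _sample_factor(comp, draws, rng)
        expo = _FACTOR_EXPONENT[comp.applies_to]
        # a perturbed denominator factor divides the measurand
        measurand = measurand * factor if expo > 0 else measurand / factor
    combined = 100.0 * float(np.std(measurand, ddof=1) / np.mean(measurand))
    return BudgetResult(
        combined_relative_std_uncertainty=combined,
        expanded_uncertainty_k2=2.0 * combined,
        draws=draws,
        seed=seed,
        component_contributions={
            c.name: c.relative_std_uncertainty for c in components
        },
    )


def gum_combine(components: list[BudgetComponent]) -> float:
    """Root-sum-of-squares combination of relative components (percent).

    The analytic counterpart of :func:`mc_combine` for the multiplicative
    model (all sensitivity coefficients are +-1 on the relative scale).
    Rectangular components are quoted as half-widths and are divided by
    sqrt 3 to get their standard uncertainty before squaring.
    """
    if not components:
        raise InvalidParameterError("component list is empty")
    total = 0.0
    for c in components:
        u = c.relative_std_uncertainty
        if c.distribution == "rectangular":
            u = u / np.sqrt(3.0)
        total += u * u
    return float(np.sqrt(total))
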