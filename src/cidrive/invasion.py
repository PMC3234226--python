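"""Discrete-generation dynamics of Wolbachia infection frequency.

The infection frequency ``p`` among adult females follows the classical
unidirectional-CI recursion (the Hoffmann/Turelli family): infected mothers
have relative fecundity ``f``, a fraction ``mu`` of their offspring fail to
inherit the infection, and a fraction ``s_h`` of incompatible fertilizations
(uninfected egg x infected male, males mating at random) are inviable::

    p' = p f (1-mu) / D,
    D  = p f (1-mu) + (1 - s_h p) (p f mu + 1 - p)

The numerator counts infected offspring; the second term of ``D`` counts
uninfected offspring (uninfected eggs from both infected and uninfected
mothers, thinned by CI with probability ``s_h p``).  Host abundance is
deliberately collapsed into this frequency recursion; absolute time is
produced by an explicit, configurable mean generation interval.

Interior equilibria are the roots in (0, 1] of the quadratic

    A p^2 + B p + C = 0,
    A = s_h (1 - f mu),  B = f - 1 - s_h,  C = 1 - f (1 - mu)

obtained by clearing ``p' = p``.  When ``f (1-mu) > 1`` the infection grows
from arbitrarily low frequency (no release threshold); otherwise the smaller
interior root, when present, is the unstable threshold an introduction must
exceed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import CIParameters

__all__ = [
    "InvasionParams",
    "DemographyConfig",
    "Equilibrium",
    "EquilibriumSet",
    "InvasionSummary",
    "DegenerateModelError",
    "IterationLimitError",
    "next_frequency",
    "equilibria",
    "fixation_prevalence",
    "release_threshold",
    "time_to_fixation",
    "fractional_generations_to_fixation",
    "invasion_params_from_ci",
]

_ROOT_TOL = 1e-10
_MAX_GENERATIONS = 10_000


class DegenerateModelError(ValueError):
    """Neutral model (f=1, mu=0, s_h=0): every frequency is an equilibrium."""


class IterationLimitError(RuntimeError):
    """The recursion hit the generation cap while still converging."""

    def __init__(self, message: str, last_frequency: float, generations: int):
        super().__init__(message)
        self.last_frequency = last_frequency
        self.generations = generations


@dataclass(frozen=True)
class InvasionParams:
    """Frequency-dynamics parameters.

    ``f`` is the relative fecundity of infected females.  In a natural
    population every fly carries *Wigglesworthia*, so ``f = 1 + F`` with F
    the *Wolbachia* fecundity benefit; :func:`invasion_params_from_ci` does
    that mapping.
    """

    f: float
    mu: float
    s_h: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"f must be positive, got {self.f}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0.0 <= self.s_h <= 1.0:
            raise ValueError(f"s_h must lie in [0, 1], got {self.s_h}")

    @property
    def degenerate(self) -> bool:
        return self.f == 1.0 and self.mu == 0.0 and self.s_h == 0.0


def invasion_params_from_ci(params: CIParameters) -> InvasionParams:
    """Map mechanistic CI estimates to frequency-dynamics parameters."""
    return InvasionParams(f=1.0 + params.F, mu=params.mu, s_h=params.s_h)


@dataclass(frozen=True)
class DemographyConfig:
    """Timing constants that convert generations to days.

    Tsetse deposit their first larva about three weeks after emergence and
    every 9-11 days thereafter; a 30-day mean generation interval is the
    package's convention for converting generation counts to days, and
    absolute times inherit its uncertainty.
    """

    generation_days: float = 30.0
    time_to_first_deposition_days: float = 21.0
    interlarval_days: float = 10.0

    def __post_init__(self) -> None:
        for name in ("generation_days", "time_to_first_deposition_days",
                     "interlarval_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Equilibrium:
    frequency: float
    stable: bool | None  # None = neutral / undecided


@dataclass(frozen=True)
class EquilibriumSet:
    points: tuple[Equilibrium, ...]
    degenerate: bool = False

    def stable_in_unit_interval(self) -> tuple[float, ...]:
        return tuple(e.frequency for e in self.points
                     if e.stable and 0.0 < e.frequency <= 1.0)

    def unstable_interior(self) -> tuple[float, ...]:
        return tuple(e.frequency for e in self.points
                     if e.stable is False and 0.0 < e.frequency < 1.0)


@dataclass(frozen=True)
class InvasionSummary:
    """Invasion outcome report (fixation, threshold, time to fixation)."""

    fixation_prevalence: float
    release_threshold: float  # 0.0 when absent; see flags for markers
    generations_to_fixation: int | None  # None = not reached
    days_to_fixation: float | None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "fixation_prevalence": self.fixation_prevalence,
            "release_threshold": self.release_threshold,
            "generations_to_fixation": self.generations_to_fixation,
            "days_to_fixation": self.days_to_fixation,
            "flags": list(self.flags),
        }


def next_frequency(p: float, params: InvasionParams) -> float:
    """One-generation update of the infection frequency; maps [0,1] to [0,1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    f, mu, s_h = params.f, params.mu, params.s_h
    infected = p * f * (1.0 - mu)
    uninfected = (1.0 - s_h * p) * (p * f * mu + 1.0 - p)
    denom = infected + uninfected
    if denom <= 0.0:
        # only reachable at p=1 with mu=0 and complete CI bookkeeping;
        # perfect transmission keeps the population fully infected
        return 1.0
    return infected / denom


def _iterate_from(p: float, params: InvasionParams, steps: int) -> float:
    for _ in range(steps):
        p = next_frequency(p, params)
    return p


def _stability_by_iteration(root: float, params: InvasionParams,
                            offset: float = 1e-4, steps: int = 400) -> bool | None:
    """Classify a fixed point by iterating from small perturbations."""
    attracts = []
    for sign in (-1.0, 1.0):
        start = min(max(root + sign * offset, 0.0), 1.0)
        if start == root:
            continue
        end = _iterate_from(start, params, steps)
        attracts.append(abs(end - root) < abs(start - root))
    if not attracts:
        return None
    if all(attracts):
        return True
    if not any(attracts):
        return False
    return None  # semi-stable; not expected for admissible parameters


def equilibria(params: InvasionParams) -> EquilibriumSet:
    """All equilibria of the recursion in [0, 1] with stability flags.

    Interior equilibria come from the quadratic; stability is confirmed by
    iterating from +/-1e-4 perturbations rather than a derivative sign, to
    avoid boundary pathologies.  The neutral case (f=1, mu=0, s_h=0) is
    flagged degenerate and returns no points.
    """
    if params.degenerate:
        return EquilibriumSet(points=(), degenerate=True)
    f, mu, s_h = params.f, params.mu, params.s_h
    growth = f * (1.0 - mu)  # low-frequency growth factor
    if growth > 1.0:
        zero_stable: bool | None = False
    elif growth < 1.0:
        zero_stable = True
    else:
        zero_stable = None
    points = [Equilibrium(0.0, zero_stable)]

    a = s_h * (1.0 - f * mu)
    b = f - 1.0 - s_h
    c = 1.0 - growth
    roots: list[float] = []
    if abs(a) < _ROOT_TOL:
        if abs(b) > _ROOT_TOL:
            roots.append(-c / b)
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots.extend(((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)))
    for root in sorted(set(roots)):
        if abs(root - 1.0) < 1e-9:
            root = 1.0  # snap: quadratic cancellation blurs the p=1 root
        if _ROOT_TOL < root <= 1.0:
            points.append(Equilibrium(root, _stability_by_iteration(root, params)))
    return EquilibriumSet(points=tuple(points))


def fixation_prevalence(params: InvasionParams) -> float:
    """The largest stable equilibrium in (0, 1]; 0 when none exists."""
    eq = equilibria(params)
    if eq.degenerate:
        raise DegenerateModelError("f=1, mu=0, s_h=0: every frequency is neutral")
    stable = eq.stable_in_unit_interval()
    return max(stable) if stable else 0.0


def release_threshold(params: InvasionParams) -> float | None:
    """The minimum introduction frequency for invasion.

    Returns 0.0 when the infection invades from any frequency
    (``f (1-mu) > 1``), the unstable interior equilibrium when one exists,
    and ``None`` when no stable positive equilibrium exists at all (invasion
    impossible).
    """
    eq = equilibria(params)
    if eq.degenerate:
        raise DegenerateModelError("f=1, mu=0, s_h=0: every frequency is neutral")
    if not eq.stable_in_unit_interval():
        return None
    if params.f * (1.0 - params.mu) > 1.0:
        return 0.0
    unstable = eq.unstable_interior()
    return min(unstable) if unstable else 0.0


def time_to_fixation(
    params: InvasionParams,
    demography: DemographyConfig | None = None,
    p0: float = 0.10,
    target_fraction: float = 0.95,
) -> InvasionSummary:
    """Generations and days from an initial prevalence to near-fixation.

    Iterates the recursion from ``p0`` and reports the first generation at
    which prevalence reaches ``target_fraction`` of the fixation prevalence;
    days are generations times the mean generation interval.  When ``p0``
    does not exceed the release threshold (or no fixation state exists) the
    infection is driven out and the time is reported as not reached
    (``None``).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    demography = demography or DemographyConfig()
    fixation = fixation_prevalence(params)
    threshold = release_threshold(params)
    flags: list[str] = []
    if threshold is None:
        flags.append("no_invasion_possible")
    if fixation == 0.0 or threshold is None or p0 <= threshold:
        if fixation > 0.0 and threshold is not None:
            flags.append("initial_prevalence_below_threshold")
        return InvasionSummary(
            fixation_prevalence=fixation,
            release_threshold=threshold if threshold is not None else 0.0,
            generations_to_fixation=None,
            days_to_fixation=None,
            flags=tuple(flags) or ("not_reached",),
        )
    target = target_fraction * fixation
    p = p0
    generation = 0
    while p < target:
        if generation >= _MAX_GENERATIONS:
            raise IterationLimitError(
                f"recursion did not reach {target:.6f} within "
                f"{_MAX_GENERATIONS} generations (last p={p:.6f})",
                last_frequency=p, generations=generation,
            )
        p = next_frequency(p, params)
        generation += 1
    return InvasionSummary(
        fixation_prevalence=fixation,
        release_threshold=threshold,
        generations_to_fixation=generation,
        days_to_fixation=generation * demography.generation_days,
        flags=(),
    )


def fractional_generations_to_fixation(
    params: InvasionParams,
    p0: float = 0.10,
    target_fraction: float = 0.95,
) -> float | None:
    """Continuous-valued crossing generation for sensitivity analysis.

    Identical to :func:`time_to_fixation` except the crossing generation is
    linearly interpolated between the bracketing generations, so the output
    varies smoothly with the parameters instead of in unit jumps.
    """
    fixation = fixation_prevalence(params)
    threshold = release_threshold(params)
    if fixation == 0.0 or threshold is None or p0 <= threshold:
        return None
    target = target_fraction * fixation
    if p0 >= target:
        return 0.0
    p_prev = p0
    for generation in range(1, _MAX_GENERATIONS + 1):
        p = next_frequency(p_prev, params)
        if p >= target:
            if p == p_prev:
                return float(generation)
            return (generation - 1) + (target - p_prev) / (p - p_prev)
        p_prev = p
    raise IterationLimitError(
        f"recursion did not reach {target:.6f} within {_MAX_GENERATIONS} "
        f"generations (last p={p_prev:.6f})",
        last_frequency=p_prev, generations=_MAX_GENERATIONS,
    )
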