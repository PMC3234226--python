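"""Mechanistic cytoplasmic-incompatibility model for larval deposition.

Five parameters govern the per-female, per-cycle probability of larval
deposition in every cross (female x male):

* ``H``   -- baseline deposition probability (aposymbiotic female x
  aposymbiotic male);
* ``F``   -- relative fecundity benefit of *Wolbachia* to females (> -1);
* ``W``   -- relative fecundity benefit of *Wigglesworthia* to females (> -1);
* ``mu``  -- transmission failure: proportion of eggs of a
  *Wolbachia*-carrying mother that are *Wolbachia*-free;
* ``s_h`` -- CI strength: proportion of fertilizations of *Wolbachia*-free
  eggs by *Wolbachia*-affected sperm that are not viable.

The deposition probability follows the classical unidirectional-CI structure
established for *Wolbachia* in *Drosophila*: female fecundity benefits act
multiplicatively, and CI removes the fraction ``s_h`` of *Wolbachia*-free
eggs (a fraction ``mu`` of an infected mother's eggs, all of an uninfected
mother's) fertilized by *Wolbachia*-carrying males::

    p = H * (1+F)^[female Wolbachia] * (1+W)^[female Wigglesworthia]
          * (1 - s_h * u * [male Wolbachia]),   u = mu if female infected else 1

so the five experimental crosses are

    p_ww = H (1+F)(1+W)(1 - mu s_h)      p_wa = H (1+F)(1+W)
    p_aa = H                             p_aw = H (1 - s_h)
    p_mm = H (1+F)(1 - mu s_h)

A parameter vector is *admissible* when every modeled cross probability lies
in [0, 1]; the flat prior is truncated to that region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .crosses import MODELED_CROSSES, CrossDataset, FlyClass

__all__ = [
    "CIParameters",
    "InadmissibleParametersError",
    "PARAMETER_NAMES",
    "PRIOR_BOX",
    "deposition_probability",
    "cross_probabilities",
    "is_admissible",
    "log_likelihood",
    "log_prior",
    "moment_match",
]

#: Canonical parameter order used by arrays, chains and CSV exports.
PARAMETER_NAMES = ("H", "F", "W", "mu", "s_h")

#: Flat-prior support per parameter.  The benefit parameters extend below
#: zero because the data cannot rule out a fecundity *cost*; the upper cap 4
#: is a generous bound, far above any plausible relative benefit.
PRIOR_BOX: Mapping[str, tuple[float, float]] = {
    "H": (0.0, 1.0),
    "F": (-1.0, 4.0),
    "W": (-1.0, 4.0),
    "mu": (0.0, 1.0),
    "s_h": (0.0, 1.0),
}


class InadmissibleParametersError(ValueError):
    """Parameters produce a cross probability outside [0, 1]."""


@dataclass(frozen=True)
class CIParameters:
    """The five mechanistic CI parameters."""

    H: float
    F: float
    W: float
    mu: float
    s_h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise ValueError(f"H must lie in [0, 1], got {self.H}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0.0 <= self.s_h <= 1.0:
            raise ValueError(f"s_h must lie in [0, 1], got {self.s_h}")
        if self.F <= -1.0:
            raise ValueError(f"F must exceed -1, got {self.F}")
        if self.W <= -1.0:
            raise ValueError(f"W must exceed -1, got {self.W}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.H, self.F, self.W, self.mu, self.s_h)

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "CIParameters":
        return cls(**{name: float(values[name]) for name in PARAMETER_NAMES})

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAMETER_NAMES, self.as_tuple()))


def _probability(H: float, F: float, W: float, mu: float, s_h: float,
                 female: FlyClass, male: FlyClass) -> float:
    p = H
    if female.wolbachia:
        p *= 1.0 + F
    if female.wigglesworthia:
        p *= 1.0 + W
    if male.wolbachia:
        u = mu if female.wolbachia else 1.0
        p *= 1.0 - s_h * u
    return p


def cross_probabilities(params: CIParameters) -> dict[tuple[FlyClass, FlyClass], float]:
    """Deposition probability for each of the five modeled crosses."""
    return {
        (f, m): _probability(*params.as_tuple(), f, m) for f, m in MODELED_CROSSES
    }


def is_admissible(params: CIParameters) -> bool:
    """True when every modeled cross probability lies in [0, 1]."""
    return all(0.0 <= p <= 1.0 for p in cross_probabilities(params).values())


def deposition_probability(params: CIParameters, female: FlyClass,
                           male: FlyClass) -> float:
    """Per-female, per-cycle larval-deposition probability for a cross.

    Any (female, male) pair is computed by the same rule; admissibility is
    checked over the five modeled crosses.
    """
    if not is_admissible(params):
        raise InadmissibleParametersError(
            f"parameters {params.to_dict()} give a cross probability outside [0, 1]"
        )
    return _probability(*params.as_tuple(), female, male)


def _binom_logpmf(k: int, n: int, p: float) -> float:
    if k > 0 and p <= 0.0:
        return -math.inf
    if k < n and p >= 1.0:
        return -math.inf
    out = (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )
    if k > 0:
        out += k * math.log(p)
    if k < n:
        out += (n - k) * math.log1p(-p)
    return out


def log_likelihood(params: CIParameters, data: CrossDataset) -> float:
    """Binomial log-likelihood of a cross dataset.

    Each observation contributes the binomial log-probability (including the
    coefficient) of its deposit count given its cross's deposition
    probability; both gonotrophic cycles share the same parameters, and
    observations with no females contribute nothing.  Impossible data
    (``p = 0`` with deposits, or ``p = 1`` with failures) yield ``-inf``.
    """
    if not is_admissible(params):
        raise InadmissibleParametersError(
            f"parameters {params.to_dict()} give a cross probability outside [0, 1]"
        )
    probs = cross_probabilities(params)
    total = 0.0
    for obs in data:
        if obs.n_females == 0:
            continue
        term = _binom_logpmf(obs.n_deposits, obs.n_females, probs[obs.cross])
        if term == -math.inf:
            return -math.inf
        total += term
    return total


def log_prior(params: CIParameters) -> float:
    """Flat prior truncated to the box and the admissible region.

    Returns 0 inside the support (up to the unnormalized constant) and
    ``-inf`` outside.
    """
    for name, value in params.to_dict().items():
        lo, hi = PRIOR_BOX[name]
        if not lo <= value <= hi:
            return -math.inf
    if not is_admissible(params):
        return -math.inf
    return 0.0


def moment_match(data: CrossDataset) -> CIParameters:
    """Solve the five pooled cross rates exactly for the five parameters.

    Pooling deposits and females per cross over cages and cycles gives five
    empirical rates r_c; the model is exactly identified, and the closed-form
    solution is

        H        = r_aa
        s_h      = 1 - r_aw / r_aa
        1-mu*s_h = r_ww / r_wa
        1+F      = r_mm / (H * (1 - mu*s_h))
        1+W      = r_wa / (H * (1+F))

    Useful as a deterministic cross-check on the sampler and as a spot where
    the model's identifiability is visible at a glance.
    """
    from .crosses import A, M, W as WT

    pooled = data.pooled_counts()
    required = {(A, A), (A, WT), (WT, WT), (WT, A), (M, M)}
    missing = required - set(pooled)
    if missing:
        labels = ", ".join(f"{f.value}x{m.value}" for f, m in sorted(
            missing, key=lambda c: (c[0].value, c[1].value)))
        raise ValueError(f"moment matching needs all five crosses; missing {labels}")
    rate = {c: k / n for c, (k, n) in pooled.items()}
    H = rate[(A, A)]
    if H <= 0:
        raise ValueError("pooled a x a rate is zero; H is not identified")
    s_h = 1.0 - rate[(A, WT)] / H
    one_minus_mu_sh = rate[(WT, WT)] / rate[(WT, A)]
    mu = (1.0 - one_minus_mu_sh) / s_h if s_h > 0 else 0.0
    one_plus_F = rate[(M, M)] / (H * one_minus_mu_sh)
    one_plus_W = rate[(WT, A)] / (H * one_plus_F)
    return CIParameters(H=H, F=one_plus_F - 1.0, W=one_plus_W - 1.0,
                        mu=mu, s_h=s_h)
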