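"""Local sensitivity and elasticity of invasion outputs.

Derivatives are central finite differences with a multiplicative step
``theta (1 +/- rel_step)``: the parameters live on very different scales
(probabilities vs. days), and a relative step keeps the perturbation
proportionate.  The time to fixation is differentiated through its smoothed
(linearly interpolated) crossing generation, because the raw generation
count is piecewise constant in the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .invasion import (
    DemographyConfig,
    InvasionParams,
    fixation_prevalence,
    fractional_generations_to_fixation,
    release_threshold,
)

__all__ = [
    "SensitivityRecord",
    "elasticity",
    "sensitivity_table",
    "write_sensitivity_csv",
]

SENSITIVITY_OUTPUTS = ("fixation_prevalence", "release_threshold", "days_to_fixation")
SENSITIVITY_PARAMETERS = ("f", "mu", "s_h", "generation_days")


@dataclass(frozen=True)
class SensitivityRecord:
    """One (output, parameter) sensitivity/elasticity pair.

    ``sensitivity`` is the central-difference derivative dQ/dtheta;
    ``elasticity`` is (dQ/dtheta) * theta / Q, i.e. percent change of the
    output per percent change of the parameter.  Either may be ``None`` when
    undefined (Q = 0 or theta = 0, or an undefined output), with the reason
    in ``flags``.
    """

    output_name: str
    parameter_name: str
    sensitivity: float | None
    elasticity: float | None
    flags: tuple[str, ...] = ()


def elasticity(
    output_fn: Callable[[Mapping[str, float]], float | None],
    params: Mapping[str, float],
    name: str,
    rel_step: float = 0.01,
    output_name: str = "output",
) -> SensitivityRecord:
    """Central-difference sensitivity and elasticity of one output.

    ``output_fn`` maps a full parameter dictionary to a scalar (or ``None``
    for undefined).  When the parameter is exactly zero the multiplicative
    step degenerates, so an absolute step of ``rel_step`` is used for the
    sensitivity and the elasticity is flagged undefined.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    theta = float(params[name])
    flags: list[str] = []
    if theta == 0.0:
        lo_theta, hi_theta = -rel_step, rel_step
        flags.append("theta_zero_absolute_step")
    else:
        lo_theta, hi_theta = theta * (1.0 - rel_step), theta * (1.0 + rel_step)

    center = output_fn(dict(params))
    if center is None or not math.isfinite(center):
        return SensitivityRecord(output_name, name, None, None,
                                 flags=("undefined_at_center",))
    values = {}
    for side, theta_side in (("lower", lo_theta), ("upper", hi_theta)):
        perturbed = dict(params)
        perturbed[name] = theta_side
        value = output_fn(perturbed)
        if value is None or not math.isfinite(value):
            raise ValueError(
                f"{output_name}: output undefined at the {side} perturbation "
                f"of {name} ({theta_side!r})"
            )
        values[side] = value
    sens = (values["upper"] - values["lower"]) / (hi_theta - lo_theta)
    if theta == 0.0:
        return SensitivityRecord(output_name, name, sens, None,
                                 flags=tuple(flags + ["elasticity_undefined_theta_zero"]))
    if center == 0.0:
        return SensitivityRecord(output_name, name, sens, None,
                                 flags=tuple(flags + ["elasticity_undefined_output_zero"]))
    return SensitivityRecord(output_name, name, sens, sens * theta / center,
                             flags=tuple(flags))


def _invasion_outputs(demography_defaults: DemographyConfig, p0: float,
                      target_fraction: float
                      ) -> dict[str, Callable[[Mapping[str, float]], float | None]]:
    def _params(values: Mapping[str, float]) -> InvasionParams:
        return InvasionParams(f=values["f"], mu=values["mu"], s_h=values["s_h"])

    def fix(values: Mapping[str, float]) -> float:
        return fixation_prevalence(_params(values))

    def thr(values: Mapping[str, float]) -> float | None:
        return release_threshold(_params(values))

    def days(values: Mapping[str, float]) -> float | None:
        generations = fractional_generations_to_fixation(
            _params(values), p0=p0, target_fraction=target_fraction)
        if generations is None:
            return None
        return generations * values["generation_days"]

    return {"fixation_prevalence": fix, "release_threshold": thr,
            "days_to_fixation": days}


def sensitivity_table(
    params: InvasionParams,
    demography: DemographyConfig | None = None,
    rel_step: float = 0.01,
    p0: float = 0.10,
    target_fraction: float = 0.95,
) -> list[SensitivityRecord]:
    """Sensitivities of all invasion outputs to all tunable parameters.

    Twelve records: {fixation prevalence, release threshold, days to
    fixation} x {f, mu, s_h, generation_days}.  An output that is undefined
    at the evaluation point (or identically zero, for elasticity) yields a
    flagged record instead of an error.
    """
    demography = demography or DemographyConfig()
    values = {"f": params.f, "mu": params.mu, "s_h": params.s_h,
              "generation_days": demography.generation_days}
    outputs = _invasion_outputs(demography, p0, target_fraction)
    records = []
    for output_name in SENSITIVITY_OUTPUTS:
        fn = outputs[output_name]
        for parameter_name in SENSITIVITY_PARAMETERS:
            try:
                record = elasticity(fn, values, parameter_name,
                                    rel_step=rel_step, output_name=output_name)
            except ValueError as exc:
                record = SensitivityRecord(output_name, parameter_name,
                                           None, None,
                                           flags=("undefined_at_perturbation",
                                                  str(exc)))
            records.append(record)
    return records


def write_sensitivity_csv(records: Sequence[SensitivityRecord],
                          path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "output": [r.output_name for r in records],
            "parameter": [r.parameter_name for r in records],
            "sensitivity": [r.sensitivity for r in records],
            "elasticity": [r.elasticity for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
    frame.to_csv(path, index=False)
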