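"""Random-walk Metropolis sampling of the CI posterior.

The target density is ``log_likelihood + log_prior`` from
:mod:`cidrive.model`: a binomial likelihood over pooled cross counts under a
flat prior truncated to the admissible region.  The sampler is a plain
(non-adaptive) Metropolis algorithm with independent Gaussian proposals per
parameter, chosen for exact reproducibility: a run is bitwise deterministic
given its seed.  Out-of-support proposals are rejected outright, which
preserves the truncated-flat target.

The central object is :class:`CIMetropolisEstimator`, a scikit-learn style
estimator whose ``fit`` consumes a :class:`~cidrive.crosses.CrossDataset`
and exposes the thinned post-burn-in chain as fitted attributes;
:func:`run_mcmc` is a thin functional wrapper over it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .crosses import CrossDataset, FlyClass
from .model import PARAMETER_NAMES, PRIOR_BOX, CIParameters

__all__ = [
    "MCMCConfig",
    "PosteriorChain",
    "QuantitySummary",
    "PosteriorSummary",
    "MCMCDiagnosticError",
    "CIMetropolisEstimator",
    "run_mcmc",
    "summarize_posterior",
    "pushforward",
    "TABLE3_ROW_NAMES",
]

logger = logging.getLogger(__name__)

#: Report row names used for JSON summary export, mirroring the published
#: parameter table.
TABLE3_ROW_NAMES: Mapping[str, str] = {
    "H": "Baseline Deposition Probability",
    "F": "Fecundity Benefit of Wolbachia",
    "W": "Fecundity Benefit of Wigglesworthia",
    "s_h": "CI Strength",
    "mu": "Transmission Failure",
}

_DEFAULT_SCALES = (0.02, 0.05, 0.05, 0.02, 0.02)  # H, F, W, mu, s_h
_INITIAL_STATE = (0.5, 0.2, 0.2, 0.1, 0.5)


class MCMCDiagnosticError(RuntimeError):
    """The chain failed a basic health check (e.g. nothing was accepted)."""


@dataclass(frozen=True)
class MCMCConfig:
    """Tuning knobs for the Metropolis sampler.

    ``n_iterations`` counts post-burn-in proposals; ``thin`` keeps every
    ``thin``-th post-burn-in state.  ``proposal_scales`` are the Gaussian
    step standard deviations in the order (H, F, W, mu, s_h): the benefit
    parameters get larger steps because their support ([-1, 4]) is wider.
    """

    n_iterations: int = 200_000
    burn_in: int = 20_000
    thin: int = 10
    proposal_scales: tuple[float, float, float, float, float] = _DEFAULT_SCALES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        if len(self.proposal_scales) != 5 or any(s <= 0 for s in self.proposal_scales):
            raise ValueError("proposal_scales must be five positive reals")


@dataclass(frozen=True)
class QuantitySummary:
    """Median and central 95% credible interval of one scalar quantity.

    ``None`` marks an undefined endpoint (a quantile that falls among draws
    where the quantity is undefined); ``undefined_fraction`` is the
    proportion of such draws.
    """

    median: float | None
    lower: float | None
    upper: float | None
    undefined_fraction: float = 0.0

    def as_dict(self) -> dict[str, float | None]:
        return {
            "median": self.median,
            "lower": self.lower,
            "upper": self.upper,
            "undefined_fraction": self.undefined_fraction,
        }


PosteriorSummary = dict[str, QuantitySummary]


@dataclass(frozen=True)
class PosteriorChain:
    """Thinned post-burn-in Metropolis draws."""

    draws: np.ndarray  # shape (n_draws, 5), columns in PARAMETER_NAMES order
    log_posteriors: np.ndarray
    acceptance_rate: float
    config: MCMCConfig

    def __len__(self) -> int:
        return self.draws.shape[0]

    def __iter__(self) -> Iterator[CIParameters]:
        for row in self.draws:
            yield CIParameters(*row)

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, PARAMETER_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.draws, columns=list(PARAMETER_NAMES))
        frame["log_posterior"] = self.log_posteriors
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorChain":
        frame = pd.read_csv(path)
        missing = [c for c in (*PARAMETER_NAMES, "log_posterior")
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"chain file missing column(s) {', '.join(missing)}")
        if frame.empty:
            raise ValueError("chain file contains no draws")
        return cls(
            draws=frame[list(PARAMETER_NAMES)].to_numpy(float),
            log_posteriors=frame["log_posterior"].to_numpy(float),
            acceptance_rate=math.nan,
            config=MCMCConfig(n_iterations=max(len(frame), 1)),
        )


class CIMetropolisEstimator(BaseEstimator):
    """Metropolis sampler for the CI model, scikit-learn estimator style.

    Parameters mirror :class:`MCMCConfig`.  ``fit(dataset)`` runs the chain
    and sets ``chain_`` (a :class:`PosteriorChain`), ``acceptance_rate_``
    and ``summary_``.
    """

    def __init__(
        self,
        n_iterations: int = 200_000,
        burn_in: int = 20_000,
        thin: int = 10,
        proposal_scales: tuple[float, ...] = _DEFAULT_SCALES,
        seed: int = 0,
    ) -> None:
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.proposal_scales = proposal_scales
        self.seed = seed

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            proposal_scales=tuple(self.proposal_scales),
            seed=self.seed,
        )

    def fit(self, X: CrossDataset, y: None = None) -> "CIMetropolisEstimator":
        """Sample the posterior for the cross dataset ``X``."""
        if not isinstance(X, CrossDataset):
            raise TypeError("X must be a CrossDataset")
        if len(X) == 0:
            raise ValueError("dataset is empty")
        config = self._config()
        draws, logps, acc_rate = _metropolis(X, config)
        if acc_rate == 0.0:
            raise MCMCDiagnosticError(
                "no proposal was accepted; proposal scales are likely far too large"
            )
        if not 0.1 <= acc_rate <= 0.6:
            logger.warning(
                "acceptance rate %.3f outside the [0.1, 0.6] tuning band; "
                "consider adjusting proposal_scales", acc_rate,
            )
        self.chain_ = PosteriorChain(draws, logps, acc_rate, config)
        self.acceptance_rate_ = acc_rate
        self.summary_ = summarize_posterior(self.chain_)
        return self

    def pushforward(self, fn: Callable[[CIParameters], float | None],
                    name: str = "quantity") -> QuantitySummary:
        """Posterior summary of ``fn`` applied to every retained draw."""
        return pushforward(self.chain_, fn, name=name)


def _metropolis(data: CrossDataset, config: MCMCConfig
                ) -> tuple[np.ndarray, np.ndarray, float]:
    # Pool counts per cross once: the binomial likelihood factorizes, so the
    # per-iteration cost is five probability evaluations and ten log terms.
    pooled = data.pooled_counts()
    pairs = []  # (female wolbachia, female wiggles, male wolbachia, N, K)
    log_binom_const = 0.0
    for obs in data:
        if obs.n_females > 0:
            log_binom_const += (
                math.lgamma(obs.n_females + 1)
                - math.lgamma(obs.n_deposits + 1)
                - math.lgamma(obs.n_females - obs.n_deposits + 1)
            )
    for (female, male), (k, n) in pooled.items():
        if n > 0:
            pairs.append((female.wolbachia, female.wigglesworthia,
                          male.wolbachia, n, k))

    f_lo, f_hi = PRIOR_BOX["F"]

    def log_post(h: float, fb: float, wb: float, mu: float, sh: float) -> float:
        if not (0.0 <= h <= 1.0 and 0.0 <= mu <= 1.0 and 0.0 <= sh <= 1.0
                and f_lo <= fb <= f_hi and f_lo <= wb <= f_hi):
            return -math.inf
        opf = 1.0 + fb
        opw = 1.0 + wb
        ci_infected = 1.0 - sh * mu
        # admissibility over all five modeled crosses
        p_aa = h
        p_aw = h * (1.0 - sh)
        p_wa = h * opf * opw
        p_ww = p_wa * ci_infected
        p_mm = h * opf * ci_infected
        if p_wa > 1.0 or p_ww > 1.0 or p_mm > 1.0 or p_ww < 0.0 or p_mm < 0.0:
            return -math.inf
        ll = log_binom_const
        for fw, fg, mw, n, k in pairs:
            if fw:
                p = (p_ww if fg else p_mm) if mw else (p_wa if fg else h * opf)
            else:
                p = p_aw if mw else p_aa
            if k > 0:
                if p <= 0.0:
                    return -math.inf
                ll += k * math.log(p)
            if k < n:
                if p >= 1.0:
                    return -math.inf
                ll += (n - k) * math.log1p(-p)
        return ll

    current = list(_INITIAL_STATE)
    lp_current = log_post(*current)
    if lp_current == -math.inf:
        raise MCMCDiagnosticError("initial state has zero posterior density")

    rng = np.random.default_rng(config.seed)
    total = config.burn_in + config.n_iterations
    steps = rng.standard_normal((total, 5)) * np.asarray(config.proposal_scales)
    log_uniforms = np.log(rng.random(total))

    n_keep = config.n_iterations // config.thin
    draws = np.empty((n_keep, 5))
    logps = np.empty(n_keep)
    accepted = 0
    kept = 0
    burn_in, thin = config.burn_in, config.thin
    for i in range(total):
        step = steps[i]
        proposal = (current[0] + step[0], current[1] + step[1],
                    current[2] + step[2], current[3] + step[3],
                    current[4] + step[4])
        lp_new = log_post(*proposal)
        if lp_new - lp_current >= log_uniforms[i]:
            current = list(proposal)
            lp_current = lp_new
            accepted += 1
        j = i - burn_in
        if j >= 0 and (j + 1) % thin == 0 and kept < n_keep:
            draws[kept] = current
            logps[kept] = lp_current
            kept += 1
    return draws[:kept], logps[:kept], accepted / total


def run_mcmc(data: CrossDataset, config: MCMCConfig | None = None) -> PosteriorChain:
    """Run the Metropolis sampler and return the thinned posterior chain."""
    config = config or MCMCConfig()
    estimator = CIMetropolisEstimator(
        n_iterations=config.n_iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        proposal_scales=config.proposal_scales,
        seed=config.seed,
    )
    estimator.fit(data)
    return estimator.chain_


def _quantile(sorted_finite: np.ndarray, n_total: int, q: float) -> float | None:
    """Type-7 (linear interpolation) quantile over a chain in which undefined
    draws rank above every finite value; returns None when the quantile
    touches the undefined block."""
    if n_total == 0:
        return None
    h = q * (n_total - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    if hi >= sorted_finite.size:
        return None
    if lo == hi:
        return float(sorted_finite[lo])
    frac = h - lo
    return float(sorted_finite[lo] * (1.0 - frac) + sorted_finite[hi] * frac)


def summarize_posterior(chain: PosteriorChain) -> PosteriorSummary:
    """Median and 95% credible interval for each parameter.

    Quantiles use linear interpolation between order statistics.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    summary: PosteriorSummary = {}
    for name in PARAMETER_NAMES:
        values = np.sort(chain.parameter(name))
        summary[name] = QuantitySummary(
            median=_quantile(values, values.size, 0.5),
            lower=_quantile(values, values.size, 0.025),
            upper=_quantile(values, values.size, 0.975),
        )
    return summary


def pushforward(chain: PosteriorChain,
                fn: Callable[[CIParameters], float | None],
                name: str = "quantity") -> QuantitySummary:
    """Summarize ``fn`` applied to every draw of the chain.

    ``fn`` may return ``None`` (or NaN) to mark a draw where the quantity is
    undefined -- e.g. a time to fixation when the starting prevalence is
    below the release threshold, so fixation is never reached.  Undefined
    draws rank above all finite values, and any quantile that lands among
    them is reported as undefined, matching the convention of reporting an
    unbounded upper credible limit.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    values = []
    n_undefined = 0
    for index, params in enumerate(chain):
        try:
            value = fn(params)
        except Exception as exc:
            raise RuntimeError(f"{name}: function failed on draw {index}") from exc
        if value is None or (isinstance(value, float) and math.isnan(value)):
            n_undefined += 1
        else:
            values.append(float(value))
    finite = np.sort(np.asarray(values, dtype=float))
    n_total = len(chain)
    return QuantitySummary(
        median=_quantile(finite, n_total, 0.5),
        lower=_quantile(finite, n_total, 0.025),
        upper=_quantile(finite, n_total, 0.975),
        undefined_fraction=n_undefined / n_total,
    )


def summary_to_json_dict(summary: PosteriorSummary) -> dict[str, dict[str, float | None]]:
    """Render a parameter summary with the published report row names."""
    return {
        TABLE3_ROW_NAMES.get(name, name): qs.as_dict()
        for name, qs in summary.items()
    }


def split_half_consistency(chain: PosteriorChain) -> dict[str, float]:
    """Stationarity smoke statistic per parameter.

    Returns |median(first half) - median(second half)| divided by a
    batch-means Monte-Carlo standard error of a half-chain median, which
    absorbs the autocorrelation the thinned chain retains.  Values should be
    below ~3 for a converged chain; this is a smoke check, not a formal
    convergence diagnostic.
    """
    n = len(chain)
    half = n // 2
    if half < 4:
        raise ValueError("chain too short for a split-half check")
    out = {}
    for name in PARAMETER_NAMES:
        values = chain.parameter(name)
        first, second = values[:half], values[half:]
        gap = abs(float(np.median(first)) - float(np.median(second)))
        # batch medians over each half estimate the sampling sd of a
        # half-chain median; the gap of two independent halves has sqrt(2)
        # times that sd
        n_batches = max(8, int(math.sqrt(half)))
        mcse_sq = 0.0
        for part in (first, second):
            batches = np.array_split(part, n_batches)
            medians = np.array([np.median(b) for b in batches])
            mcse_sq += float(np.var(medians, ddof=1)) / n_batches
        mcse = math.sqrt(mcse_sq)
        out[name] = gap / mcse if mcse > 0 else 0.0
    return out
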