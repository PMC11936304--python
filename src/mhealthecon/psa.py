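"""Probabilistic sensitivity analysis of the savings threshold.

Propagates uncertainty in the intervention cost, the inpatient and ED unit
costs (gamma distributions, moment-matched), and the annual visit counts
(Poisson) through the savings-threshold calculation by Monte Carlo:

    threshold_i = 100 · C_i / (n_ip,i · c_ip,i + n_ed,i · c_ed,i)

Draws with a zero denominator (no visits at all, probability exp(-5) ≈ 0.7%
under the default means) would make the threshold infinite; they are handled
by a configurable policy (redraw by default). The resulting threshold
distribution is heavily right-skewed — draws with few visits produce very
large thresholds — so the mean sits well above the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PSAConfig",
    "PSAResult",
    "gamma_moments_to_params",
    "probable_interval",
    "draw_inputs",
    "run_psa",
    "summarize_psa",
]


def probable_interval(values: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Central probable interval by linear interpolation between order
    statistics (the default numpy percentile convention), so intervals are
    reproducible across runs and implementations."""
    half_tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [half_tail, 100.0 - half_tail])
    return float(lo), float(hi)

ZeroDenominatorPolicy = Literal["redraw", "drop", "cap"]


@dataclass(frozen=True)
class PSAConfig:
    """Distributional assumptions and run parameters for the Monte Carlo.

    Costs are gamma-distributed with method-of-moments parameters
    (shape = (mean/sd)², scale = sd²/mean); visit counts are Poisson. The
    intervention-cost dispersion is a coefficient of variation because no
    standard error accompanies the PPPY cost estimate; the default CV of
    0.10 spans roughly the published scenario range and the PSA mean and
    upper interval bound are sensitive to it (see the methods note).
    All five inputs are drawn independently.

    ``fixed_visit_counts=True`` replaces the Poisson draws with their means
    (the degenerate limit used to check agreement with the deterministic
    threshold). ``zero_denominator_policy`` is one of ``redraw`` (resample
    the whole joint draw), ``drop`` (discard it), or ``cap`` (record the
    threshold as ``cap_pct``).
    """

    n_draws: int = 10_000
    seed: int | None = None
    intervention_cost_mean: float = 2_865.34
    intervention_cost_cv: float = 0.10
    inpatient_cost_mean: float = 16_609.0
    inpatient_cost_sd: float = 860.0
    ed_cost_mean: float = 1_233.0
    ed_cost_sd: float = 66.0
    mean_inpatient_visits: float = 2.0
    mean_ed_visits: float = 3.0
    fixed_visit_counts: bool = False
    zero_denominator_policy: ZeroDenominatorPolicy = "redraw"
    cap_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if self.intervention_cost_mean <= 0:
            raise ValueError("intervention_cost_mean must be positive")
        if self.inpatient_cost_mean <= 0 or self.ed_cost_mean <= 0:
            raise ValueError("unit-cost means must be positive")
        if min(
            self.intervention_cost_cv,
            self.inpatient_cost_sd,
            self.ed_cost_sd,
            self.mean_inpatient_visits,
            self.mean_ed_visits,
        ) < 0:
            raise ValueError("dispersions and visit means must be nonnegative")
        if self.zero_denominator_policy not in ("redraw", "drop", "cap"):
            raise ValueError(
                f"unknown zero_denominator_policy {self.zero_denominator_policy!r}"
            )


def gamma_moments_to_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters: shape = (mean/sd)², scale = sd²/mean."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    if sd <= 0:
        raise ValueError("gamma sd must be positive")
    return (mean / sd) ** 2, sd**2 / mean


def _gamma_draws(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    if sd == 0:  # degenerate limit: a point mass at the mean
        return np.full(size, mean)
    shape, scale = gamma_moments_to_params(mean, sd)
    return rng.gamma(shape, scale, size)


def _poisson_draws(
    rng: np.random.Generator, mean: float, size: int, fixed: bool
) -> np.ndarray:
    if fixed:
        return np.full(size, mean)
    return rng.poisson(mean, size).astype(float)


def draw_inputs(
    config: PSAConfig, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``size`` joint samples of (C, c_ip, c_ed, n_ip, n_ed).

    Costs are positive reals; visit counts are nonnegative integers unless
    ``fixed_visit_counts`` pins them at their (possibly fractional) means.
    """
    C = _gamma_draws(
        rng,
        config.intervention_cost_mean,
        config.intervention_cost_cv * config.intervention_cost_mean,
        size,
    )
    c_ip = _gamma_draws(rng, config.inpatient_cost_mean, config.inpatient_cost_sd, size)
    c_ed = _gamma_draws(rng, config.ed_cost_mean, config.ed_cost_sd, size)
    n_ip = _poisson_draws(
        rng, config.mean_inpatient_visits, size, config.fixed_visit_counts
    )
    n_ed = _poisson_draws(rng, config.mean_ed_visits, size, config.fixed_visit_counts)
    return C, c_ip, c_ed, n_ip, n_ed


@dataclass(frozen=True)
class PSAResult:
    """Per-draw savings thresholds (%) and their summary statistics.

    ``probable_interval_95`` is the (2.5th, 97.5th) percentile pair computed
    by linear interpolation between order statistics; ``n_excluded`` counts
    zero-denominator draws handled by the configured policy.
    """

    thresholds: np.ndarray
    mean: float
    median: float
    probable_interval_95: tuple[float, float]
    n_excluded: int
    config: PSAConfig


_MAX_REDRAW_ROUNDS = 100


def run_psa(config: PSAConfig) -> PSAResult:
    """Run the Monte Carlo and summarize the savings-threshold distribution.

    Fully reproducible for a fixed ``config.seed``. Raises if the
    configuration yields no valid draw (e.g. both visit means zero with
    fixed counts).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_draws
    C, c_ip, c_ed, n_ip, n_ed = draw_inputs(config, rng, n)
    denom = n_ip * c_ip + n_ed * c_ed
    n_excluded = 0

    policy = config.zero_denominator_policy
    if policy == "redraw":
        for _ in range(_MAX_REDRAW_ROUNDS):
            bad = denom == 0
            k = int(bad.sum())
            if k == 0:
                break
            n_excluded += k
            C[bad], c_ip[bad], c_ed[bad], n_ip[bad], n_ed[bad] = draw_inputs(
                config, rng, k
            )
            denom = n_ip * c_ip + n_ed * c_ed
        if (denom == 0).any():
            raise RuntimeError(
                "zero-denominator draws persist after redrawing; the configured "
                "visit means make a denominator of zero (near-)certain"
            )
        thresholds = 100.0 * C / denom
    elif policy == "drop":
        keep = denom > 0
        n_excluded = int(n - keep.sum())
        if not keep.any():
            raise RuntimeError(
                "all draws had zero denominators; nothing to summarize under "
                "the 'drop' policy"
            )
        thresholds = 100.0 * C[keep] / denom[keep]
    else:  # cap
        bad = denom == 0
        n_excluded = int(bad.sum())
        thresholds = np.where(bad, config.cap_pct, 100.0 * C / np.where(bad, 1.0, denom))

    return PSAResult(
        thresholds=thresholds,
        mean=float(thresholds.mean()),
        median=float(np.median(thresholds)),
        probable_interval_95=probable_interval(thresholds),
        n_excluded=n_excluded,
        config=config,
    )


def summarize_psa(result: PSAResult) -> dict[str, float | int]:
    """One report row: median, mean, 95% probable interval (1 decimal each),
    plus draw and exclusion counts."""
    if result.thresholds.size == 0:
        raise ValueError("empty threshold vector")
    lo, hi = result.probable_interval_95
    return {
        "median_pct": round(result.median, 1),
        "mean_pct": round(result.mean, 1),
        "pi95_low_pct": round(lo, 1),
        "pi95_high_pct": round(hi, 1),
        "n_draws": int(result.thresholds.size),
        "n_excluded": result.n_excluded,
    }
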