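"""Power and type-I-error characterization of the slope test.

The screen's test statistic is the two-sided slope t-test of a simple linear
regression.  Its power at true slope b1, residual standard deviation sigma
and age design x_1..x_n is governed by the noncentral t distribution with
noncentrality

    ncp = b1 * sqrt(Sxx) / sigma,     Sxx = sum (x_i - xbar)^2,

on n - 2 degrees of freedom: power = P(|T'| > t_{1-alpha/2}).  A uniform
age design on [0.33, 40] with n samples is represented deterministically by
its n quantile midpoints, so the analytic and Monte-Carlo routes share one
design and agree up to simulation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .age_screen import ScreenConfig, screen_all
from .synthetic_data import AGE_MAX, AGE_MIN, SimConfig, generate_dataset

__all__ = [
    "PowerSpec",
    "uniform_age_design",
    "analytic_power",
    "mc_power",
    "empirical_type1",
    "power_grid",
]


def uniform_age_design(
    n: int, lo: float = AGE_MIN, hi: float = AGE_MAX
) -> np.ndarray:
    """Deterministic n-point design of uniform-[lo, hi] quantile midpoints."""
    if n < 3:
        raise ValueError("need n >= 3 for a slope test")
    return lo + (hi - lo) * (np.arange(n) + 0.5) / n


@dataclass
class PowerSpec:
    """One power scenario: effect size, noise, age design and test size."""

    true_slope: float
    noise_sd: float
    ages: np.ndarray | None = None
    n: int | None = None
    alpha: float = 0.05

    def design(self) -> np.ndarray:
        if self.ages is not None:
            ages = np.asarray(self.ages, dtype=float)
        elif self.n is not None:
            ages = uniform_age_design(self.n)
        else:
            raise ValueError("provide either an age list or n")
        if ages.size < 3:
            raise ValueError("need at least 3 ages")
        if np.ptp(ages) == 0:
            raise ValueError("age design must have positive variance")
        return ages

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.design()


def analytic_power(spec: PowerSpec) -> float:
    """Exact power of the two-sided slope t-test via the noncentral t.

    At true slope 0 this equals alpha (the test's size) exactly.
    """
    spec.validate()
    ages = spec.design()
    n = ages.size
    dof = n - 2
    sxx = float(((ages - ages.mean()) ** 2).sum())
    ncp = spec.true_slope * np.sqrt(sxx) / spec.noise_sd
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, dof)
    upper = stats.nct.sf(tcrit, dof, ncp)
    lower = stats.nct.cdf(-tcrit, dof, ncp)
    # the far tail can underflow to NaN in scipy's noncentral-t at large |ncp|
    if not np.isfinite(upper):
        upper = 1.0 if ncp > 0 else 0.0
    if not np.isfinite(lower):
        lower = 0.0 if ncp > 0 else 1.0
    return float(min(max(upper + lower, 0.0), 1.0))


def mc_power(spec: PowerSpec, reps: int = 20_000, seed: int = 0) -> float:
    """Monte-Carlo power: simulate Gaussian responses on the fixed design."""
    spec.validate()
    ages = spec.design()
    n = ages.size
    dof = n - 2
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(reps, n))
    Y = spec.true_slope * ages[None, :] + noise
    xc = ages - ages.mean()
    sxx = float(xc @ xc)
    slopes = (Y - Y.mean(axis=1, keepdims=True)) @ xc / sxx
    resid = Y - Y.mean(axis=1, keepdims=True) - slopes[:, None] * xc[None, :]
    rss = np.einsum("ij,ij->i", resid, resid)
    se = np.sqrt(rss / dof / sxx)
    t = slopes / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return float(np.mean(p < spec.alpha))


def empirical_type1(
    n_pairs: int,
    n_samples: int,
    alpha: float = 0.05,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Empirical type-I error of the screen on simulated null data.

    Generates ``n_pairs`` gene-region pairs with zero true slope through the
    synthetic-data generator (``n_samples`` donors with uniform ages, full
    coverage), runs the screen, and returns the fraction of pairs rejected
    at ``alpha`` together with the null p-values.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    from .data_io import REGION_CODES  # local import avoids cycle at module load

    if n_pairs % len(REGION_CODES) == 0:
        regions = REGION_CODES
        n_genes = n_pairs // len(REGION_CODES)
    else:
        regions = (REGION_CODES[0],)
        n_genes = n_pairs
    config = SimConfig(
        n_genes=n_genes,
        n_donors=n_samples,
        regions=tuple(regions),
        frac_age_linear=0.0,
        intercept_range=(20.0, 50.0),
        noise_sd=noise_sd,
        missing_rate=0.0,
        seed=seed,
    )
    matrix, samples, _ = generate_dataset(config)
    results = screen_all(matrix, samples, config=ScreenConfig(alpha_raw=max(alpha, 1e-12)))
    p = results.loc[results["status"] == "ok", "p"].to_numpy(float)
    return float(np.mean(p < alpha)), p


def power_grid(
    slopes,
    ns,
    noise_sd: float,
    alpha: float = 0.05,
    mc_reps: int | None = None,
    seed: int = 0,
):
    """Analytic (and optionally Monte-Carlo) power over a slope x n grid.

    Returns a DataFrame with columns slope, n, power (and mc_power when
    ``mc_reps`` is given).
    """
    import pandas as pd

    rows = []
    for slope in slopes:
        for n in ns:
            spec = PowerSpec(
                true_slope=float(slope), noise_sd=noise_sd, n=int(n),
                alpha=alpha,
            )
            row = {"slope": float(slope), "n": int(n),
                   "power": analytic_power(spec)}
            if mc_reps:
                row["mc_power"] = mc_power(spec, reps=mc_reps, seed=seed)
            rows.append(row)
    return pd.DataFrame(rows)
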