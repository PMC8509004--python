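"""Per-gene, per-region linear age-trend screen.

For every (gene, region) pair the expression level is regressed on donor age
in years by ordinary least squares:

    expr = b0 + b1 * age + eps,    eps ~ N(0, sigma^2)

The slope b1 (the "regression coefficient", expression units per year) is
tested against zero with the usual two-sided t statistic on n-2 degrees of
freedom.  Genes with raw p below ``alpha_raw`` in a region are called
differentially expressed genes with age (DEGAs) there, with direction given
by the slope sign; a second, higher-confidence tier flags pairs that also
pass a Benjamini–Hochberg FDR threshold computed across the whole screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, GeneAnnotation, REGION_CODES, as_samples_frame

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_PERFECT = "perfect_fit"
STATUS_DEGENERATE = "degenerate"

#: Cap applied to -log10(p) in volcano tables when p underflows (p = 0).
NEG_LOG10_P_CAP = 300.0

#: Relative residual threshold below which a fit counts as exact (RSS = 0).
_PERFECT_RTOL = 1e-12


@dataclass
class ScreenConfig:
    """Thresholds of the screen.

    alpha_raw : raw-p cutoff defining DEGAs (default 0.05).
    fdr_alpha : BH FDR threshold for the higher-confidence tier (default 0.05).
    min_samples : minimum samples per fit; below it the pair is flagged
        degenerate (3 leaves one residual degree of freedom).
    per_region_fdr : apply BH within each region instead of across the whole
        screen (default off: the screen is one joint search).
    """

    alpha_raw: float = 0.05
    fdr_alpha: float = 0.05
    min_samples: int = 3
    per_region_fdr: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha_raw < 1:
            raise ValueError("alpha_raw must lie in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


@dataclass
class RegressionResult:
    """One gene-region OLS fit (q_value attached only by the full screen)."""

    gene: str | None
    region: str | None
    n_samples: int
    intercept: float
    slope: float
    se_slope: float
    t_stat: float
    p_value: float
    r_squared: float
    status: str
    q_value: float | None = None
    direction: str = "none"


def _ols_stats(x: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized simple-OLS statistics for many responses on one design.

    ``x`` has shape (n,), ``Y`` shape (G, n).  Returns slope, intercept,
    se, t, p, r2 and a status array.  Exact fits (relative RSS below
    ``_PERFECT_RTOL``) get p = 0 and status ``perfect_fit``; responses with
    zero variance get slope 0, t 0, p 1, r2 0.
    """
    n = x.size
    dof = n - 2
    xm = x.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    ym = Y.mean(axis=1)
    yc = Y - ym[:, None]
    slope = (yc @ xc) / sxx
    intercept = ym - slope * xm
    resid = yc - slope[:, None] * xc[None, :]
    rss = np.einsum("ij,ij->i", resid, resid)
    tss = np.einsum("ij,ij->i", yc, yc)

    constant = tss <= 0.0
    perfect = (~constant) & (rss <= _PERFECT_RTOL * np.maximum(tss, 1.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        r2 = 1.0 - rss / tss

    status = np.full(Y.shape[0], STATUS_OK, dtype=object)
    status[perfect] = STATUS_PERFECT
    t[perfect] = np.sign(slope[perfect]) * np.inf
    p[perfect] = 0.0
    r2[perfect] = 1.0

    slope[constant] = 0.0
    intercept[constant] = ym[constant]
    se[constant] = 0.0
    t[constant] = 0.0
    p[constant] = 1.0
    r2[constant] = 0.0
    return {
        "slope": slope, "intercept": intercept, "se": se,
        "t": t, "p": p, "r2": r2, "status": status,
    }


def fit_age_regression(
    ages, expr, min_samples: int = 3
) -> RegressionResult:
    """Fit one gene-region age regression.

    Degenerate inputs (fewer than ``min_samples`` observations, or zero age
    variance) are returned with status ``degenerate`` and NaN statistics
    rather than raised, so that partial-coverage designs keep a complete
    result grid.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and expr must be 1-D arrays of equal length")
    n = x.size
    if n < min_samples or n < 3 or np.ptp(x) == 0.0:
        return RegressionResult(
            gene=None, region=None, n_samples=n,
            intercept=math.nan, slope=math.nan, se_slope=math.nan,
            t_stat=math.nan, p_value=math.nan, r_squared=math.nan,
            status=STATUS_DEGENERATE,
        )
    s = _ols_stats(x, y[None, :])
    return RegressionResult(
        gene=None, region=None, n_samples=n,
        intercept=float(s["intercept"][0]), slope=float(s["slope"][0]),
        se_slope=float(s["se"][0]), t_stat=float(s["t"][0]),
        p_value=float(s["p"][0]), r_squared=float(s["r2"][0]),
        status=str(s["status"][0]),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def screen_all(
    matrix: ExpressionMatrix,
    samples,
    gene_list=None,
    regions=None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full screen: one row per (gene, region) pair.

    ``gene_list`` may be a list of :class:`GeneAnnotation` or of symbols;
    default is every gene in the matrix.  ``regions`` defaults to the region
    codes present in ``samples`` (in controlled-vocabulary order).  Pairs
    that cannot be fit — a listed gene absent from the matrix, a region with
    too few samples or no age variance — are flagged ``degenerate``, not
    dropped.  q-values are attached by BH over all successful fits (globally
    by default, per region if configured).

    Returns a DataFrame with columns: gene, region, n, intercept, slope,
    se, t, p, q, r2, status.
    """
    config = config or ScreenConfig()
    config.validate()
    sf = as_samples_frame(samples)
    if gene_list is None:
        genes = list(matrix.gene_symbols)
    else:
        genes = [
            g.symbol if isinstance(g, GeneAnnotation) else str(g)
            for g in gene_list
        ]
    if not genes:
        raise ValueError("empty gene list")
    if regions is None:
        present = set(sf["region"])
        regions = [r for r in REGION_CODES if r in present]
    if not regions:
        raise ValueError("no usable regions")

    in_matrix = set(matrix.gene_symbols)
    known = [g for g in genes if g in in_matrix]
    missing = [g for g in genes if g not in in_matrix]
    if missing:
        log.warning(
            "%d listed genes absent from the matrix (flagged degenerate), "
            "e.g. %s", len(missing), missing[:5],
        )

    frames: list[pd.DataFrame] = []
    nan = np.nan
    for region in regions:
        ids = sf.loc[sf["region"] == region, "sample_id"].tolist()
        ages = sf.loc[sf["region"] == region, "age_years"].to_numpy(float)
        n = len(ids)
        usable = n >= config.min_samples and np.ptp(ages) > 0.0
        if usable and known:
            Y = matrix.data.loc[known, ids].to_numpy(dtype=float)
            s = _ols_stats(ages, Y)
            frame = pd.DataFrame(
                {
                    "gene": known, "region": region, "n": n,
                    "intercept": s["intercept"], "slope": s["slope"],
                    "se": s["se"], "t": s["t"], "p": s["p"],
                    "r2": s["r2"], "status": s["status"],
                }
            )
        else:
            frame = pd.DataFrame(
                {
                    "gene": known, "region": region, "n": n,
                    "intercept": nan, "slope": nan, "se": nan, "t": nan,
                    "p": nan, "r2": nan, "status": STATUS_DEGENERATE,
                }
            )
        if missing:
            frame = pd.concat(
                [
                    frame,
                    pd.DataFrame(
                        {
                            "gene": missing, "region": region, "n": 0,
                            "intercept": nan, "slope": nan, "se": nan,
                            "t": nan, "p": nan, "r2": nan,
                            "status": STATUS_DEGENERATE,
                        }
                    ),
                ],
                ignore_index=True,
            )
        # restore requested gene order within the region
        frame = frame.set_index("gene").loc[genes].reset_index()
        frames.append(frame)

    results = pd.concat(frames, ignore_index=True)
    results["q"] = np.nan
    fit_mask = results["status"].isin([STATUS_OK, STATUS_PERFECT])
    if config.per_region_fdr:
        for region in regions:
            mask = fit_mask & (results["region"] == region)
            if mask.any():
                results.loc[mask, "q"] = bh_fdr(results.loc[mask, "p"])
    elif fit_mask.any():
        results.loc[fit_mask, "q"] = bh_fdr(results.loc[fit_mask, "p"])
    return results[
        ["gene", "region", "n", "intercept", "slope", "se", "t", "p", "q",
         "r2", "status"]
    ]


@dataclass
class DegaSets:
    """Per-region DEGA membership with direction, plus the FDR tier.

    ``by_region`` maps region -> {gene: "up" | "down"}; ``fdr_by_region``
    holds the subset also passing the FDR threshold.
    """

    regions: tuple[str, ...]
    by_region: dict[str, dict[str, str]]
    fdr_by_region: dict[str, set[str]] = field(default_factory=dict)

    def genes(self, region: str) -> set[str]:
        return set(self.by_region[region])

    def union_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.by_region.values():
            out.update(members)
        return out


def annotate_degas(results: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Return a copy of the screen results with dega/direction/fdr columns."""
    config = config or ScreenConfig()
    out = results.copy()
    fit = out["status"].isin([STATUS_OK, STATUS_PERFECT])
    dega = fit & (out["p"] < config.alpha_raw) & (out["slope"] != 0.0)
    out["dega"] = dega
    out["direction"] = np.where(
        dega & (out["slope"] > 0), "up",
        np.where(dega & (out["slope"] < 0), "down", "none"),
    )
    out["fdr_pass"] = dega & (out["q"] <= config.fdr_alpha)
    return out


def call_degas(results: pd.DataFrame, config: ScreenConfig | None = None) -> DegaSets:
    """Call DEGAs from the screen results.

    A pair is a DEGA iff the fit succeeded and p < alpha_raw; direction is
    the slope sign.  Pairs additionally passing q <= fdr_alpha populate the
    higher-confidence tier.
    """
    annotated = annotate_degas(results, config)
    regions = tuple(pd.unique(annotated["region"]))
    by_region: dict[str, dict[str, str]] = {r: {} for r in regions}
    fdr_by_region: dict[str, set[str]] = {r: set() for r in regions}
    hits = annotated[annotated["dega"]]
    for row in hits.itertuples(index=False):
        by_region[row.region][row.gene] = row.direction
        if row.fdr_pass:
            fdr_by_region[row.region].add(row.gene)
    return DegaSets(regions=regions, by_region=by_region,
                    fdr_by_region=fdr_by_region)


def region_summary(
    dega_sets: DegaSets, n_screened_genes: int
) -> pd.DataFrame:
    """Per-region DEGA counts plus an ALL row for the whole-screen union.

    Columns: region, n_dega, n_up, n_down, pct_of_panel (100 * n / panel
    size).  The ALL row counts the union of DEGAs over regions.
    """
    rows = []
    for region in dega_sets.regions:
        members = dega_sets.by_region[region]
        up = sum(1 for d in members.values() if d == "up")
        down = sum(1 for d in members.values() if d == "down")
        rows.append(
            {
                "region": region, "n_dega": len(members),
                "n_up": up, "n_down": down,
                "pct_of_panel": 100.0 * len(members) / n_screened_genes,
            }
        )
    union = dega_sets.union_genes()
    rows.append(
        {
            "region": "ALL", "n_dega": len(union),
            "n_up": np.nan, "n_down": np.nan,
            "pct_of_panel": 100.0 * len(union) / n_screened_genes,
        }
    )
    return pd.DataFrame(rows)


def volcano_table(
    results: pd.DataFrame, region: str, cap: float = NEG_LOG10_P_CAP
) -> pd.DataFrame:
    """Volcano-plot backing table for one region.

    One row per successfully fit gene: gene, slope, neg_log10_p, direction.
    p = 0 (exact fits) maps to the documented cap.
    """
    if region not in set(results["region"]):
        raise KeyError(f"unknown region: {region!r}")
    sub = results[
        (results["region"] == region)
        & results["status"].isin([STATUS_OK, STATUS_PERFECT])
    ]
    annotated = annotate_degas(sub)
    with np.errstate(divide="ignore"):
        y = -np.log10(annotated["p"].to_numpy(float))
    y = np.minimum(y, cap)
    return pd.DataFrame(
        {
            "gene": annotated["gene"].to_numpy(),
            "slope": annotated["slope"].to_numpy(),
            "neg_log10_p": y,
            "direction": annotated["direction"].to_numpy(),
        }
    )


def age_group_fold_change(
    matrix: ExpressionMatrix,
    samples,
    gene: str,
    region: str,
    bin_width: float = 5.0,
) -> float:
    """Fold change between the last and first age bins for one gene-region.

    Ages are binned as [0, w), [w, 2w), …, with the final bin closed at 40
    years; the result is mean(last bin) / mean(first bin).

    Raises
    ------
    ValueError
        If either bin is empty or the first-bin mean is zero.
    """
    sf = as_samples_frame(samples)
    sub = sf[sf["region"] == region]
    if sub.empty:
        raise ValueError(f"no samples in region {region!r}")
    ages = sub["age_years"].to_numpy(float)
    values = matrix.data.loc[gene, sub["sample_id"]].to_numpy(float)
    n_bins = int(np.ceil(40.0 / bin_width))
    last_start = (n_bins - 1) * bin_width
    first = values[ages < bin_width]
    last = values[(ages >= last_start) & (ages <= 40.0)]
    if first.size == 0 or last.size == 0:
        raise ValueError(
            f"empty first or last {bin_width}-year age bin for {gene}/{region}"
        )
    first_mean = float(first.mean())
    if first_mean == 0.0:
        raise ValueError("first-bin mean expression is zero")
    return float(last.mean()) / first_mean
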