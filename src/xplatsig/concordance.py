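"""Cross-platform expression concordance.

Given a merged two-platform dataset (row i of matrix A measures the same
transcript as row i of matrix B), this module quantifies agreement three
ways:

* per-pair Pearson correlation of the two probes' expression profiles
  across the shared samples;
* rank tests on those correlations — Kruskal-Wallis across genomic
  distance bins (<500 bp, 500–1000 bp, >1000 bp) and Mann-Whitney for
  mutual-best-match vs non-mutual pairs;
* a two-segment ("bilinear") least-squares fit of one platform's signal
  against the other's, capturing the empirical pattern that the two
  platforms track each other with different slopes below and above an
  expression threshold.

The bilinear fit is a breakpoint grid search: candidate breakpoints are
x-quantiles from 5% to 95% in 1% steps; at each candidate an ordinary
least-squares line is fitted on each side and the breakpoint minimising
total SSE wins.  The two segments are deliberately NOT constrained to be
continuous; the gap at the breakpoint is reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistanceBins",
    "BIN_LABELS",
    "bin_by_distance",
    "ConcordanceReport",
    "pairwise_expression_correlation",
    "kruskal_wallis_across_bins",
    "mann_whitney_mutual_vs_nonmutual",
    "BilinearModel",
    "BilinearResults",
    "fit_bilinear",
]

BIN_LABELS = ("lt500", "500to1000", "gt1000")


@dataclass(frozen=True)
class DistanceBins:
    """Genomic-distance bin edges in bp; default (500, 1000)."""

    edges: tuple = (500.0, 1000.0)

    def __post_init__(self):
        lo, hi = self.edges
        if not lo < hi:
            raise ValueError("bin edges must be strictly increasing")


def bin_by_distance(distance_bp, bins: DistanceBins = DistanceBins()):
    """Assign a distance (or array of distances) to its bin label.

    ``d < lo`` -> ``lt500``; ``lo <= d <= hi`` -> ``500to1000``;
    ``d > hi`` -> ``gt1000``.  Both boundaries therefore fall in the
    middle bin.  Negative distances are rejected.
    """
    lo, hi = bins.edges
    d = np.asarray(distance_bp, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    labels = np.where(d < lo, BIN_LABELS[0],
                      np.where(d <= hi, BIN_LABELS[1], BIN_LABELS[2]))
    if np.isscalar(distance_bp) or np.ndim(distance_bp) == 0:
        return str(labels[()])
    return labels


@dataclass
class ConcordanceReport:
    """Per-pair correlation table plus summary statistics.

    ``pairs`` has columns probe_a, probe_b, gene_id, distance_bp, mutual,
    bin, pearson_r.  Zero-variance probes produce NaN correlations; they
    are excluded from the rank tests and counted in
    ``n_excluded_zero_variance``.
    """

    pairs: pd.DataFrame
    n_samples: int
    n_excluded_zero_variance: int = 0
    stats: dict = field(default_factory=dict)

    @property
    def n_per_bin(self) -> dict:
        counts = self.pairs["bin"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in BIN_LABELS}

    def valid_r(self) -> pd.DataFrame:
        return self.pairs[np.isfinite(self.pairs["pearson_r"])]

    def summary_dict(self) -> dict:
        out = {
            "n_pairs": int(len(self.pairs)),
            "n_samples": self.n_samples,
            "n_excluded_zero_variance": self.n_excluded_zero_variance,
            "n_per_bin": self.n_per_bin,
            "median_r_per_bin": {
                lab: float(np.median(grp))
                for lab, grp in self.valid_r().groupby("bin")["pearson_r"]
            },
        }
        out.update(self.stats)
        return out


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two equal-shape matrices.

    Rows with zero variance on either side give NaN.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def pairwise_expression_correlation(merged, bins: DistanceBins = DistanceBins()
                                    ) -> ConcordanceReport:
    """Correlate each matched probe pair's profiles across shared samples.

    ``merged`` is a :class:`~xplatsig.probes.MergedDataset` (duck-typed:
    needs ``.a``, ``.b`` row-aligned DataFrames and a ``.pairs`` table).
    Requires at least 3 samples.
    """
    a, b = merged.a, merged.b
    if a.shape[1] < 3:
        raise ValueError("need >= 3 shared samples to correlate profiles")
    r = _rowwise_pearson(a.to_numpy(float), b.to_numpy(float))
    pairs = merged.pairs.reset_index(drop=True).copy()
    pairs["pearson_r"] = r
    pairs["bin"] = bin_by_distance(pairs["distance_bp"].to_numpy(), bins)
    n_bad = int(np.isnan(r).sum())
    return ConcordanceReport(pairs=pairs, n_samples=int(a.shape[1]),
                             n_excluded_zero_variance=n_bad)


def kruskal_wallis_across_bins(report: ConcordanceReport):
    """Kruskal-Wallis H (tie-corrected) on per-pair r grouped by distance bin."""
    valid = report.valid_r()
    groups = [grp["pearson_r"].to_numpy()
              for _, grp in valid.groupby("bin") if len(grp)]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty distance bins")
    h, p = stats.kruskal(*groups)
    report.stats["kw_statistic"] = float(h)
    report.stats["kw_p"] = float(p)
    return float(h), float(p)


def mann_whitney_mutual_vs_nonmutual(report: ConcordanceReport):
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected) on
    per-pair r split by the mutual-best-match flag.  Returns U for the
    mutual group and the p-value."""
    valid = report.valid_r()
    mutual = valid.loc[valid["mutual"], "pearson_r"].to_numpy()
    other = valid.loc[~valid["mutual"], "pearson_r"].to_numpy()
    if len(mutual) == 0 or len(other) == 0:
        raise ValueError("both mutual and non-mutual groups must be non-empty")
    u, p = stats.mannwhitneyu(mutual, other, alternative="two-sided",
                              method="asymptotic")
    report.stats["mwu_statistic"] = float(u)
    report.stats["mwu_p"] = float(p)
    return float(u), float(p)


# ---------------------------------------------------------------------------
# bilinear (two-segment) fit


@dataclass
class BilinearResults:
    """Parameters of a two-segment OLS fit of y on x."""

    breakpoint_x: float
    slope_low: float
    intercept_low: float
    slope_high: float
    intercept_high: float
    sse: float
    frac_above: float
    n: int
    continuity_gap: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        low = self.intercept_low + self.slope_low * x
        high = self.intercept_high + self.slope_high * x
        return np.where(x <= self.breakpoint_x, low, high)

    def summary(self) -> str:
        lines = [
            "Two-segment linear fit (breakpoint grid search)",
            f"  n points          {self.n}",
            f"  breakpoint (x)    {self.breakpoint_x:.4f}",
            f"  fraction above    {self.frac_above:.3f}",
            f"  low segment       y = {self.intercept_low:.4f} + {self.slope_low:.4f} x",
            f"  high segment      y = {self.intercept_high:.4f} + {self.slope_high:.4f} x",
            f"  SSE               {self.sse:.6g}",
            f"  gap at breakpoint {self.continuity_gap:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "breakpoint_x": self.breakpoint_x,
            "slope_low": self.slope_low,
            "intercept_low": self.intercept_low,
            "slope_high": self.slope_high,
            "intercept_high": self.intercept_high,
            "sse": self.sse,
            "frac_above": self.frac_above,
            "n": self.n,
            "continuity_gap": self.continuity_gap,
        }


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, SSE of OLS y ~ x; degenerate x -> horizontal line."""
    n = len(x)
    if n == 0:
        return 0.0, 0.0, 0.0
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0.0:
        resid = y - ym
        return 0.0, ym, float((resid**2).sum())
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    return float(slope), float(intercept), float((resid**2).sum())


class BilinearModel:
    """Two-segment regression of platform-B signal on platform-A signal.

    ``fit`` scans candidate breakpoints over x-quantiles (5%..95%, 1%
    steps by default), fits OLS independently on the points at or below
    and above each candidate, and keeps the candidate with minimal total
    SSE.  Segments are not constrained to meet; the discontinuity at the
    chosen breakpoint is reported as ``continuity_gap``.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        mask = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[mask], y[mask]
        if len(self.x) < 20:
            raise ValueError("need >= 20 points for a two-segment fit")
        if np.ptp(self.x) == 0:
            raise ValueError("x is constant; breakpoint search is undefined")

    def fit(self, q_lo: float = 0.05, q_hi: float = 0.95,
            q_step: float = 0.01) -> BilinearResults:
        order = np.argsort(self.x, kind="stable")
        xs, ys = self.x[order], self.y[order]
        quantiles = np.arange(q_lo, q_hi + q_step / 2, q_step)
        candidates = np.unique(np.quantile(xs, quantiles))

        def scan(cands):
            best = None
            for bp in cands:
                k = int(np.searchsorted(xs, bp, side="right"))
                if k < 2 or len(xs) - k < 2:
                    continue
                s_lo, i_lo, sse_lo = _ols_line(xs[:k], ys[:k])
                s_hi, i_hi, sse_hi = _ols_line(xs[k:], ys[k:])
                sse = sse_lo + sse_hi
                if best is None or sse < best[0] - 1e-12:
                    best = (sse, bp, s_lo, i_lo, s_hi, i_hi, len(xs) - k)
            return best

        best = scan(candidates)
        if best is None:
            raise ValueError("no admissible breakpoint candidate")
        # local refinement: interpolated quantiles rarely coincide with
        # observed values, so also try every data value within one grid
        # step of the winning candidate — exact segment boundaries
        i = int(np.searchsorted(candidates, best[1]))
        lo = candidates[max(i - 1, 0)]
        hi = candidates[min(i + 1, len(candidates) - 1)]
        window = np.unique(xs[(xs >= lo) & (xs <= hi)])
        refined = scan(window)
        if refined is not None and refined[0] < best[0] - 1e-12:
            best = refined
        sse, bp, s_lo, i_lo, s_hi, i_hi, n_above = best
        gap = (i_hi + s_hi * bp) - (i_lo + s_lo * bp)
        return BilinearResults(
            breakpoint_x=float(bp), slope_low=s_lo, intercept_low=i_lo,
            slope_high=s_hi, intercept_high=i_hi, sse=float(sse),
            frac_above=n_above / len(xs), n=len(xs),
            continuity_gap=float(gap),
        )


def fit_bilinear(x, y, **kwargs) -> BilinearResults:
    """Convenience wrapper: ``BilinearModel(x, y).fit(**kwargs)``."""
    return BilinearModel(x, y).fit(**kwargs)
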