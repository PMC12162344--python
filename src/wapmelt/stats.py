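"""Statistical comparisons: correlation screening and the two-period
Welch test.

The analysis chain mirrors standard practice for comparing two climate
periods of a regional daily series: per-group Shapiro–Wilk normality
p-values and a mean-centred Levene variance-homogeneity p-value are
reported for interpretation, and the decision statistic is Welch's t-test,

    t  = (x̄_a − x̄_b) / sqrt(s²_a/n_a + s²_b/n_b)
    df = (s²_a/n_a + s²_b/n_b)² /
         [ (s²_a/n_a)²/(n_a−1) + (s²_b/n_b)²/(n_b−1) ]     (Welch–Satterthwaite)

which tolerates unequal variances and unequal sample sizes.  Welch's t is
implemented from the formula above (it carries the inference); the
screening tests delegate to scipy.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import InsufficientDataError, InvalidInputError

#: Shapiro–Wilk loses validity for very large n; above this cap a fixed-seed
#: subsample is tested instead and the result flagged.
SHAPIRO_CAP = 5000


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the pair count actually used."""

    r: float
    p: float
    n: int
    transform: str  # "identity" | "log10-y"


@dataclass(frozen=True)
class PeriodComparison:
    """Full two-period comparison record."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    shapiro_subsampled: bool
    levene_p: float
    welch_t: float
    welch_df: float
    welch_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def correlate(x, y, transform: str = "identity") -> CorrelationResult:
    """Pearson correlation between two series, missing-aware.

    Pairs with any missing member are excluded.  ``transform="log10-y"``
    applies log10 to y first (all remaining y must be positive); this is
    the natural choice when y is chlorophyll-a, whose distribution is
    close to log-normal.

    The two-sided p-value comes from the t-distribution with n − 2 degrees
    of freedom.
    """
    if transform not in ("identity", "log10-y"):
        raise InvalidInputError(f"unknown transform {transform!r}")
    xs = pd.Series(np.asarray(x, dtype=float).ravel())
    ys = pd.Series(np.asarray(y, dtype=float).ravel())
    if len(xs) != len(ys):
        raise InvalidInputError("x and y must have equal length")
    ok = xs.notna() & ys.notna()
    xs, ys = xs[ok], ys[ok]
    if transform == "log10-y":
        bad = ys <= 0
        if bad.any():
            raise InvalidInputError(
                "log10-y transform requires positive y; offending indices: "
                f"{list(ys.index[bad][:10])}")
        ys = np.log10(ys)
    n = len(xs)
    if n < 3:
        raise InsufficientDataError(f"correlation needs >= 3 pairs, got {n}")
    r, p = _sps.pearsonr(xs.to_numpy(), ys.to_numpy())
    return CorrelationResult(float(r), float(p), n, transform)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with t for mean(a) − mean(b), Welch–Satterthwaite
    degrees of freedom, and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    sa, sb = va / na, vb / nb
    if sa + sb == 0:
        if a.mean() == b.mean():
            raise InvalidInputError(
                "t undefined: zero variance in both groups and equal means")
        return float("inf") * np.sign(a.mean() - b.mean()), float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _shapiro_p(x: np.ndarray, seed: int = 0) -> tuple[float, bool]:
    if len(x) > SHAPIRO_CAP:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, SHAPIRO_CAP, replace=False)
        return float(_sps.shapiro(x).pvalue), True
    return float(_sps.shapiro(x).pvalue), False


def compare_periods(series: pd.DataFrame | pd.Series, split,
                    djf_only: bool = True,
                    label_a: str | None = None,
                    label_b: str | None = None) -> PeriodComparison:
    """Compare a regional daily series before/after a date boundary.

    Parameters
    ----------
    series
        Daily regional series (DataFrame with ``value`` column, or Series)
        indexed by date.
    split
        Boundary date: group A is strictly before it, group B at/after.
    djf_only
        Restrict to austral-summer (December–February) days first, the
        season at the peak of the growing season.

    All screening statistics are reported whatever their outcome; they
    inform interpretation but do not gate the Welch test.
    """
    vals = series["value"] if isinstance(series, pd.DataFrame) else series
    vals = vals.dropna()
    idx = pd.DatetimeIndex(vals.index)
    if djf_only:
        keep = idx.month.isin([12, 1, 2])
        vals, idx = vals[keep], idx[keep]
    boundary = pd.Timestamp(split)
    a = vals[idx < boundary].to_numpy(dtype=float)
    b = vals[idx >= boundary].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"both periods need >= 3 values (got {len(a)}, {len(b)})")
    sp_a, sub_a = _shapiro_p(a)
    sp_b, sub_b = _shapiro_p(b)
    levene_p = float(_sps.levene(a, b, center="mean").pvalue)
    t, df, p = welch_t(a, b)
    return PeriodComparison(
        label_a=label_a or f"pre-{boundary.date()}",
        label_b=label_b or f"post-{boundary.date()}",
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        var_a=float(a.var(ddof=1)), var_b=float(b.var(ddof=1)),
        shapiro_p_a=sp_a, shapiro_p_b=sp_b,
        shapiro_subsampled=sub_a or sub_b,
        levene_p=levene_p, welch_t=t, welch_df=df, welch_p=p)


def format_comparison(c: PeriodComparison) -> str:
    """Human-readable report table for one comparison."""
    lines = [
        f"Period comparison: {c.label_a} vs {c.label_b}",
        f"  n                : {c.n_a:>10d}  {c.n_b:>10d}",
        f"  mean             : {c.mean_a:>10.4g}  {c.mean_b:>10.4g}",
        f"  variance         : {c.var_a:>10.4g}  {c.var_b:>10.4g}",
        f"  Shapiro-Wilk p   : {c.shapiro_p_a:>10.3g}  {c.shapiro_p_b:>10.3g}"
        + ("  (subsampled)" if c.shapiro_subsampled else ""),
        f"  Levene p         : {c.levene_p:>10.3g}",
        f"  Welch t, df, p   : {c.welch_t:.4g}, {c.welch_df:.1f}, "
        f"{c.welch_p:.3g}",
    ]
    return "\n".join(lines)
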