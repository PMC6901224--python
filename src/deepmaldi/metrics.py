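"""Reproducibility and information-content analytics over feature tables.

Three views of analytical quality as shot number grows:

* per-feature coefficients of variation over replicate averages of one
  sample (their median falls as shots^-1/2);
* concordance of duplicate runs over a sample set, summarized as the
  median of (1 - Pearson's R);
* the per-feature information content
  S_j = log2( sd over all samples and runs / mean over samples of the
  within-sample sd over runs ), in bits - the log ratio of total to
  technical variability.

Standard deviations use the unbiased (n-1) denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

__all__ = [
    "CVSummary",
    "ConcordanceResult",
    "InfoContent",
    "cv_per_feature",
    "concordance",
    "information_content",
    "fit_power_law",
]


@dataclass(frozen=True)
class CVSummary:
    per_feature: pd.Series = field(repr=False)  # CV in percent, indexed by feature
    median: float
    q25: float
    q75: float
    n_shots: int | None = None
    excluded: tuple = ()

    def __post_init__(self) -> None:
        if not self.q25 <= self.median <= self.q75:
            raise ValueError("CV quartiles out of order")


@dataclass(frozen=True)
class ConcordanceResult:
    per_feature: pd.DataFrame = field(repr=False)  # columns: pearson_r, slope
    median_one_minus_r: float
    flagged: tuple = ()  # features with undefined R (constant in a run)


@dataclass(frozen=True)
class InfoContent:
    per_feature: pd.Series = field(repr=False)  # S_j in bits
    total: float
    excluded: tuple = ()


def cv_per_feature(replicates: FeatureTable, n_shots: int | None = None) -> CVSummary:
    """Per-feature CV (%) over replicate runs of a single sample.

    CV_j = 100 * sd_k f(1, j, k) / mean_k f(1, j, k).  Features with
    zero mean are flagged and excluded from the summary quartiles.
    """
    if len(replicates.samples) != 1:
        raise ValueError("CV analysis expects a table with exactly 1 sample")
    if len(replicates.runs) < 2:
        raise ValueError("CV analysis needs at least 2 replicate runs")
    cube = replicates.cube()[0]  # features x runs
    means = cube.mean(axis=1)
    sds = cube.std(axis=1, ddof=1)
    features = np.asarray(replicates.features)
    ok = means != 0
    cv = pd.Series(100.0 * sds[ok] / means[ok], index=features[ok], name="cv_percent")
    if cv.empty:
        raise ValueError("no feature has a nonzero mean; CV undefined everywhere")
    q25, q50, q75 = np.percentile(cv.to_numpy(), [25.0, 50.0, 75.0])
    return CVSummary(per_feature=cv, median=float(q50), q25=float(q25), q75=float(q75),
                     n_shots=n_shots, excluded=tuple(features[~ok]))


def concordance(run_a: pd.DataFrame, run_b: pd.DataFrame) -> ConcordanceResult:
    """Per-feature agreement of two runs over the same samples.

    For each feature, Pearson's R and the least-squares slope of run B
    on run A across samples; summarized by the median of (1 - R) over
    features where R is defined.  Features constant in either run are
    flagged, not dropped silently.
    """
    if not run_a.index.equals(run_b.index):
        raise ValueError("runs must cover the same samples in the same order")
    if not run_a.columns.equals(run_b.columns):
        raise ValueError("runs must cover the same features")
    if len(run_a) < 3:
        raise ValueError("concordance needs at least 3 samples")
    rows, flagged = {}, []
    for feat in run_a.columns:
        x = run_a[feat].to_numpy(dtype=float)
        y = run_b[feat].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            flagged.append(feat)
            rows[feat] = (np.nan, np.nan)
            continue
        fit = stats.linregress(x, y)
        rows[feat] = (float(fit.rvalue), float(fit.slope))
    per_feature = pd.DataFrame.from_dict(rows, orient="index",
                                         columns=["pearson_r", "slope"])
    defined = per_feature["pearson_r"].dropna()
    if defined.empty:
        raise ValueError("Pearson's R undefined for every feature")
    return ConcordanceResult(per_feature=per_feature,
                             median_one_minus_r=float((1.0 - defined).median()),
                             flagged=tuple(flagged))


def information_content(table: FeatureTable) -> InfoContent:
    """Analytical information content S_j per feature and its total, in bits.

    Numerator: sd of all samples-x-runs values of feature j.
    Denominator: mean over samples of the within-sample sd over runs.
    Features with zero denominator are excluded and reported.
    """
    if len(table.samples) < 2 or len(table.runs) < 2:
        raise ValueError("information content needs >= 2 samples and >= 2 runs")
    cube = table.cube()  # samples x features x runs
    num = cube.transpose(1, 0, 2).reshape(cube.shape[1], -1).std(axis=1, ddof=1)
    den = cube.std(axis=2, ddof=1).mean(axis=0)
    features = np.asarray(table.features)
    ok = den > 0
    s_j = pd.Series(np.log2(num[ok] / den[ok]), index=features[ok], name="S_j_bits")
    return InfoContent(per_feature=s_j, total=float(s_j.sum()),
                       excluded=tuple(features[~ok]))


def fit_power_law(x, y) -> tuple[float, float]:
    """Fit y = C * x^p by ordinary least squares of log y on log x.

    Returns (exponent p, intercept log C in natural log units).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("power-law fit needs >= 3 (x, y) pairs of equal length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return float(slope), float(intercept)
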