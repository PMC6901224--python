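"""Protein-set enrichment analysis (PSEA) of mass-spectral features.

A feature (an integrated m/z interval) is associated with a biological
process without assigning it to a protein: the feature value is
rank-correlated (Spearman) with every protein of a measured abundance
panel, the resulting correlation profile is scored against the protein
set of the process with a weighted running-sum enrichment score, and
significance comes from a null distribution generated by permuting the
feature values across the sample set.  Benjamini-Hochberg adjustment
controls the FDR over features.

The enrichment score is the weighted Kolmogorov-Smirnov-like statistic:
proteins are ranked by decreasing correlation, in-set proteins advance
the running sum proportionally to |rho|^w (w = 1 by default; w = 0
recovers the classic unweighted KS form) and out-of-set proteins
decrement it uniformly; the score is the signed extremum of the running
sum.  P-values are computed on |ES|.
"""

from __future__ import annotations

from itertools import permutations as _all_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, ProteinPanel, ProteinSet

__all__ = [
    "spearman_screen",
    "enrichment_score",
    "permutation_pvalue",
    "bh_fdr",
    "run_psea",
]

EXHAUSTIVE_MAX_SAMPLES = 7
N_PERM_DEFAULT = 499


def _std_ranks(values: np.ndarray) -> np.ndarray:
    """Average-tie ranks, centered and scaled to unit norm (NaN if constant)."""
    r = rankdata(values)
    r = r - r.mean()
    norm = np.sqrt((r ** 2).sum())
    if norm == 0:
        return np.full_like(r, np.nan)
    return r / norm


def _panel_std_ranks(panel: ProteinPanel) -> pd.DataFrame:
    mat = panel.data.to_numpy()
    cols = np.column_stack([_std_ranks(mat[:, j]) for j in range(mat.shape[1])])
    return pd.DataFrame(cols, index=panel.data.index, columns=panel.data.columns)


def spearman_screen(feature_values: pd.Series, panel: ProteinPanel) -> pd.Series:
    """Spearman rho between one feature and every protein of the panel.

    Ties are handled by average ranks.  Constant protein columns give
    NaN (flagged, not dropped); a constant feature is an error.
    """
    if len(feature_values) < 4:
        raise ValueError("Spearman screen needs at least 4 samples")
    if set(feature_values.index) != set(panel.data.index):
        raise ValueError("feature sample ids do not match panel sample ids")
    fv = feature_values.reindex(panel.data.index).to_numpy(dtype=float)
    fz = _std_ranks(fv)
    if np.isnan(fz).all():
        raise ValueError("feature is constant across samples; Spearman undefined")
    pz = _panel_std_ranks(panel).to_numpy()
    rho = fz @ pz
    return pd.Series(rho, index=panel.data.columns, name="spearman_rho")


def _es_many(rho_mat: np.ndarray, in_set: np.ndarray, weight: float) -> np.ndarray:
    """Signed enrichment score for each row of correlations.

    ``rho_mat``: (m, P) correlation rows; ``in_set``: boolean mask of
    length P.  Ranking is by decreasing rho; in-set steps are
    proportional to |rho|^weight, out-of-set steps uniform.
    """
    m, p = rho_mat.shape
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("protein set has empty intersection with the panel")
    if n_in == p:
        raise ValueError("protein set covers the whole panel; no out-of-set proteins")
    # rank on rho rounded to 12 decimals so that mathematically tied
    # correlations (common at small sample counts) tie numerically too,
    # then break ties by panel order (stable sort)
    rho_mat = np.round(rho_mat, 12)
    order = np.argsort(-rho_mat, axis=1, kind="stable")
    in_ord = in_set[order]  # (m, P)
    if weight == 0:
        w = in_ord.astype(float)
    else:
        w = np.where(in_ord, np.abs(np.take_along_axis(rho_mat, order, axis=1)) ** weight, 0.0)
    w_tot = w.sum(axis=1, keepdims=True)
    # all in-set correlations exactly zero: fall back to uniform in-set steps
    flat = (w_tot[:, 0] == 0)
    if flat.any():
        w[flat] = in_ord[flat].astype(float)
        w_tot = w.sum(axis=1, keepdims=True)
    hit = np.cumsum(w, axis=1) / w_tot
    miss = np.cumsum(~in_ord, axis=1) / (p - n_in)
    dev = hit - miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(m), idx]


def _set_mask(proteins, pset: ProteinSet) -> np.ndarray:
    return np.asarray(pd.Index(proteins).isin(pset.proteins))


def enrichment_score(correlations: pd.Series, pset: ProteinSet,
                     weight: float = 1.0) -> float:
    """Enrichment score of a correlation profile against one protein set.

    Only proteins with defined correlations participate; the set is
    intersected with the panel's measured proteins.
    """
    rho = correlations.dropna()
    if rho.empty:
        raise ValueError("no defined correlations")
    mask = _set_mask(rho.index, pset)
    return float(_es_many(rho.to_numpy()[None, :], mask, weight)[0])


def _permutation_rho(feature_values: pd.Series, panel: ProteinPanel,
                     n_perm: int | None, seed: int | None):
    """Observed rho plus a matrix of rho rows under sample permutation.

    With ``n_perm`` None the permutation group is enumerated exhaustively
    (sample count <= EXHAUSTIVE_MAX_SAMPLES); otherwise ``n_perm``
    Monte-Carlo draws seeded by ``seed``.
    Returns (rho_obs Series, rho_perm ndarray, exhaustive flag).
    """
    fv = feature_values.reindex(panel.data.index).to_numpy(dtype=float)
    n = fv.size
    fz = _std_ranks(fv)
    if np.isnan(fz).all():
        raise ValueError("feature is constant across samples; Spearman undefined")
    pz_df = _panel_std_ranks(panel)
    defined = ~pz_df.isna().any(axis=0)
    pz = pz_df.loc[:, defined].to_numpy()
    rho_obs = pd.Series(fz @ pz, index=pz_df.columns[defined])

    if n_perm is None:
        perms = np.array(list(_all_permutations(range(n))))
        exhaustive = True
    else:
        if seed is None:
            raise ValueError("seed is mandatory for Monte-Carlo permutations")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        exhaustive = False
    rho_perm = fz[perms] @ pz  # (m, P)
    return rho_obs, rho_perm, exhaustive


def _pvalue(es_obs: float, es_null: np.ndarray, exhaustive: bool) -> float:
    hits = int(np.sum(np.abs(es_null) >= abs(es_obs) - 1e-12))
    if exhaustive:
        return hits / es_null.size  # identity permutation is in the group, so p > 0
    return (1 + hits) / (1 + es_null.size)


def permutation_pvalue(feature_values: pd.Series, panel: ProteinPanel,
                       pset: ProteinSet, n_perm: int = N_PERM_DEFAULT,
                       seed: int | None = None, weight: float = 1.0,
                       exhaustive: bool | None = None) -> tuple[float, float]:
    """Permutation p-value of the feature-process association.

    Feature values are permuted across samples, the Spearman screen and
    enrichment score recomputed each time, and p compares |ES| with the
    null: p = (1 + hits) / (1 + n_perm) for Monte-Carlo, or the exact
    fraction over the full permutation group when the sample count is at
    most EXHAUSTIVE_MAX_SAMPLES (or ``exhaustive=True``).

    Returns (ES_observed, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(feature_values)
    if exhaustive is None:
        exhaustive = n <= EXHAUSTIVE_MAX_SAMPLES
    if exhaustive and factorial(n) > 50000:
        raise ValueError(f"exhaustive enumeration infeasible for {n} samples")
    rho_obs, rho_perm, exh = _permutation_rho(
        feature_values, panel, None if exhaustive else n_perm, seed)
    mask = _set_mask(rho_obs.index, pset)
    es_obs = float(_es_many(rho_obs.to_numpy()[None, :], mask, weight)[0])
    es_null = _es_many(rho_perm, mask, weight)
    return es_obs, _pvalue(es_obs, es_null, exh)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_psea(table, panel: ProteinPanel, sets: list[ProteinSet],
             p_cutoff: float = 0.01, fdr_cutoff: float = 0.05,
             n_perm: int = N_PERM_DEFAULT, seed: int | None = None,
             weight: float = 1.0, fdr_scope: str = "per_process",
             ) -> tuple[pd.DataFrame, pd.Series]:
    """Full screen: every (feature, process) pair scored, tested and counted.

    ``table`` is a samples x features DataFrame or a FeatureTable (runs
    are collapsed by their mean per sample).  One permutation null of
    the correlation profile is shared by all processes for a given
    feature.  BH adjustment is applied per process across features by
    default (``fdr_scope='global'`` pools all pairs).

    Returns (result rows, per-process count of features passing
    p < p_cutoff and q < fdr_cutoff).
    """
    if isinstance(table, FeatureTable):
        wide = table.data.groupby(["sample", "feature"], sort=False)["value"].mean().unstack()
        wide = wide.reindex(index=table.samples, columns=table.features)
    else:
        wide = table
    if fdr_scope not in {"per_process", "global"}:
        raise ValueError("fdr_scope must be 'per_process' or 'global'")
    counts = pd.Series(0, index=[ps.name for ps in sets], dtype=int)
    if not sets:
        return pd.DataFrame(columns=["feature", "process", "es", "p_value",
                                     "q_value", "n_permutations", "seed"]), counts

    n = wide.shape[0]
    exhaustive = n <= EXHAUSTIVE_MAX_SAMPLES
    if not exhaustive and seed is None:
        raise ValueError("seed is mandatory for Monte-Carlo permutations")
    seeds = (np.random.SeedSequence(seed).generate_state(wide.shape[1]) % (2 ** 31)
             if not exhaustive else [None] * wide.shape[1])

    rows = []
    for fi, feat in enumerate(wide.columns):
        fv = wide[feat]
        rho_obs, rho_perm, exh = _permutation_rho(
            fv, panel, None if exhaustive else n_perm, None if exhaustive else int(seeds[fi]))
        n_used = rho_perm.shape[0]
        for ps in sets:
            mask = _set_mask(rho_obs.index, ps)
            es_obs = float(_es_many(rho_obs.to_numpy()[None, :], mask, weight)[0])
            es_null = _es_many(rho_perm, mask, weight)
            p = _pvalue(es_obs, es_null, exh)
            rows.append({"feature": feat, "process": ps.name, "es": es_obs,
                         "p_value": p, "n_permutations": n_used,
                         "seed": None if exhaustive else int(seeds[fi])})
    result = pd.DataFrame(rows)
    if fdr_scope == "global":
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    else:
        result["q_value"] = np.nan
        for name, idx in result.groupby("process").groups.items():
            result.loc[idx, "q_value"] = bh_fdr(result.loc[idx, "p_value"].to_numpy())
    passing = result[(result["p_value"] < p_cutoff) & (result["q_value"] < fdr_cutoff)]
    for name, grp in passing.groupby("process"):
        counts[name] = len(grp)
    return result, counts
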