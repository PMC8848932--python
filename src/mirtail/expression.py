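"""Count-level expression analysis.

Negative-binomial differential expression in the DESeq2 spirit —
median-of-ratios size factors, per-feature method-of-moments dispersion
shrunk toward a mean-dispersion trend, and a Wald z-test on the log2 ratio
of normalized group means — plus BH-FDR, k-means clustering of fold-change
profiles, and PCA sample QC.

The test is a documented approximation of the NB GLM machinery, not a
re-implementation of DESeq2's shrinkage estimators: the target property is
calibration (type-I error near nominal, high power on strong effects), not
bit-agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

_MIN_DISP = 1e-8
_MAX_DISP = 20.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample/column).

    factor_j = median over all-nonzero features of count_ij / geometric mean
    of feature i across samples. Raises when no feature is nonzero in every
    sample; in that case add a pseudocount upstream or subset features.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "median-of-ratios is undefined (consider a pseudocount mode)"
        )
    loggeomean = logs[usable].mean(axis=1)
    sf = np.exp(np.median(logs[usable] - loggeomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on the MoM estimates."""
    ok = (mean > 0) & np.isfinite(disp)
    if ok.sum() < 10:
        med = float(np.median(disp[ok])) if ok.any() else 0.1
        return np.full_like(mean, max(med, _MIN_DISP))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    if coef.sum() == 0:
        coef[0] = max(float(np.median(disp[ok])), _MIN_DISP)
    trend = coef[0] + coef[1] / np.maximum(mean, 1e-8)
    return np.clip(trend, _MIN_DISP, _MAX_DISP)


def nb_wald_test(counts: pd.DataFrame, condition: pd.Series | dict,
                 ref: str, alt: str, sf: pd.Series | None = None,
                 alpha: float = 0.01, shrink_weight: float = 0.1) -> pd.DataFrame:
    """Two-group NB Wald test on a features x samples count matrix.

    log2fc is alt vs ref on size-factor-normalized means. Per-feature
    dispersions are method-of-moments estimates geometrically shrunk toward
    the fitted trend with weight ``shrink_weight`` on the per-feature value.
    Features with all-zero counts are excluded (count reported in
    ``result.attrs['n_all_zero']``).
    """
    if isinstance(condition, dict):
        condition = pd.Series(condition)
    condition = condition.reindex(counts.columns)
    if condition.isna().any():
        raise ValueError("every sample column needs a condition label")
    cols_ref = condition[condition == ref].index
    cols_alt = condition[condition == alt].index
    if len(cols_ref) < 2 or len(cols_alt) < 2:
        raise ValueError("need >= 2 replicates per group")

    nonzero = counts.sum(axis=1) > 0
    n_all_zero = int((~nonzero).sum())
    sub = counts.loc[nonzero, list(cols_ref) + list(cols_alt)]
    if sf is None:
        sf = size_factors(sub)
    s = sf.reindex(sub.columns).to_numpy(dtype=float)
    y = sub.to_numpy(dtype=float) / s  # normalized counts
    iref = np.arange(len(cols_ref))
    ialt = np.arange(len(cols_ref), len(cols_ref) + len(cols_alt))
    n_r, n_a = len(iref), len(ialt)

    m_r = y[:, iref].mean(axis=1)
    m_a = y[:, ialt].mean(axis=1)
    base_mean = y.mean(axis=1)

    # method-of-moments dispersion from within-group residuals:
    # Var(K_j/s_j) = mu/s_j + alpha mu^2
    v_r = y[:, iref].var(axis=1, ddof=1)
    v_a = y[:, ialt].var(axis=1, ddof=1)
    v = ((n_r - 1) * v_r + (n_a - 1) * v_a) / (n_r + n_a - 2)
    inv_s = 1.0 / s
    shot = 0.5 * (m_r * inv_s[iref].mean() + m_a * inv_s[ialt].mean())
    msq = 0.5 * (m_r ** 2 + m_a ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(msq > 0, (v - shot) / msq, np.nan)
    disp_mom = np.clip(np.nan_to_num(disp_mom, nan=_MIN_DISP), _MIN_DISP, _MAX_DISP)
    trend = _dispersion_trend(base_mean, disp_mom)
    disp = np.exp(shrink_weight * np.log(disp_mom) + (1 - shrink_weight) * np.log(trend))
    disp = np.clip(disp, _MIN_DISP, _MAX_DISP)

    # Wald z on log2(m_a/m_r); delta-method SE with NB variance
    delta = 0.5 * float(inv_s.mean())  # half a normalized read
    log2fc = np.log2(m_a + delta) - np.log2(m_r + delta)

    def var_log_mean(m, idx, n):
        var = (m * inv_s[idx].sum() / n + disp * m ** 2) / n
        return var / np.maximum(m + delta, 1e-12) ** 2

    var_log = var_log_mean(m_r, iref, n_r) + var_log_mean(m_a, ialt, n_a)
    se_log2fc = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2fc > 0, log2fc / se_log2fc, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)

    result = pd.DataFrame({
        "base_mean": base_mean,
        "log2fc": log2fc,
        "dispersion": disp,
        "wald_stat": z,
        "p_value": p,
        "q_value": q,
        "significant": q < alpha,
    }, index=sub.index)
    result.attrs["n_all_zero"] = n_all_zero
    result.attrs["alpha"] = alpha
    return result


def kmeans_profiles(lfc: pd.DataFrame, k: int = 15, seed: int = 0,
                    n_init: int = 25, exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """k-means clustering of per-feature log2 fold-change profiles.

    Rows are features (miRNAs), columns contrasts. ``exclude`` drops listed
    feature ids (e.g. let-7 family members) before clustering. k-means++
    init, Euclidean metric, best of ``n_init`` restarts; deterministic under
    ``seed``.
    """
    data = lfc.drop(index=[i for i in exclude if i in lfc.index])
    if k > len(data):
        raise ValueError(f"k={k} exceeds the {len(data)} clusterable rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(data.to_numpy(dtype=float))
    dists = np.linalg.norm(data.to_numpy(dtype=float) - km.cluster_centers_[labels], axis=1)
    out = pd.DataFrame({"cluster": labels, "distance": dists}, index=data.index)
    out.attrs["inertia"] = float(km.inertia_)
    out.attrs["seed"] = seed
    return out


def pca_qc(counts: pd.DataFrame, sf: pd.Series | None = None,
           log: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2 normalized counts (features centered).

    Returns (scores with samples as rows, explained variance fractions
    summing to 1 over the full rank).
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    if sf is not None:
        mat = mat / sf.reindex(counts.columns).to_numpy(dtype=float)
    if log:
        mat = np.log2(mat + 1.0)
    if np.allclose(mat.var(axis=1), 0):
        import warnings

        warnings.warn("constant matrix: PCA variance is zero", stacklevel=2)
    X = mat.T  # samples x features
    pca = PCA(n_components=None)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=counts.columns, columns=cols), pca.explained_variance_ratio_
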