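"""Integrative and phenotype analyses.

Hypergeometric set enrichment (the test behind miRNA/gene set servers),
negative-correlation filtering of miRNA-mRNA target edges against two DE
tables, relative-confluency preprocessing, and logistic growth-curve
fitting: N(t) = K / (1 + exp(-r t) (K - N0) / N0) with carrying capacity K
(% confluency), growth rate r (per hour) and initial confluency N0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression import bh_adjust
from .simulate import logistic_curve


def hypergeom_enrich(query: set, annotation_sets: dict[str, set], background: set) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    p = P(X >= k) with N = |background|, K = |set ∩ background|,
    n = |query|, k = |query ∩ set|; BH across sets. The query must be a
    subset of the background (detection-conditioned inference).
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for name, members in annotation_sets.items():
        inset = set(members) & background
        K = len(inset)
        k = len(query & inset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


def read_gmt(path) -> dict[str, set]:
    """GMT-style TSV: set name, description, then member ids."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def _status(de: pd.DataFrame, alpha: float) -> pd.Series:
    sig = de["q_value"] < alpha
    return pd.Series(
        np.where(sig & (de["log2fc"] > 0), "up", np.where(sig & (de["log2fc"] < 0), "down", "ns")),
        index=de.index,
    )


def negative_correlation_edges(edges: pd.DataFrame, mirna_de: pd.DataFrame,
                               mrna_de: pd.DataFrame, alpha: float = 0.01,
                               mode: str = "both") -> dict[str, pd.DataFrame]:
    """Split target edges by the deregulation pattern of their endpoints.

    ``edges`` needs columns mirna_id, mrna_id. Returns {'negative',
    'positive', 'dropped'}: negative edges oppose in the requested
    direction ('up_down' = up-miRNA/down-mRNA, 'down_up', or 'both');
    positive edges have both endpoints significantly co-directional;
    everything else (ns endpoint or unknown node) is dropped with a reason.
    """
    if mode not in ("up_down", "down_up", "both"):
        raise ValueError("mode must be 'up_down', 'down_up' or 'both'")
    mi_status = _status(mirna_de, alpha)
    mr_status = _status(mrna_de, alpha)
    annotated = edges.copy()
    annotated["mirna_status"] = annotated["mirna_id"].map(mi_status)
    annotated["mrna_status"] = annotated["mrna_id"].map(mr_status)
    annotated["mirna_log2fc"] = annotated["mirna_id"].map(mirna_de["log2fc"])
    annotated["mrna_log2fc"] = annotated["mrna_id"].map(mrna_de["log2fc"])

    unknown = annotated["mirna_status"].isna() | annotated["mrna_status"].isna()
    ns = ~unknown & ((annotated["mirna_status"] == "ns") | (annotated["mrna_status"] == "ns"))
    wanted = []
    if mode in ("up_down", "both"):
        wanted.append(("up", "down"))
    if mode in ("down_up", "both"):
        wanted.append(("down", "up"))
    pairs = list(zip(annotated["mirna_status"], annotated["mrna_status"]))
    neg = pd.Series([p in wanted for p in pairs], index=annotated.index) & ~unknown & ~ns
    pos = pd.Series([p in (("up", "up"), ("down", "down")) for p in pairs], index=annotated.index) & ~unknown & ~ns

    dropped = annotated[unknown | ns].copy()
    dropped["reason"] = np.where(unknown[unknown | ns], "unknown_node", "ns_endpoint")
    return {
        "negative": annotated[neg].reset_index(drop=True),
        "positive": annotated[pos].reset_index(drop=True),
        "dropped": dropped.reset_index(drop=True),
    }


def relative_confluency(series: pd.DataFrame) -> pd.DataFrame:
    """Subtract each well's earliest-time confluency (baseline becomes 0).

    Expects columns well, time_h, value. Idempotent.
    """
    if series.empty:
        raise ValueError("empty confluency series")
    out = series.copy()
    baseline = (out.sort_values("time_h").groupby("well")["value"].first())
    out["value"] = out["value"] - out["well"].map(baseline)
    return out


@dataclass(frozen=True)
class GrowthFit:
    """Logistic growth-curve fit for one well."""

    K: float
    r: float
    N0: float
    rss: float
    se_r: float
    p_r: float
    n: int
    converged: bool

    def predict(self, t) -> np.ndarray:
        return logistic_curve(np.asarray(t, dtype=float), self.K, self.r, self.N0)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    K0 = 1.1 * float(np.max(y))
    pos = y > 0
    N00 = float(y[pos][0]) if pos.any() else max(float(y[0]), 1e-3)
    # r from the log-slope of the early (first half) positive points
    tp, yp = t[pos], y[pos]
    if len(tp) >= 3:
        half = max(3, len(tp) // 2)
        slope = np.polyfit(tp[:half], np.log(yp[:half]), 1)[0]
        r0 = float(np.clip(slope, -1.0, 1.0))
    else:
        r0 = 0.1
    return K0, r0, N00


def fit_logistic(t, y, init: tuple[float, float, float] | None = None) -> GrowthFit:
    """Nonlinear least squares over (K, r, N0) of the logistic model.

    p_r is a Wald t-test on the r estimate (df = n - 3). Non-convergence
    and degenerate covariances are reported via ``converged`` / infinite
    standard errors rather than raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need >= 4 distinct time points")
    if np.any(y <= 0):
        raise ValueError("confluency values must be > 0 to fit the logistic model")
    p0 = init if init is not None else _initial_guess(t, y)
    converged = True
    try:
        with np.errstate(all="ignore"):
            popt, pcov = optimize.curve_fit(
                logistic_curve, t, y, p0=p0, maxfev=20000,
                bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            )
    except (RuntimeError, optimize.OptimizeWarning):
        popt, pcov = np.asarray(p0, dtype=float), np.full((3, 3), np.inf)
        converged = False
    K, r, N0 = (float(v) for v in popt)
    resid = y - logistic_curve(t, K, r, N0)
    rss = float(resid @ resid)
    var_r = float(pcov[1, 1]) if np.all(np.isfinite(np.diag(pcov))) else np.inf
    se_r = float(np.sqrt(var_r)) if var_r >= 0 else np.inf
    df = max(len(t) - 3, 1)
    if np.isfinite(se_r) and se_r > 0:
        p_r = float(2.0 * stats.t.sf(abs(r) / se_r, df))
    elif se_r == 0.0:
        # perfect fit: the covariance is degenerate; call the rate
        # significant only when it is numerically non-zero
        p_r = 0.0 if abs(r) > 1e-12 else 1.0
    else:
        p_r = 1.0
    return GrowthFit(K=K, r=r, N0=N0, rss=rss, se_r=se_r, p_r=p_r, n=len(t), converged=converged)


def fit_growth_wells(series: pd.DataFrame) -> pd.DataFrame:
    """fit_logistic per well of a (well, time_h, value) table."""
    rows = []
    for well, sub in series.groupby("well"):
        fit = fit_logistic(sub["time_h"].to_numpy(), sub["value"].to_numpy())
        rows.append({"well": well, "K": fit.K, "r": fit.r, "N0": fit.N0,
                     "rss": fit.rss, "se_r": fit.se_r, "p_r": fit.p_r,
                     "n": fit.n, "converged": fit.converged})
    return pd.DataFrame(rows)
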