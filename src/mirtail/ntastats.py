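"""Nontemplated-addition summary statistics and condition comparisons.

All statistics run on the aggregated call cube (long-format weighted counts
by sample/miRNA/arm/category/tail type). Two estimators of a tail-type
burden are distinguished throughout:

* mean isomiR percent — the unweighted arithmetic mean of per-miRNA tail
  fractions (each miRNA counts equally), and
* weighted mean ratio — pooled tail-carrying reads divided by pooled total
  reads (depth-weighted across miRNAs).

"Uridylation"/"adenylation" in fold-change analyses means a homopolymeric
tail of that base of ANY length (U, UU, polyU; A, AA, polyA) — mixed tails
never count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

U_ANY = ("U", "UU", "polyU")
A_ANY = ("A", "AA", "polyA")

QUADRANTS = ("downU_upA", "downU_downA", "upU_upA", "upU_downA", "unchanged")


def _drop_unassigned(cube: pd.DataFrame) -> pd.DataFrame:
    return cube[cube["mirna"] != "*"]


def attach_condition(cube: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Add a condition column by joining the sample sheet on sample."""
    mapping = dict(zip(sample_sheet["sample"], sample_sheet["condition"]))
    out = cube.copy()
    out["condition"] = out["sample"].map(mapping)
    if out["condition"].isna().any():
        missing = sorted(out.loc[out["condition"].isna(), "sample"].unique())
        raise ValueError(f"samples missing from sample sheet: {missing}")
    return out


def build_profiles(cube: pd.DataFrame, group_cols: tuple[str, ...] = ("sample",),
                   by_arm: bool = False) -> pd.DataFrame:
    """Per-(group, miRNA[, arm]) tail-type count profile with a total column.

    Unassigned reads are excluded. miRNAs below a read floor are *retained*
    here; per-miRNA statistics apply their own ``min_reads`` cut so pooled
    statistics keep every read.
    """
    cube = _drop_unassigned(cube)
    keys = list(group_cols) + ["mirna"] + (["arm"] if by_arm else [])
    prof = (cube.pivot_table(index=keys, columns="tail_type", values="count",
                             aggfunc="sum", fill_value=0.0)
            .rename_axis(columns=None))
    prof["total"] = prof.sum(axis=1)
    return prof.reset_index()


def _tail_cols(profiles: pd.DataFrame, tails) -> pd.Series:
    if isinstance(tails, str):
        tails = (tails,)
    cols = [t for t in tails if t in profiles.columns]
    if not cols:
        return pd.Series(0.0, index=profiles.index)
    return profiles[cols].sum(axis=1)


def mean_isomir_percent(profiles: pd.DataFrame, tails, min_reads: int = 10) -> float:
    """Unweighted mean of per-miRNA tail fractions, as a percentage."""
    qual = profiles[profiles["total"] >= min_reads]
    if qual.empty:
        return float("nan")
    frac = _tail_cols(qual, tails) / qual["total"]
    return float(frac.mean() * 100.0)


def weighted_mean_ratio(profiles: pd.DataFrame, tails) -> float:
    """Pooled tail-carrying reads / pooled total reads, as a fraction."""
    total = profiles["total"].sum()
    if total == 0:
        return float("nan")
    return float(_tail_cols(profiles, tails).sum() / total)


def stratify_by_arm(cube: pd.DataFrame, group_cols: tuple[str, ...] = ("sample",)) -> pd.DataFrame:
    """Arm-level profiles (same statistics computed per 5p/3p arm)."""
    return build_profiles(cube, group_cols=group_cols, by_arm=True)


def filter_modified(profiles: pd.DataFrame, threshold: float = 0.01) -> list[str]:
    """miRNAs whose total NTA fraction (any tail) is strictly > threshold."""
    tail_cols = [c for c in profiles.columns if c not in ("total", "none", "mirna", "sample", "condition", "arm")]
    frac = profiles[tail_cols].sum(axis=1) / profiles["total"].replace(0, np.nan)
    kept = profiles.loc[frac > threshold, "mirna"]
    return sorted(kept.unique())


def compare_conditions(profiles_ref: pd.DataFrame, profiles_alt: pd.DataFrame,
                       pseudocount: float = 0.5, band: float = 0.25,
                       min_reads: int = 10) -> pd.DataFrame:
    """Per-miRNA log2 fold changes of any-length U and A fractions.

    Fractions are Haldane-Anscombe stabilized: log2((count+pc)/(total+2pc)).
    The quadrant is unchanged when both |log2fc| fall inside the no-change
    band, otherwise it is assigned by sign. ``fivefold_a_gain`` flags
    log2fc_a >= log2(5).
    """
    def pooled(profiles):
        agg = profiles.groupby("mirna").sum(numeric_only=True)
        return agg
    ref = pooled(profiles_ref)
    alt = pooled(profiles_alt)
    common = ref.index.intersection(alt.index)
    ref, alt = ref.loc[common], alt.loc[common]
    qual = (ref["total"] >= min_reads) & (alt["total"] >= min_reads)
    ref, alt = ref[qual], alt[qual]

    def frac_lfc(tails):
        cr = _tail_cols(ref, tails)
        ca = _tail_cols(alt, tails)
        fr = (cr + pseudocount) / (ref["total"] + 2 * pseudocount)
        fa = (ca + pseudocount) / (alt["total"] + 2 * pseudocount)
        return cr, ca, fr, fa, np.log2(fa) - np.log2(fr)

    cu_r, cu_a, fu_r, fu_a, lfc_u = frac_lfc(U_ANY)
    ca_r, ca_a, fa_r, fa_a, lfc_a = frac_lfc(A_ANY)

    quad = np.where(
        (lfc_u.abs() < band) & (lfc_a.abs() < band), "unchanged",
        np.where(lfc_u < 0, "down", "up") + "U_" + np.where(lfc_a < 0, "down", "up") + "A",
    )
    return pd.DataFrame({
        "mirna": ref.index,
        "u_frac_ref": fu_r.values, "u_frac_alt": fu_a.values,
        "a_frac_ref": fa_r.values, "a_frac_alt": fa_a.values,
        "log2fc_u": lfc_u.values, "log2fc_a": lfc_a.values,
        "quadrant": quad,
        "fivefold_a_gain": (lfc_a >= np.log2(5)).values,
    }).reset_index(drop=True)


def arm_ratios(cube: pd.DataFrame, group_col: str | None = None,
               pseudocount: float = 0.5) -> pd.DataFrame:
    """5p/3p weighted-count ratio per miRNA (per group when group_col given).

    dominant is '5p' when ratio > 1 else '3p'; miRNAs seen on only one arm
    are skipped (single-arm precursors have no ratio).
    """
    cube = _drop_unassigned(cube)
    keys = ([group_col] if group_col else []) + ["mirna", "arm"]
    counts = cube.groupby(keys)["count"].sum().unstack("arm", fill_value=0.0)
    for arm in ("5p", "3p"):
        if arm not in counts.columns:
            counts[arm] = 0.0
    both = counts[(counts["5p"] > 0) & (counts["3p"] > 0)]
    ratio = (both["5p"] + pseudocount) / (both["3p"] + pseudocount)
    out = both.reset_index()
    out = out.rename(columns={"5p": "count5p", "3p": "count3p"})
    out["ratio"] = ratio.values
    out["dominant"] = np.where(out["ratio"] > 1.0, "5p", "3p")
    return out


def detect_arm_switch(ratios_ref: pd.DataFrame, ratios_alt: pd.DataFrame,
                      margin: float = 1.5) -> pd.DataFrame:
    """Arm-switch calls between two conditions.

    A switch requires the dominant arm to differ AND both ratios to sit at
    least ``margin``-fold away from 1 (ratios inside the balanced band make
    no call).
    """
    ref = ratios_ref.set_index("mirna")
    alt = ratios_alt.set_index("mirna")
    common = ref.index.intersection(alt.index)
    ref, alt = ref.loc[common], alt.loc[common]
    clear_ref = (ref["ratio"] >= margin) | (ref["ratio"] <= 1.0 / margin)
    clear_alt = (alt["ratio"] >= margin) | (alt["ratio"] <= 1.0 / margin)
    switched = (ref["dominant"] != alt["dominant"]) & clear_ref & clear_alt
    return pd.DataFrame({
        "mirna": common,
        "ratio_ref": ref["ratio"].values,
        "ratio_alt": alt["ratio"].values,
        "dominant_ref": ref["dominant"].values,
        "dominant_alt": alt["dominant"].values,
        "switch": switched.values,
    }).reset_index(drop=True)


def summary_stats(cube: pd.DataFrame, sample_sheet: pd.DataFrame,
                  min_reads: int = 10) -> dict:
    """Machine-readable global NTA summary per condition."""
    with_cond = attach_condition(cube, sample_sheet)
    out: dict = {}
    for cond, sub in with_cond.groupby("condition"):
        prof = build_profiles(sub, group_cols=("condition",))
        out[str(cond)] = {
            "weighted_mono_u_pct": weighted_mean_ratio(prof, "U") * 100.0,
            "weighted_mono_a_pct": weighted_mean_ratio(prof, "A") * 100.0,
            "weighted_u_any_pct": weighted_mean_ratio(prof, U_ANY) * 100.0,
            "weighted_a_any_pct": weighted_mean_ratio(prof, A_ANY) * 100.0,
            "mean_mono_u_pct": mean_isomir_percent(prof, "U", min_reads),
            "mean_mono_a_pct": mean_isomir_percent(prof, "A", min_reads),
            "total_reads": float(prof["total"].sum()),
        }
    return out
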