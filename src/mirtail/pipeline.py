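"""Stage orchestration for the command-line pipeline.

Stages run in dependency order (simulate -> preprocess -> classify ->
ntastats -> de -> cluster -> growth), communicate through TSV files inside
one output directory, and each writes a JSON metadata sidecar (stage,
parameters, seed). A frozen copy of the resolved configuration is written
next to the outputs. Reruns with the same config and seed are
byte-identical except file timestamps.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import pandas as pd
import yaml

from . import expression, isomir, ntastats, preprocess, reference, simulate
from .downstream import fit_growth_wells, relative_confluency

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "classify", "ntastats", "de", "cluster", "growth")

_KNOWN_KEYS = {"seed", "log_level"} | set(STAGES)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2)."""


class DataError(RuntimeError):
    """Missing or inconsistent stage inputs (exit code 3)."""


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _sidecar(outdir: Path, stage: str, params: dict, seed: int) -> None:
    with open(outdir / f"{stage}.meta.json", "w") as fh:
        json.dump({"stage": stage, "seed": seed, "parameters": params}, fh, indent=2, default=str)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DataError(f"missing input {path.name}; run the '{producer}' stage first")
    return path


def _sim_config(cfg: dict, seed: int) -> simulate.SimConfig:
    sim = dict(cfg.get("simulate") or {})
    conds = sim.pop("conditions", None)
    try:
        config = simulate.SimConfig(seed=seed, **sim)
        if conds is not None:
            config.conditions = [simulate.ConditionSpec(**c) for c in conds]
        config.validate()
    except (TypeError, simulate.SimConfigError) as exc:
        raise ConfigError(str(exc)) from exc
    return config


def run_pipeline(config: dict, outdir: str | Path, stages: list[str] | None = None,
                 seed: int | None = None) -> dict:
    """Run the requested stages; returns a manifest of written outputs."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    resolved = {**config, "seed": seed}
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    written: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path):
        written.setdefault(stage, []).extend(p.name for p in paths)

    if "simulate" in stages:
        sc = _sim_config(config, seed)
        ref = simulate.simulate_reference(sc)
        reference.write_reference(ref.records, outdir / "hairpins.fasta", outdir / "mature_coords.tsv")
        reference.write_let7_annotations(ref.let7_annotations, outdir / "let7_annotations.tsv")
        sim = simulate.simulate_reads(sc, ref, outdir=outdir / "fastq")
        sim.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        sim.manifest.to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
        sim.mirna_truth.to_csv(outdir / "mirna_truth.tsv", sep="\t", index=False)
        counts, truth = simulate.simulate_mrna_counts(sc)
        counts.to_csv(outdir / "mrna_counts.tsv", sep="\t")
        truth.to_csv(outdir / "mrna_truth.tsv", sep="\t", index=False)
        growth_cfg = config.get("growth") or {}
        grid = growth_cfg.get("simulate", {"K": 100.0, "r": 0.08, "N0": 5.0,
                                           "t_max": 72, "step": 2, "noise_sd": 2.0, "n_wells": 3})
        wells = []
        times = list(range(0, int(grid["t_max"]) + 1, int(grid["step"])))
        for w in range(int(grid.get("n_wells", 3))):
            tab = simulate.simulate_growth(grid["K"], grid["r"], grid["N0"], times,
                                           noise_sd=grid.get("noise_sd", 0.0), seed=seed * 1000 + w)
            tab.insert(0, "well", f"well_{w + 1}")
            wells.append(tab)
        pd.concat(wells).rename(columns={"confluency": "value"}).to_csv(
            outdir / "confluency.tsv", sep="\t", index=False)
        _sidecar(outdir, "simulate", {"n_mirnas": sc.n_mirnas, "conditions": [c.name for c in sc.conditions]}, seed)
        record("simulate", outdir / "hairpins.fasta", outdir / "mature_coords.tsv",
               outdir / "sample_sheet.tsv", outdir / "truth_manifest.tsv",
               outdir / "mrna_counts.tsv", outdir / "confluency.tsv")

    pp_cfg = dict(config.get("preprocess") or {})
    adapter = pp_cfg.pop("adapter", simulate.NEXTFLEX_ADAPTER)
    if "preprocess" in stages:
        fastq_dir = _require(outdir / "fastq", "simulate")
        proc_dir = outdir / "processed"
        proc_dir.mkdir(exist_ok=True)
        qc = {}
        for fq in sorted(fastq_dir.glob("*.fastq*")):
            sample = fq.name.split(".fastq")[0]
            table, report = preprocess.preprocess_sample(fq, adapter, **pp_cfg)
            counts = Counter(table["insert"])
            pd.DataFrame(sorted(counts.items()), columns=["insert", "count"]).to_csv(
                proc_dir / f"{sample}.inserts.tsv", sep="\t", index=False)
            qc[sample] = report
            log.info("preprocess %s: %s", sample, {k: v for k, v in report.items() if k != "dedup"})
        with open(outdir / "preprocess_qc.json", "w") as fh:
            json.dump(qc, fh, indent=2)
        _sidecar(outdir, "preprocess", {"adapter": adapter, **pp_cfg}, seed)
        record("preprocess", outdir / "preprocess_qc.json")

    if "classify" in stages:
        fasta = _require(outdir / "hairpins.fasta", "simulate")
        coords = _require(outdir / "mature_coords.tsv", "simulate")
        proc_dir = _require(outdir / "processed", "preprocess")
        records = reference.load_reference(fasta, coords)
        cls_cfg = dict(config.get("classify") or {})
        index = isomir.ReferenceIndex(records, **cls_cfg)
        insert_counts = {}
        for tsv in sorted(proc_dir.glob("*.inserts.tsv")):
            sample = tsv.name.replace(".inserts.tsv", "")
            tab = pd.read_csv(tsv, sep="\t")
            insert_counts[sample] = dict(zip(tab["insert"], tab["count"]))
        cube = isomir.build_cube(insert_counts, index)
        cube.to_csv(outdir / "call_cube.tsv", sep="\t", index=False)
        _sidecar(outdir, "classify", cls_cfg, seed)
        record("classify", outdir / "call_cube.tsv")

    if "ntastats" in stages:
        cube = pd.read_csv(_require(outdir / "call_cube.tsv", "classify"), sep="\t")
        sheet = pd.read_csv(_require(outdir / "sample_sheet.tsv", "simulate"), sep="\t")
        ns_cfg = dict(config.get("ntastats") or {})
        ref_cond = ns_cfg.get("reference_condition", sheet["condition"].iloc[0])
        with_cond = ntastats.attach_condition(cube, sheet)
        prof = ntastats.build_profiles(with_cond, group_cols=("condition",))
        prof.to_csv(outdir / "nta_profiles.tsv", sep="\t", index=False)
        arm_prof = ntastats.stratify_by_arm(with_cond, group_cols=("condition",))
        arm_prof.to_csv(outdir / "nta_profiles_by_arm.tsv", sep="\t", index=False)
        comparisons = []
        ratio_frames = []
        ref_prof = prof[prof["condition"] == ref_cond]
        ref_ratios = ntastats.arm_ratios(with_cond[with_cond["condition"] == ref_cond])
        for cond in sheet["condition"].unique():
            if cond == ref_cond:
                continue
            comp = ntastats.compare_conditions(
                ref_prof, prof[prof["condition"] == cond],
                pseudocount=ns_cfg.get("pseudocount", 0.5), band=ns_cfg.get("band", 0.25),
                min_reads=ns_cfg.get("min_reads", 10))
            comp.insert(0, "contrast", f"{cond}_vs_{ref_cond}")
            comparisons.append(comp)
            alt_ratios = ntastats.arm_ratios(with_cond[with_cond["condition"] == cond])
            switches = ntastats.detect_arm_switch(ref_ratios, alt_ratios,
                                                  margin=ns_cfg.get("switch_margin", 1.5))
            switches.insert(0, "contrast", f"{cond}_vs_{ref_cond}")
            ratio_frames.append(switches)
        if comparisons:
            pd.concat(comparisons).to_csv(outdir / "nta_comparison.tsv", sep="\t", index=False)
        if ratio_frames:
            pd.concat(ratio_frames).to_csv(outdir / "arm_switches.tsv", sep="\t", index=False)
        with open(outdir / "nta_summary.json", "w") as fh:
            json.dump(ntastats.summary_stats(cube, sheet), fh, indent=2)
        _sidecar(outdir, "ntastats", ns_cfg, seed)
        record("ntastats", outdir / "nta_profiles.tsv", outdir / "nta_summary.json")

    if "de" in stages:
        cube = pd.read_csv(_require(outdir / "call_cube.tsv", "classify"), sep="\t")
        sheet = pd.read_csv(_require(outdir / "sample_sheet.tsv", "simulate"), sep="\t")
        de_cfg = dict(config.get("de") or {})
        alpha = de_cfg.get("fdr", 0.01)
        conds = list(sheet["condition"].unique())
        ref_cond = de_cfg.get("reference_condition", conds[0])
        cond_map = dict(zip(sheet["sample"], sheet["condition"]))
        mat = (cube[cube["mirna"] != "*"]
               .assign(feature=lambda d: d["mirna"] + "-" + d["arm"])
               .pivot_table(index="feature", columns="sample", values="count", aggfunc="sum", fill_value=0.0)
               .round())
        de_frames = []
        for cond in conds:
            if cond == ref_cond:
                continue
            res = expression.nb_wald_test(mat, cond_map, ref=ref_cond, alt=cond, alpha=alpha)
            res.insert(0, "contrast", f"{cond}_vs_{ref_cond}")
            de_frames.append(res)
        if not de_frames:
            raise DataError("differential expression needs at least two conditions")
        de_all = pd.concat(de_frames)
        de_all.to_csv(outdir / "de_mirna.tsv", sep="\t")
        mrna_path = outdir / "mrna_counts.tsv"
        if mrna_path.exists():
            mcounts = pd.read_csv(mrna_path, sep="\t", index_col=0)
            mcond = {c: c.rsplit("_", 1)[0] for c in mcounts.columns}
            mres = []
            for cond in conds:
                if cond == ref_cond:
                    continue
                r = expression.nb_wald_test(mcounts, mcond, ref=ref_cond, alt=cond, alpha=alpha)
                r.insert(0, "contrast", f"{cond}_vs_{ref_cond}")
                mres.append(r)
            pd.concat(mres).to_csv(outdir / "de_mrna.tsv", sep="\t")
        sf = expression.size_factors(mat.loc[(mat > 0).all(axis=1)]) if (mat > 0).all(axis=1).any() else None
        scores, var = expression.pca_qc(mat, sf)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.DataFrame({"component": scores.columns, "variance_fraction": var}).to_csv(
            outdir / "pca_variance.tsv", sep="\t", index=False)
        _sidecar(outdir, "de", {"fdr": alpha, "reference_condition": ref_cond}, seed)
        record("de", outdir / "de_mirna.tsv", outdir / "pca_scores.tsv")

    if "cluster" in stages:
        de_path = _require(outdir / "de_mirna.tsv", "de")
        de_all = pd.read_csv(de_path, sep="\t", index_col=0)
        cl_cfg = dict(config.get("cluster") or {})
        k = int(cl_cfg.get("k", 15))
        lfc = de_all.pivot_table(index=de_all.index, columns="contrast", values="log2fc")
        exclude = ()
        let7_path = outdir / "let7_annotations.tsv"
        if let7_path.exists():
            fam = pd.read_csv(let7_path, sep="\t")
            exclude = tuple(f"{m}-{arm}" for m in fam["mirna_id"] for arm in ("5p", "3p"))
        k = min(k, max(1, len(lfc.drop(index=[i for i in exclude if i in lfc.index])) ))
        clusters = expression.kmeans_profiles(lfc.fillna(0.0), k=k,
                                              seed=int(cl_cfg.get("seed", 0)),
                                              n_init=int(cl_cfg.get("n_init", 25)),
                                              exclude=exclude)
        clusters.to_csv(outdir / "clusters.tsv", sep="\t")
        _sidecar(outdir, "cluster", {"k": k, "seed": int(cl_cfg.get("seed", 0)), "excluded_let7": len(exclude)}, seed)
        record("cluster", outdir / "clusters.tsv")

    if "growth" in stages:
        conf_path = _require(outdir / "confluency.tsv", "simulate")
        series = pd.read_csv(conf_path, sep="\t")
        fits = fit_growth_wells(series)
        fits.to_csv(outdir / "growth_fits.tsv", sep="\t", index=False)
        rel = relative_confluency(series)
        rel.to_csv(outdir / "relative_confluency.tsv", sep="\t", index=False)
        _sidecar(outdir, "growth", {}, seed)
        record("growth", outdir / "growth_fits.tsv")

    with open(outdir / "output_manifest.json", "w") as fh:
        json.dump(written, fh, indent=2)
    return written
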