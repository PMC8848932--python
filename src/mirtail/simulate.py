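"""Synthetic small-RNA-seq data with known ground truth.

Emulates the statistical structure of a NEXTFlex-style TUT4/7 knockout
experiment: per-miRNA negative-binomial abundances with condition-specific
fold changes, per-arm (5p/3p) expression bias, templated 3'/5' trim-extend
isomiR mixtures, condition-specific nontemplated 3' tail rates (e.g. mono-U
15% in wild type collapsing to 2% in the catalytic knockout while mono-A
rises from 12% to 18%), 4-nt UMIs at both insert ends, a fixed 3' adapter,
and optional per-base substitution error. Every read is recorded in a truth
manifest with its generative labels.

Identifiability: the generator constrains the last two bases of each mature
arm and the four template bases downstream of each arm end to {C,G}. A
planted U/A tail therefore never coincides with the template within the
default +-2 trim/extend range, so the greedy maximal-templated decomposition
can recover the generative tail exactly. Real references carry no such
guarantee; template-mimicking tails remain possible (and enumerable) for
user-supplied hairpins.

All randomness flows from ``SimConfig.seed`` through named substreams (one
stream per sample), so reruns are byte-identical and adding samples does not
perturb earlier ones.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import HairpinRecord, Let7Annotation

NEXTFLEX_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CG = np.frombuffer(b"CG", dtype=np.uint8)

# DNA-space strings for the configurable tail types (U-space names).
TAIL_STRINGS = {"none": "", "U": "T", "UU": "TT", "A": "A", "AA": "AA", "AU": "AT", "UA": "TA"}
TAIL_KEYS = ("none", "U", "UU", "A", "AA", "AU", "UA", "other")

# Substream ids (second word of the RNG seed sequence).
_STREAM_REFERENCE = 1
_STREAM_ABUNDANCE = 2
_STREAM_SAMPLE_BASE = 100
_STREAM_MRNA = 3
_STREAM_GROWTH = 4


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ConditionSpec:
    """One experimental condition (e.g. wild type or TUT4/7 cKO)."""

    name: str
    n_replicates: int = 3
    depth: int = 100_000  # mean library depth (reads per sample)
    dispersion: float = 0.05  # NB dispersion of per-miRNA counts across replicates
    tail_rates: dict[str, float] = field(default_factory=lambda: {"none": 0.73, "U": 0.15, "A": 0.12})
    is_reference: bool = False  # fold changes are relative to the reference condition
    arm_bias_override: dict[str, float] = field(default_factory=dict)  # mirna -> 5p fraction


def _default_conditions() -> list[ConditionSpec]:
    return [
        ConditionSpec(name="WT", is_reference=True,
                      tail_rates={"none": 0.73, "U": 0.15, "A": 0.12}),
        ConditionSpec(name="cKO",
                      tail_rates={"none": 0.80, "U": 0.02, "A": 0.18}),
    ]


def _default_templated3_rates() -> dict[int, float]:
    # shaped to a realistic isomiR composition: 3' extension common,
    # 3' trimming less so
    return {0: 0.54, 1: 0.30, 2: 0.08, -1: 0.06, -2: 0.02}


def _default_offset5_rates() -> dict[int, float]:
    return {0: 0.976, 1: 0.02, -1: 0.004}


@dataclass
class SimConfig:
    """Full description of a synthetic experiment (a pure function of seed)."""

    seed: int = 0
    n_mirnas: int = 50
    hairpin_length: int = 70
    flank_length: int = 10
    umi_length: int = 4
    adapter: str = NEXTFLEX_ADAPTER
    error_rate: float = 0.001
    read_length: int | None = None  # pad reads with random bases up to this length
    abundance_sigma: float = 0.8  # lognormal sd of per-miRNA baseline abundance
    let7_fraction: float = 0.2
    csd_plus_fraction: float = 0.5
    arm_bias: dict[str, float] | None = None  # mirna -> 5p fraction; drawn if None
    de_effects: dict[str, float] = field(default_factory=dict)  # mirna -> log2FC vs reference
    templated3_rates: dict[int, float] = field(default_factory=_default_templated3_rates)
    offset5_rates: dict[int, float] = field(default_factory=_default_offset5_rates)
    conditions: list[ConditionSpec] = field(default_factory=_default_conditions)
    # mRNA count simulation
    n_genes: int = 2000
    mrna_depth: int = 2_000_000
    mrna_dispersion: float = 0.05
    mrna_de_effects: dict[str, float] = field(default_factory=dict)  # gene -> log2FC

    def validate(self) -> None:
        if self.n_mirnas < 0:
            raise SimConfigError("n_mirnas must be >= 0")
        # both arms (max 23 nt), 2 nt of 5' context, 2 nt after the 3p arm,
        # and a loop able to host the 4-base C/G window plus the CSD motif
        min_len = 2 + 23 + 9 + 23 + 2
        if self.hairpin_length < min_len:
            raise SimConfigError(f"hairpin_length must be >= {min_len} to host both arms")
        if self.umi_length < 0:
            raise SimConfigError("umi_length must be >= 0")
        if not self.adapter:
            raise SimConfigError("adapter must be non-empty")
        if not 0 <= self.error_rate < 1:
            raise SimConfigError("error_rate must be in [0, 1)")
        if not self.conditions:
            raise SimConfigError("at least one condition is required")
        for rates, what in ((self.templated3_rates, "templated3_rates"), (self.offset5_rates, "offset5_rates")):
            if abs(sum(rates.values()) - 1.0) > 1e-9:
                raise SimConfigError(f"{what} must sum to 1")
            if any(p < 0 for p in rates.values()):
                raise SimConfigError(f"{what} must be non-negative")
        n_ref = sum(c.is_reference for c in self.conditions)
        if len(self.conditions) > 1 and n_ref != 1:
            raise SimConfigError("exactly one condition must be the reference")
        for cond in self.conditions:
            if cond.depth <= 0:
                raise SimConfigError(f"condition {cond.name}: depth must be > 0")
            if cond.n_replicates < 1:
                raise SimConfigError(f"condition {cond.name}: n_replicates must be >= 1")
            if cond.dispersion < 0:
                raise SimConfigError(f"condition {cond.name}: dispersion must be >= 0")
            unknown = set(cond.tail_rates) - set(TAIL_KEYS)
            if unknown:
                raise SimConfigError(f"condition {cond.name}: unknown tail types {sorted(unknown)}")
            if any(p < 0 for p in cond.tail_rates.values()):
                raise SimConfigError(f"condition {cond.name}: tail rates must be non-negative")
            total = sum(cond.tail_rates.values())
            if total - 1.0 > 1e-9:
                raise SimConfigError(f"condition {cond.name}: tail rates sum to {total} > 1")
        if self.mrna_depth <= 0:
            raise SimConfigError("mrna_depth must be > 0")

    def full_tail_rates(self, cond: ConditionSpec) -> dict[str, float]:
        """Tail rates with the unspecified remainder assigned to 'none'."""
        rates = {k: 0.0 for k in TAIL_KEYS}
        rates.update(cond.tail_rates)
        rates["none"] += max(0.0, 1.0 - sum(rates.values()))
        return rates

    def sample_names(self) -> list[str]:
        return [f"{c.name}_{r + 1}" for c in self.conditions for r in range(c.n_replicates)]


@dataclass
class SyntheticReference:
    records: list[HairpinRecord]
    let7_annotations: dict[str, Let7Annotation]
    arm_bias: dict[str, float]  # mirna -> 5p fraction


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(s) for s in stream])


def _random_bases(rng: np.random.Generator, n: int, alphabet: np.ndarray = _BASES) -> np.ndarray:
    return alphabet[rng.integers(0, len(alphabet), n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_reference(config: SimConfig) -> SyntheticReference:
    """Random hairpins with non-overlapping arms and planted let-7 classes.

    Arm lengths are drawn from 20-23 nt. A ``let7_fraction`` subset is
    flagged as let-7-like; half of those (``csd_plus_fraction``) get a UGAU
    motif planted in the loop, the rest are rejection-sampled to contain no
    GAU in the loop so the motif scan recovers the planted labels exactly.
    """
    config.validate()
    rng = _rng(config, _STREAM_REFERENCE)
    records: list[HairpinRecord] = []
    annotations: dict[str, Let7Annotation] = {}
    arm_bias: dict[str, float] = {}

    n_let7 = int(round(config.let7_fraction * config.n_mirnas))
    let7_idx = set(rng.choice(config.n_mirnas, size=n_let7, replace=False).tolist()) if n_let7 else set()

    for i in range(config.n_mirnas):
        is_let7 = i in let7_idx
        hid = f"sim-let7-{i + 1}" if is_let7 else f"sim-mir-{i + 1}"
        L = config.hairpin_length
        l5, l3 = rng.integers(20, 24, size=2)
        # layout: [2 nt upstream][5p arm][loop][3p arm][2 nt downstream]
        m5 = (2, 2 + int(l5))
        m3 = (L - 2 - int(l3), L - 2)
        seq = _random_bases(rng, L)
        # identifiability windows (see module docstring)
        seq[m5[1] - 2: m5[1]] = _random_bases(rng, 2, _CG)
        seq[m5[1]: m5[1] + 4] = _random_bases(rng, 4, _CG)
        seq[m3[1] - 2: m3[1]] = _random_bases(rng, 2, _CG)
        seq[m3[1]: m3[1] + 2] = _random_bases(rng, 2, _CG)
        flank = _random_bases(rng, config.flank_length)
        flank[:2] = _random_bases(rng, 2, _CG)

        loop_lo, loop_hi = m5[1] + 4, m3[0]  # mutable part of the loop
        csd_plus = False
        if is_let7:
            csd_plus = rng.random() < config.csd_plus_fraction
            if csd_plus:
                pos = int(rng.integers(loop_lo, loop_hi - 4))
                seq[pos: pos + 4] = np.frombuffer(b"TGAT", dtype=np.uint8)
            else:
                # no GAU anywhere in the loop (motif scan must say minus)
                for _ in range(1000):
                    if b"GAT" not in seq[m5[1]: m3[0]].tobytes():
                        break
                    seq[loop_lo: loop_hi] = _random_bases(rng, loop_hi - loop_lo)
                else:  # pragma: no cover - virtually impossible
                    raise SimConfigError("failed to sample a GAU-free loop")
        rec = HairpinRecord(
            id=hid,
            sequence=_to_str(seq),
            mature5p=m5,
            mature3p=m3,
            flank3p=_to_str(flank),
            family="let-7" if is_let7 else "",
        )
        records.append(rec)
        if is_let7:
            annotations[hid] = Let7Annotation(
                mirna_id=hid,
                group="II" if rng.random() < 0.5 else "I",
                csd="plus" if csd_plus else "minus",
            )
        if config.arm_bias and hid in config.arm_bias:
            arm_bias[hid] = float(config.arm_bias[hid])
        else:
            arm_bias[hid] = float(rng.uniform(0.2, 0.8))
    return SyntheticReference(records=records, let7_annotations=annotations, arm_bias=arm_bias)


@dataclass
class ReadSimResult:
    """Reads plus the truth manifest for one simulated experiment."""

    reads: dict[str, list[tuple[str, str, str]]]  # sample -> [(id, seq, qual)]
    manifest: pd.DataFrame  # one row per read: generative labels
    mirna_truth: pd.DataFrame  # per miRNA x condition: true abundance etc.
    sample_sheet: pd.DataFrame  # sample, condition, replicate
    fastq_paths: dict[str, Path] = field(default_factory=dict)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _apply_errors(rng: np.random.Generator, mat: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-base substitution errors on a (n_reads, L) uint8 base matrix."""
    if error_rate <= 0 or mat.size == 0:
        return mat
    hits = rng.random(mat.shape) < error_rate
    n_hits = int(hits.sum())
    if n_hits:
        base_idx = np.searchsorted(_BASES, mat[hits])
        shift = rng.integers(1, 4, n_hits)
        mat[hits] = _BASES[(base_idx + shift) % 4]
    return mat


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    if mat.shape[0] == 0:
        return []
    width = mat.shape[1]
    if width == 0:
        return [""] * mat.shape[0]
    return [b.decode("ascii") for b in np.ascontiguousarray(mat).view(f"S{width}").ravel()]


def simulate_reads(config: SimConfig, reference: SyntheticReference,
                   outdir: str | Path | None = None, gzip_fastq: bool = False) -> ReadSimResult:
    """Generate per-sample FASTQ reads and the per-read truth manifest.

    Per sample, miRNA counts are NB(depth * relative abundance * 2^log2FC,
    dispersion); each read picks an arm by the miRNA's 5p bias, a templated
    trim/extend state, and a nontemplated tail, then gets substitution
    errors and is wrapped as UMI5 + insert + UMI3 + adapter. Qualities are
    constant 'I'.
    """
    config.validate()
    if not reference.records:
        empty = pd.DataFrame()
        return ReadSimResult(reads={}, manifest=empty, mirna_truth=empty, sample_sheet=empty)

    # shared across samples: baseline relative abundance per miRNA
    rng_ab = _rng(config, _STREAM_ABUNDANCE)
    mirna_ids = [r.id for r in reference.records]
    baseline = rng_ab.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(mirna_ids))

    t3_keys = sorted(config.templated3_rates)
    t3_p = np.array([config.templated3_rates[k] for k in t3_keys])
    o5_keys = sorted(config.offset5_rates)
    o5_p = np.array([config.offset5_rates[k] for k in o5_keys])

    arm_ctx = {}  # (mirna, arm) -> (ctx string as uint8 array, start of mature, end of mature)
    for rec in reference.records:
        ctx = np.frombuffer((rec.sequence + rec.flank3p).encode(), dtype=np.uint8)
        for arm in ("5p", "3p"):
            iv = rec.arm_interval(arm)
            if iv is not None:
                arm_ctx[(rec.id, arm)] = (ctx, iv[0], iv[1])

    reads: dict[str, list[tuple[str, str, str]]] = {}
    manifest_parts: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    sheet_rows: list[dict] = []

    qual_cache: dict[int, str] = {}
    sample_index = 0
    for cond in config.conditions:
        lfc = np.array([config.de_effects.get(m, 0.0) if not cond.is_reference else 0.0 for m in mirna_ids])
        cond_mean = baseline * np.power(2.0, lfc)
        weights = cond_mean / cond_mean.sum()
        rates = config.full_tail_rates(cond)
        tail_keys = [k for k in TAIL_KEYS if rates[k] > 0]
        tail_p = np.array([rates[k] for k in tail_keys])
        bias5 = np.array([
            cond.arm_bias_override.get(m, reference.arm_bias[m]) for m in mirna_ids
        ])
        for mid, w, b in zip(mirna_ids, weights, bias5):
            truth_rows.append({
                "mirna": mid, "condition": cond.name, "relative_abundance": w,
                "log2fc": config.de_effects.get(mid, 0.0), "frac_5p": b,
                **{f"rate_{k}": rates[k] for k in TAIL_KEYS},
            })
        for rep in range(cond.n_replicates):
            sample = f"{cond.name}_{rep + 1}"
            sheet_rows.append({"sample": sample, "condition": cond.name, "replicate": rep + 1})
            rng = _rng(config, _STREAM_SAMPLE_BASE + sample_index)
            sample_index += 1
            counts = _nb_counts(rng, cond.depth * weights, cond.dispersion)
            sample_reads: list[tuple[str, str, str]] = []
            man_cols = {k: [] for k in ("mirna", "arm", "offset5", "templated3", "tail", "tail_type", "insert")}
            serial = 0
            for mi, mid in enumerate(mirna_ids):
                total = int(counts[mi])
                if total == 0:
                    continue
                n5 = rng.binomial(total, bias5[mi])
                for arm, n_arm in (("5p", n5), ("3p", total - n5)):
                    if n_arm == 0:
                        continue
                    key = (mid, arm)
                    if key not in arm_ctx:
                        continue
                    ctx, a_start, a_end = arm_ctx[key]
                    o5 = rng.choice(len(o5_keys), size=n_arm, p=o5_p)
                    t3 = rng.choice(len(t3_keys), size=n_arm, p=t3_p)
                    tl = rng.choice(len(tail_keys), size=n_arm, p=tail_p)
                    combo = (o5 * len(t3_keys) + t3) * len(tail_keys) + tl
                    order = np.argsort(combo, kind="stable")
                    combo_sorted = combo[order]
                    uniq, starts = np.unique(combo_sorted, return_index=True)
                    bounds = np.append(starts, n_arm)
                    for ui, code in enumerate(uniq):
                        n = int(bounds[ui + 1] - bounds[ui])
                        tl_i = int(code % len(tail_keys))
                        t3_i = int((code // len(tail_keys)) % len(t3_keys))
                        o5_i = int(code // (len(tail_keys) * len(t3_keys)))
                        off5 = int(o5_keys[o5_i])
                        ext3 = int(t3_keys[t3_i])
                        tkey = tail_keys[tl_i]
                        start = a_start + off5
                        end = a_end + ext3
                        if start < 0 or end > len(ctx) or end - start < 8:
                            continue  # cannot template this state; skip
                        if tkey == "other":
                            # mixed C/G di-nucleotide tails, drawn per combo
                            tail_arr = _random_bases(rng, 2, _CG)
                            tail_dna = _to_str(tail_arr)
                        else:
                            tail_dna = TAIL_STRINGS[tkey]
                        base = np.concatenate([
                            ctx[start:end],
                            np.frombuffer(tail_dna.encode(), dtype=np.uint8),
                        ])
                        mat = np.tile(base, (n, 1))
                        mat = _apply_errors(rng, mat, config.error_rate)
                        inserts = _rows_to_strings(mat)
                        man_cols["mirna"].append(np.repeat(mid, n))
                        man_cols["arm"].append(np.repeat(arm, n))
                        man_cols["offset5"].append(np.repeat(off5, n))
                        man_cols["templated3"].append(np.repeat(ext3, n))
                        man_cols["tail"].append(np.repeat(tail_dna.replace("T", "U"), n))
                        man_cols["tail_type"].append(np.repeat(tkey, n))
                        man_cols["insert"].append(np.asarray(inserts, dtype=object))
                        # UMIs and read assembly
                        umis = _BASES[rng.integers(0, 4, (n, 2 * config.umi_length))]
                        u5 = _rows_to_strings(umis[:, : config.umi_length])
                        u3 = _rows_to_strings(umis[:, config.umi_length:])
                        for j in range(n):
                            seq = u5[j] + inserts[j] + u3[j] + config.adapter
                            if config.read_length is not None and len(seq) < config.read_length:
                                pad = _to_str(_random_bases(rng, config.read_length - len(seq)))
                                seq = seq + pad
                            if len(seq) not in qual_cache:
                                qual_cache[len(seq)] = "I" * len(seq)
                            sample_reads.append((f"{sample}:{serial + j}", seq, qual_cache[len(seq)]))
                        serial += n
            n_reads = len(sample_reads)
            man = pd.DataFrame({
                "read_id": [r[0] for r in sample_reads],
                "sample": np.repeat(sample, n_reads),
                "condition": np.repeat(cond.name, n_reads),
                **{k: (np.concatenate(v) if v else np.array([], dtype=object)) for k, v in man_cols.items()},
            })
            manifest_parts.append(man)
            reads[sample] = sample_reads

    manifest = pd.concat(manifest_parts, ignore_index=True) if manifest_parts else pd.DataFrame()
    result = ReadSimResult(
        reads=reads,
        manifest=manifest,
        mirna_truth=pd.DataFrame(truth_rows),
        sample_sheet=pd.DataFrame(sheet_rows),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, rlist in reads.items():
            suffix = ".fastq.gz" if gzip_fastq else ".fastq"
            path = outdir / f"{sample}{suffix}"
            opener = gzip.open if gzip_fastq else open
            with opener(path, "wt") as fh:
                fh.writelines(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in rlist)
            result.fastq_paths[sample] = path
    return result


def simulate_mrna_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB mRNA count table (genes x samples) with planted log2 fold changes.

    Returns (counts, truth) where truth has columns gene, log2fc.
    """
    config.validate()
    rng = _rng(config, _STREAM_MRNA)
    genes = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=config.n_genes)
    lfc = np.array([config.mrna_de_effects.get(g, 0.0) for g in genes])
    cols = {}
    for cond in config.conditions:
        mult = np.power(2.0, lfc) if not cond.is_reference else np.ones_like(lfc)
        mean = baseline * mult
        weights = mean / mean.sum()
        for rep in range(cond.n_replicates):
            sample = f"{cond.name}_{rep + 1}"
            cols[sample] = _nb_counts(rng, config.mrna_depth * weights, config.mrna_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes, "log2fc": lfc})
    return counts, truth


def logistic_curve(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + exp(-r t) (K - N0) / N0)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + np.exp(-r * t) * (K - N0) / N0)


def simulate_growth(K: float, r: float, N0: float, times: np.ndarray,
                    noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Confluency time series from the logistic model plus Gaussian noise."""
    if N0 <= 0:
        raise SimConfigError("N0 must be > 0")
    if K <= N0:
        raise SimConfigError("carrying capacity K must exceed N0")
    times = np.asarray(times, dtype=float)
    values = logistic_curve(times, K, r, N0)
    if noise_sd > 0:
        rng = np.random.default_rng([int(seed), _STREAM_GROWTH])
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return pd.DataFrame({"time_h": times, "confluency": values})
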