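# mirtail

isomiR and 3′ nontemplated-addition (NTA) profiling for small RNA-seq.

## The problem

Mature miRNAs are not single sequences. Sequenced reads from one miRNA locus
differ at the 5′ end, at the 3′ end (templated trimming or extension along
the precursor hairpin), and by **nontemplated 3′ additions** — extra
nucleotides, mostly uridines and adenosines, added enzymatically after
processing. Terminal uridylyl transferases (TUT4/7) write the U tails;
uridylation is associated with miRNA decay and adenylation with stability,
so the balance of uridylated vs adenylated isomiRs is a regulatory signal.
Knocking out the catalytic activity of TUT4/7 collapses miRNA uridylation
(mono-U isomiR fractions drop from the ~15% range to the low percent range)
while adenylated isomiRs rise in compensation, and a subset of precursors
even switch which arm (5p vs 3p) dominates.

`mirtail` implements the complete quantitative side of such a study as a
reusable, tested pipeline:

- **reference** handling — hairpins plus mature-arm coordinates (1-based
  miRBase-style tables), and let-7 classification by Group I/II overhang
  annotation and the (U)GAU LIN28A cold-shock-domain motif;
- **preprocessing** of NEXTFlex-style libraries — 3′ adapter
  `TGGAATTCTCGGGTGCCAAGG`, 4-nt UMIs on both insert ends, UMI-exact
  PCR-duplicate collapsing, length filtering;
- **isomiR classification** — gapless arm assignment with ±2 nt 5′ offsets,
  greedy maximal-templated 3′ decomposition into (templated extent,
  nontemplated tail), the standard category taxonomy
  (exact / lv5pE / lv5pT / lv3pE / lv3pT / mv / nta / snp_flagged) and the
  tail typology (A, AA, AU, U, UA, UU, polyA/polyU, other);
- **NTA statistics** — mean isomiR percent (unweighted across miRNAs) vs
  weighted mean ratio (pooled reads), arm stratification, the >1%
  modification filter, log2 fold-change quadrants of uridylation vs
  adenylation with a five-fold adenylation-gain flag, and 5p/3p arm-switch
  detection;
- **expression analysis** — median-of-ratios size factors, a negative-
  binomial Wald test with trend-shrunken method-of-moments dispersions,
  BH-FDR, k-means clustering (k = 15 by default) of log2 fold-change
  profiles, PCA sample QC;
- **downstream** — hypergeometric set enrichment, negative-correlation
  filtering of miRNA–mRNA target edges, relative confluency, and logistic
  growth-curve fitting `N(t) = K / (1 + e^{-rt}(K - N0)/N0)`;
- a **synthetic-data generator** that emulates the full experiment
  (negative-binomial abundances, condition-specific tail rates, templated
  trim/extend mixtures, UMIs, adapters, sequencing error) with a per-read
  ground-truth manifest, so every stage is testable without any download.

## Worked example

Simulate a wild-type vs TUT4/7-catalytic-knockout experiment (2 × 3
samples, 20 miRNAs, 20 000 reads per sample), run it through the pipeline
and recover the tail statistics:

```python
from mirtail import simulate, ntastats, preprocess
from mirtail.isomir import ReferenceIndex, build_cube

cfg = simulate.SimConfig(seed=1, n_mirnas=20)
for cond in cfg.conditions:
    cond.depth = 20_000

ref = simulate.simulate_reference(cfg)
sim = simulate.simulate_reads(cfg, ref)

index = ReferenceIndex(ref.records)
counts = {}
for sample, reads in sim.reads.items():
    table, report = preprocess.preprocess_sample(reads, cfg.adapter)
    counts[sample] = table["insert"].value_counts().to_dict()

cube = build_cube(counts, index)
with_cond = ntastats.attach_condition(cube, sim.sample_sheet)
profiles = ntastats.build_profiles(with_cond, group_cols=("condition",))
for cond in ("WT", "cKO"):
    prof = profiles[profiles["condition"] == cond]
    u = 100 * ntastats.weighted_mean_ratio(prof, "U")
    a = 100 * ntastats.weighted_mean_ratio(prof, "A")
    print(f"{cond}: mono-U {u:.1f}%  mono-A {a:.1f}%")

comp = ntastats.compare_conditions(profiles[profiles["condition"] == "WT"],
                                   profiles[profiles["condition"] == "cKO"])
print(comp["quadrant"].value_counts().to_dict())
```

prints

```
WT: mono-U 15.1%  mono-A 12.1%
cKO: mono-U 1.9%  mono-A 18.2%
{'downU_upA': 20}
```

i.e. the pipeline recovers the generator's planted condition rates
(WT mono-U 15% / mono-A 12%; cKO 2% / 18%) from raw reads, and every miRNA
lands in the loss-of-uridylation / gain-of-adenylation quadrant.

The same run is available from the shell:

```bash
mirtail all --outdir out --seed 1          # full demo on synthetic data
mirtail growth --outdir out                # refit growth curves only
mirtail enrich --query q.txt --sets sets.gmt --background bg.txt --out e.tsv
```

`mirtail all` writes the reference, FASTQ files, QC reports, the call cube,
NTA profile/comparison/arm-switch tables, DE and cluster tables, PCA scores
and growth fits, each with a JSON metadata sidecar; reruns with the same
config and seed are byte-identical.

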