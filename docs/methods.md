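# Methods

## Pipeline model and assumptions

The pipeline treats a two-condition (cancer vs paracancer) study with two data
layers: RNA-seq counts per gene and array-style methylation β per CpG probe.
Its central premise is regulatory: promoter methylation represses
transcription, so only the discordant combinations — up-regulated ∧
promoter-hypomethylated (U-Hypo) and down-regulated ∧ promoter-hypermethylated
(D-Hyper) — are treated as methylation-driven expression classes. Enhancer
methylation is handled separately: an enhancer is linked to its nearest TSS
(≤ 1 Mb), and a differentially methylated enhancer (DME) is called only when
the per-patient methylation change anti-correlates with the target's
per-patient expression change *and* the target's promoter is methylation-quiet
(|RD| ≤ 0.2), isolating expression changes attributable to the enhancer alone.

All differential methylation uses the relative difference
RD = (β_t − β_p)/(β_p + Δ) with Δ = 10⁻⁹. RD is asymmetric by construction:
a fixed absolute Δβ yields a larger |RD| on a lowly methylated baseline than
on a highly methylated one, so hypomethylation of high-β promoters needs a
larger absolute shift to clear the ±0.2 threshold. When β_p ≈ 0 the Δ guard
produces extremely large RD values; these are legitimate outputs of the
definition and are classified, not clamped.

Group pooling: gene- and bin-level RD pools *all* cancer samples against
*all* paracancer samples (unmatched); only the DME correlation uses the
matched-pair structure, because a rank correlation across patients requires
paired observations.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| FC thresholds | > 1.25 up, < 0.8 down (strict) | expression fold-change gates |
| padj | < 0.05 | BH-adjusted significance gate |
| α (intensity offset) | 100 | stabilizes β when both channels are low |
| RD threshold | ±0.2 (strict) | abnormal-methylation gate at gene and bin level |
| Δ | 1e-9 | RD denominator guard |
| promoter | TSS ± 1500 bp, closed interval | gene-level methylation window |
| promoter bins | 30 × 100 bp | bin μ covers offsets (−1500+100(μ−1), −1500+100μ] |
| key bins | 14–17 | the (−200, +200] core around the TSS |
| other-region bins | 10 equal bins | over concatenated intervals, transcription order |
| r threshold | < −0.4 (strict) | DME anti-correlation gate |
| target window | 1 Mb, inclusive | enhancer-center-to-TSS assignment range |
| FC pseudocount | +1 | per-patient (NC+1)/(NC+1) ratio; defined at zero counts |

Bin numbering is fixed by requiring bins 14–17 to cover exactly (−200, +200):
bin 15 = (−100, 0], bin 16 = (0, +100], boundary positions belong to the
downstream-numbered bin, and the single offset −1500 is folded into bin 1 so
the 30 bins partition the whole closed promoter window. Consequently the
m_r-weighted mean of the 30 bin values equals the gene-level promoter mean
exactly, and reversing a gene's strand maps bin μ to 31 − μ for any position
not on a 100 bp boundary. On the minus strand all offsets are taken in
transcription orientation (upstream = larger coordinate).

## The significance test

The upstream definition of the pipeline delegates per-gene testing to a
generic "DESeq function" without settings; here the test is an explicit
negative-binomial Wald test: per-gene dispersion is a pooled
method-of-moments estimate α = (var − mean)/mean² averaged over the two
groups (floored at 1e-8), the statistic compares log group means of
normalized counts with delta-method standard errors, and a zero group mean
receives a 0.5 pseudo-mean for the test only. The test is a keyword argument
of `de_test`, so any callable returning per-gene p-values can replace it; BH
adjustment runs over tested genes only. On all-null simulated studies this
test rejects at ~5–6% at p < 0.05 (slightly anticonservative, as expected for
a moment-based Wald test at n ≈ 20–30 per group).

Rounding in the normalization is round-half-to-even (`np.rint`), chosen for
its lack of directional bias; re-estimating size factors on normalized counts
returns factors equal to 1 up to a small offset common to all samples
(~2% at the default study size) caused by integer rounding of small counts.

## Spearman shortcut

r = 1 − 6Σd²/n(n²−1) is exact only for distinct ranks. Ranks are computed as
midranks; with ties present the implementation returns the Pearson
correlation of the midranks instead (the standard tie-corrected Spearman),
and a constant vector yields NaN with a warning rather than an arbitrary
sign. With ≥ 3 points and no ties the two paths agree to machine precision.

## What the synthetic generator emulates — and what it does not

`simulate_study(SimConfig(...))` builds one toy chromosome with genes tiled
every 50 kb, NB counts (log-normal baselines, per-sample library factors,
dispersion 0.1), Beta-distributed probe β (concentration 50), 9 matched pairs
plus 12/3 unmatched cancer/paracancer samples, ~2% non-CpG probes and 0.2% NA
cells. Promoter probe density is 6× higher in bins 14–17 than elsewhere,
mirroring the dense probe coverage HM450K gives CpG-island TSS cores; this is
also what lets a key-bin-confined Δβ move the whole-promoter mean past the
RD threshold, as the class definitions require. Planted classes: D-Hyper
(log2FC −1.5, key-bin Δβ +0.25 by default on a 0.15–0.35 baseline), U-Hypo
(mirror image on a 0.45–0.6 baseline — higher, as hypomethylation needs
headroom), DME (per-patient expression shifts; enhancer Δβ assigned as a
decreasing function of the patient's realized expression ratio plus
N(0, 0.02) jitter, so the planted anti-correlation survives count noise),
and null. Causal enhancers sit 5–20 kb from their target's TSS — unambiguous
under 50 kb gene spacing — alongside unshifted decoy enhancers near null
genes.

Not emulated: Illumina type I/II probe chemistry, copy-number confounding,
batch effects, within-pair methylation correlation beyond the planted
effects, multi-transcript TSS ambiguity, and realistic genome geometry.
Passing the planted-recovery checks therefore demonstrates that the pipeline
machinery recovers the effects it defines, at desk scale — not that it would
reach any particular sensitivity on real tumor data.

## Numerical and design choices

* Internal coordinates are 1-based inclusive (HM450K manifest convention);
  BED files are converted at the IO boundary only. Enhancer centers use the
  floor midpoint.
* Reference genes for size factors are rows positive in every sample (the
  geometric-mean logarithm forces this); absence of any such gene is an error.
* FC with a zero paracancer mean is +inf (flagged, excluded from DME
  correlation); 0/0 is NaN.
* Probe QC order is fixed: non-CpG first, then any-NA; the logged counts
  reflect that order. Because NA probes are removed globally, no per-cell NA
  logic exists downstream.
* Nearest-gene ties break to the smaller TSS, then lexicographic gene id;
  all outputs are deterministically ordered, and the full pipeline is a pure
  function of (inputs, config, seed).
* Genes in both the oncogene and TSG lists get role "both" and are reported,
  never silently assigned; role/direction concordance is a report column,
  not a filter. The pipeline deliberately stops at the reproducible
  candidate table — the final manual, literature-guided curation step of key
  genes is out of scope.
* "Abnormal in the key bins" means |RD| > 0.2 in at least one of bins 14–17.

## Problem sizes

Simulated validation studies use 300 genes, ~15k probes and 33 samples;
null-calibration and planted-recovery checks aggregate 10–20 seeded
replicates (test bands were frozen from ≥ 20-seed Monte-Carlo runs at the
generator defaults before being asserted). A full study simulation plus
pipeline run takes ~1.5 s, the whole test suite well under a minute.

## Known limitations

* The Wald test is not a DESeq replica; shrinkage-based dispersion estimation
  would behave differently at very small n.
* RD's Δ guard makes near-zero-baseline genes classify as hyper at tiny
  absolute changes; interpret RD magnitudes on low-β baselines with care.
* One TSS per gene is assumed; multi-TSS genes must be collapsed upstream
  (the annotation reader rejects duplicate gene ids rather than guessing).
* Enhancer-target assignment is purely nearest-TSS; no chromatin-contact or
  eQTL evidence is consulted.
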