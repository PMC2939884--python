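# ailqtl

QTL mapping for advanced intercross lines (AILs), built around the analysis
design that resolved a rat chromosome-17 region regulating experimental
autoimmune encephalomyelitis (EAE) into two adjacent loci: one where alleles
from the clinically resistant PVG strain promote disease dominantly
(transgressive segregation), and one where heterozygotes are more susceptible
than either homozygote (heterosis).

The package is for quantitative geneticists working with experimental
crosses — F2s and multi-generation AILs — who need the full path from
genotype/phenotype tables to a QTL report: LOD scans, resampling-free
significance thresholds suited to family-structured cohorts, support
intervals, multi-locus model fits, bootstrap localization probabilities, and
allelic-effect classification. Because the original rat cohort is not
publicly deposited, the package ships a first-class AIL simulator that
reproduces the cohort's statistical structure and anchors every test.

## Models

**Haley–Knott regression.** At each position, genotype-class probabilities
`(P(AA), P(AB), P(BB))` are computed from the nearest informative flanking
markers under a two-locus Markov model with Haldane-transformed
recombination fractions, scaled by the AIL map-expansion factor *t*/2 for
generation *t*. A quantitative trait *y* is regressed on the additive dosage
*a* = P(BB) − P(AA) and dominance *d* = P(AB):

    LOD = (n/2) · log10(RSS₀ / RSS₁)

with RSS₀ from the covariate-only null. Binary incidence uses logistic
regression on the same regressors, LOD = (ℓ₁ − ℓ₀)/ln 10, with a small
fixed ridge under complete separation.

**Family-residual thresholds.** Genome-wide permutation thresholds assume
exchangeable individuals, which a G10 AIL's sibship structure violates.
Instead each animal's trait is centered on its family mean and the scan is
rerun on the residuals; the maximum residual-scan LOD is the trait's
threshold. A fixed fallback cutoff of 3.4 is also provided.

**1.5-LOD support intervals.** Interval bounds are the closest markers whose
LOD falls 1.5 below the peak (region ends otherwise) — approximately a 95%
confidence interval for QTL location in an intercross.

**Two-QTL fit and localization.** Independent locus effects are tested by
drop-term comparisons of `phenotype = locusA + locusB + ε` (F test for
Haley–Knott, 2-df likelihood ratio for the binary model). Localization
probabilities resample individuals with replacement, rescan with a
single-QTL model, and report how often the supra-threshold genome maximum
falls inside each locus's support interval.

**Allelic effects and ΔΔCt.** Genotype-class stratification at peak markers
uses Kruskal–Wallis (Bonferroni-controlled), pairwise Mann–Whitney and
Fisher's exact tests, and classifies loci as additive, dominant, or
heterotic, with a transgression flag. A small qPCR module implements
relative quantification RQ = 2^(−ΔΔCt) with a configurable calibrator set.

## Worked example

Simulate the default desk-scale cohort (428 G10 animals, 20 microsatellite
markers over 13.9–81.6 Mb, two linked loci at 47.3 and 62.0 Mb) and run the
full pipeline:

```python
from ailqtl.cli import RunConfig, run_pipeline

cfg = RunConfig(out_dir="demo", simulate=True, seed=1, n_boot=1000,
                traits=("INC", "MAX"))
print(run_pipeline(cfg).to_string(index=False))
```

```
trait  threshold peak_marker  peak_lod  si_lower_mb  si_upper_mb  prob_pct    fit_p
  INC      1.575    D17Got70     2.709         57.2         70.5      67.1      NaN
  MAX      3.699   D17Got120     5.075         59.5         66.0      70.0 0.000000
  MAX      3.699    D17Got45     3.701         45.0         50.8      23.0 0.000001
```

For MAX the scan resolves two QTLs: a peak at D17Got120 (LOD 5.08) whose
1.5-LOD support interval (59.5–66.0 Mb) covers the simulated heterotic locus
at 62.0 Mb, and a second peak at D17Got45 (LOD 3.70, interval 45.0–50.8 Mb)
covering the simulated dominant locus at 47.3 Mb. Both clear the
family-residual threshold (3.70); `prob_pct` is the share of 1,000
bootstrap pedigrees whose supra-threshold genome maximum lands inside each
interval (70% vs 23% — the stronger locus wins the single-QTL scan more
often), and `fit_p` shows each locus retains an independent effect in the
two-QTL model. For the binary incidence trait only the heterotic locus
clears its threshold in this realization.

The same steps are available as shell commands: `ailqtl simulate`,
`ailqtl validate`, `ailqtl scan`, `ailqtl effects`, `ailqtl congenic-predict`,
`ailqtl rq`, and `ailqtl run --config cfg.yaml`.

## Layout

| module | contents |
| --- | --- |
| `ailqtl.formats` | table containers, delimited I/O, weight-loss arithmetic |
| `ailqtl.synthdata` | AIL simulator and the default two-locus cohort |
| `ailqtl.genoprob` | flanking-marker genotype probabilities, map expansion |
| `ailqtl.scan` | Haley–Knott and binary LOD scans, sex-covariate models |
| `ailqtl.inference` | thresholds, support intervals, two-QTL fit, bootstrap |
| `ailqtl.effects` | allelic-effect stratification, nonparametric tests |
| `ailqtl.qpcr` | ΔΔCt relative quantification |
| `ailqtl.cli` | `ailqtl` command-line pipeline |

See `docs/methods.md` for the modelling decisions and their rationale.
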