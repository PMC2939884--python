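# Methods

## The mapping problem

An advanced intercross line (AIL) is produced by crossing two inbred strains
and then intercrossing randomly for many generations — here DA and
PVG.1AV1-style founders carried to generation 10 (G10) with ~50 breeding
couples per generation. Each extra generation adds recombinations, so linkage
disequilibrium between nearby markers decays roughly in proportion to *t*/2
for generation *t*, sharpening QTL localization relative to an F2 at the cost
of a family-structured cohort that breaks the assumptions behind standard
permutation thresholds. The package maps EAE traits — binary incidence (INC),
day of onset (ONS), maximum clinical score (MAX, 0–4 scale), duration (DUR,
days), cumulative score (CUM) and percent weight loss (WL) — over a single
labelled chromosome region described by physical Mb positions.

## Genotype probabilities

Scans regress on expected genotype rather than raw marker calls. In an
intercross the two transmitted gametes are independent two-state Markov
chains along the chromosome, giving the standard 3×3 genotype transition
matrix in the recombination fraction *r*. Probabilities at a position
condition on the nearest informative flanking marker on each side (single
nearest marker beyond the terminal markers; the intercross prior
(¼, ½, ¼) if an individual has no data, with a logged warning). Distances
are converted Mb → cM at a uniform, configurable rate (default 1 cM/Mb —
the cohort itself was mapped on physical positions, so the genetic scale
must be made explicit), multiplied by the AIL expansion factor (default
*t*/2), then Haldane-transformed: r = (1 − e^(−2·E·d/100))/2. Haldane's
no-interference map keeps the chain Markov-consistent, so conditioning on
the two nearest informative flanks is exact; a brute-force enumeration of
three-locus haplotype configurations agrees to < 1e-9. The default scan
grid is the marker positions (marker-anchored LOD curves); pseudo-position
stepping is available via `step`.

## Scan models

Haley–Knott regression: trait on additive dosage a = P(BB) − P(AA) ∈ [−1, 1]
and dominance d = P(AB), LOD = (n/2)·log10(RSS₀/RSS₁) against the
covariate-only null. Individuals with an undefined trait (e.g. ONS of
unaffected animals) are dropped, not imputed. ONS is treated as a
quantitative trait. A residual sum of squares below 1e-12 is treated as a
numerically perfect fit: the LOD is capped and flagged.

Binary model for INC: logistic regression on (a, d) (+ covariates) by
Newton iteration, LOD = (ℓ₁ − ℓ₀)/ln 10. Complete separation or
non-convergence triggers a refit with a fixed ridge of 1e-4 on the
coefficients and a `ridge` flag on the result.

Sex enters as an additive or interactive covariate. For both covariate
scans the null model contains sex, so the interactive scan dominates the
additive scan position-wise (nested models); the plain scan uses the
intercept-only null and is not ordered against the other two.

## Thresholds

The family-residual procedure centers each animal's trait on its family
(sibship) mean, rescans the residuals with the Haley–Knott machinery
(binary incidence is centered on its 0/1 coding — residuals of a binary
trait are no longer binary), and takes the maximum residual-scan LOD over
the region as the trait's threshold. Two properties follow from the
construction and should be understood before use:

* With a real QTL present, full sibs share roughly half the additive
  genotype variance (less for dominance), so family centering removes only
  part of the QTL signal: the threshold tracks a substantial fraction
  (~0.5–0.6 here) of the strongest peak. This is how the original design
  behaves as well — its thresholds sit at roughly half its peak LODs.
* Under the null, centering the phenotype but not the genotype deflates
  the residual-scan LOD by the within-family share of regressor variance,
  so the threshold is **not** an unbiased estimate of the null genome
  maximum; on no-QTL cohorts it exceeds the realized null maximum in only
  ~18% of replicates. The test suite records this calibration property
  honestly rather than assuming the nominal behaviour.

A fixed fallback cutoff of 3.4 — the classical simulated-data suggestion
for intercross genome scans — is provided, and a QTL is reported when its
LOD exceeds max(family-residual threshold, configurable floor; default 0).

## Intervals, multi-peak calls, two-QTL fit, bootstrap

Support intervals use the 1.5-LOD drop with the closest-marker-outside
rule: on each side the bound is the nearest marker whose LOD falls below
peak − 1.5 (region end if none). Ties at the peak break toward the smaller
position; bounds are closed; widening the drop never narrows the interval.
The rule is conservative, so Monte-Carlo coverage of a true single QTL
comes out at or a little above the nominal ~95% (97–99% at n = 400 with
markers every 5 cM; `support_interval_coverage` recomputes this).

Multiple peaks are called in decreasing LOD order with a peak-separation
rule: a further peak is accepted only if the curve dips at least `drop`
below it between it and every accepted peak. Plain interval masking was
rejected because monotone shoulders of a strong peak otherwise surface as
spurious second QTLs.

The two-QTL fit (`phenotype = locusA + locusB + ε`, additive + dominance
terms per locus) tests each locus by dropping its two terms: an F test
against the full-model residual for Haley–Knott, a 2-df likelihood ratio
for the binary model. Loci closer than |corr| > 0.999 in their additive
dosages are rejected as collinear. On pure-noise traits the drop-term test
rejects at the nominal 5% (measured 5.2–5.5% over 400 replicates).

Localization probabilities resample individuals with replacement (family
structure ignored, matching plain pedigree resampling), rescan with the
single-QTL model, and count replicates whose supra-threshold genome
maximum falls inside each support interval. Sub-threshold replicates count
in the denominator by default (consistent with reported probabilities
summing well below 100%); a flag switches to the conditional reading.

## Allelic effects

At a peak marker the cohort is stratified by genotype class. Trait-level
confirmation uses Kruskal–Wallis with Bonferroni control across the marker
× phenotype family (multiplier configurable). Classification uses the
pairwise contrasts — Fisher's exact test for incidence, Mann–Whitney for
quantitative traits (exact enumeration at combined n ≤ 12, midranks with
tie-corrected normal approximation otherwise; all tests two-sided) — at
the stated α unadjusted: heterosis when the heterozygote differs from both
homozygotes in the same direction, dominance when it sides with one
homozygote, additive when the homozygotes differ with the heterozygote in
between. A locus-level label takes the modal per-trait classification
(ties → none), pooling power across the correlated clinical traits. The
transgression flag marks the resistant-strain (PVG) allele class as the
more severe one. Genotype-matched "congenic prediction" selects cohort
members matching two-locus genotype combinations and compares each combo
with the all-DA reference.

## ΔΔCt quantification

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt centers ΔCt on the
calibrator-set mean (all samples by default, or a named group); RQ =
2^(−ΔΔCt) with efficiency fixed at 2. Centering on the mean ΔCt makes the
geometric mean of RQ over the calibrator set exactly 1. Ct values outside
10–40 cycles are soft-checked with a warning.

## The simulator

`simulate_ail` gene-drops haplotypes through the breeding design: founder
couples pair one fully-A with one fully-B parent, each later generation
forms `n_couples` couples by random male–female pairing with
sibling-mating avoidance, and every meiosis recombines adjacent loci
independently with Haldane fractions from the cM map. QTLs are extra
hidden loci on the same map; the final generation is genotyped at the
markers only and phenotyped.

Trait model: INC is Bernoulli with penetrance = base + per-locus
genotype-class shifts (clipped to [0, 1]); quantitative traits are
baseline + per-locus class shifts + family effect + sex effect + Gaussian
noise, with ONS defined only for affected animals, MAX/DUR/CUM zero for
unaffected ones, DUR capped by the remaining 35-day observation window,
and CUM generated as ≈ MAX·DUR/2 plus noise so severity traits correlate
as clinical scores do. Family and sex effects are expressed as multiples
of each trait's residual SD because the traits live on disparate scales
(days, scores, percent).

The default cohort (`make_eae23_fixture`) encodes the mapped study's
conditions: 20 markers over 13.9–81.6 Mb including the 33.3–42.7 Mb
non-polymorphic gap, 10 generations, 50 couples, 428 analyzed animals in
~50 sibships, overall incidence ≈ 0.29, a dominant/transgressive locus at
47.3 Mb and a heterotic locus at 62.0 Mb with heterozygote/homozygote
penetrance ratio ≈ 1.6 (matching the reported 43% vs 27%). Class-mean
separations for the quantitative traits were sized once so that
single-cohort peak LODs land in the reported 4–6 range and heterozygote
contrasts reach the reported significance levels at n = 428.

What the simulator does **not** emulate: genotyping error and missing
data patterns (markers are fully typed unless masked), shared-environment
litter effects beyond a single Gaussian family effect, sex-linked or
mitochondrial inheritance, crossover interference, selection during
breeding, and any immune mechanism behind the traits — passing tests show
the statistical machinery is correct under the declared generative model,
not that the biology of any particular cohort is captured.

## Numerical and design choices

* Genotype coding AA = DA/DA, AB, BB = PVG/PVG; dosage a ∈ {−1, 0, 1} at
  typed markers.
* Problem sizes in tests and calibration runs (300 coverage replicates at
  n = 400; 100 cohort seeds; 400 null replicates) were chosen as the
  smallest sizes at which the Monte-Carlo error is well inside the asserted
  margins.
* Bootstrap and simulation randomness route through
  `numpy.random.default_rng`; the pipeline fans stage seeds out of one
  master seed so stages are independently re-runnable and reports are
  byte-reproducible.
* Degenerate inputs fail loudly: zero trait variance, single outcome
  class, single family, residuals identical to family means, collinear
  loci, penetrance escaping [0, 1].

## Known limitations

The family-residual threshold's null mis-calibration (above) is inherent
to the published procedure, not an implementation artifact; a calibrated
alternative would center genotype regressors on family means as well.
Support-interval coverage is assessed for a single additive QTL; with two
linked QTLs intervals can be biased toward each other (the original design
notes positional bootstrap fails there for the same reason). Two-locus
architectures are additive across loci, so epistatic patterns — including
a double-heterozygote that is *not* the most severe combination under
per-locus heterosis — cannot be represented.
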