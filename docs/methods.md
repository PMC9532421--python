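# Methods

`cfhmc` implements a plasma cfDNA analysis for colorectal-cancer (CRC)
detection built from three feature families and one classifier, plus the
synthetic cohort generator used to exercise them end to end. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic tests do and do not demonstrate.

## Library QC scoring (`cfhmc.qc`)

Each sequencing library (the whole-genome "input" library and the
5hmC-enriched "pulldown" library of a sample) accumulates penalty points; 0
is a perfect library and a total over 15 discards the library **and its mate**
(both libraries of the sample are dropped together).

Fixed 5-point criteria: post-deduplication reads < 10 M; genic/intergenic
RPKM ratio < 1 (pulldown only); spike-in enrichment ratio < 1; mitochondrial
RPKM > 1000; < 10% of reads in peaks; median insert size > 200 nt;
uniformity < 0.8 (input only). Three points are added per auxiliary metric
outside the cohort median ± 1.5×IQR, and one point per listed metric more
than 2 SD outside previously observed ("prior") ranges — pulldown:
genic/intergenic enrichment, duplication rate, coverage; input: sequence
diversity. A boundary total of exactly 15 passes ("over 15" is strict).

Two quantities have no published definition and are defined here:

* **uniformity** — fraction of non-blacklist 10 kb bins whose fragment count
  lies within [0.2×, 5×] of the genome-wide mean. It is monotone in coverage
  evenness and usable with the printed 0.8 threshold.
* **sequence diversity** — unique fragment start positions ÷ total fragments.

The 26-metric auxiliary set is configurable; the default is the computed
scalar metrics plus per-chromosome fragment shares, with 3 points per
offending metric (the published rule is ambiguous between per-metric and
overall; per-metric is the conservative reading). Similarly "coverage" in
the 1-point rule is taken as mean depth. A missing metric is scored as its
worst case, with a warning recorded in the result's reasons.

## 5hmC enrichment features (`cfhmc.hmc`)

For each candidate enhancer region r and library L,
`RPKM_L(r) = reads_r / (len_r/1e3) / (total_reads_L/1e6)`. Fragments are
assigned to regions by **midpoint membership** and each fragment counts as 2
reads (a proper pair), making the fragment-level computation comparable with
a read counter while counting each fragment exactly once. The per-enhancer
feature is

```
e_r = log2( (RPKM_pulldown,r + 1) / (RPKM_input,r + 1) )
```

with the pseudocount added to both RPKMs (symmetric, bounded, and maps a
doubly-empty region to 0; adding it to raw counts instead is an admissible
alternative the implementation does not use). Spike-in folds are
`(pull_s/total_pull) / (in_s/total_in)` per species against library-wide
read totals; species with zero input counts report NA.

For modelling, the feature matrix is quantile-normalized across samples
(each sample's values mapped onto the mean order statistics of the training
samples; ties take the reference value at the mean of their rank positions,
the limma convention) and then z-scored per feature. Both transforms are
fitted on training samples only and frozen; zero-variance features are
dropped and recorded. Applying the frozen state to validation samples never
mutates it — this is asserted by hashing the state.

## Fragment-size (DELFI-like) features (`cfhmc.delfi`)

The genome is tiled into 100 kb bins; bins overlapping the blacklist or
assembly gaps by any amount are dropped whole (conservative and
deterministic, since partial-overlap handling is not specified), and only
declared standard chromosomes are used. Fragments are size-filtered to
[100, 220] nt; short = [100, 150], long = [151, 220] (length = end − start);
each fragment goes to the bin containing its midpoint. Per bin: short count,
long count, total, and short/long ratio (NA when no long fragments, not
+inf). The four metrics are averaged (arithmetic mean, NA skipped) over
non-overlapping 5 Mb tiles; a tile with no surviving bins is NA and is later
imputed by the training-set feature median. With the real genome and
published masks this tiling yields 26,170 bins and 512 aggregate regions;
those counts depend on external blacklist/gap versions and are not asserted
by tests.

## Nucleosome Presence Score (`cfhmc.nps`)

For position i, a 121 bp window W(i) = [i−60, i+60] is scored
`NPS(i) = n_span / n_within`, where n_span counts fragments fully covering
the window and n_within counts fragments with ≥ 1 endpoint inside it. In
half-open coordinates a fragment [s, e) **spans** W(i) iff `s ≤ i−60` and
`e ≥ i+61`, and has an **endpoint inside** iff s or e−1 lies in [i−60, i+60];
a fragment contributes once even when both endpoints fall in the window.
These inclusivity conventions are a documented choice (the prose definition
does not fix them) and the test oracles use the same ones. Only fragments of
120–250 bp contribute (single-nucleosome configurations), and the statistic
is depth-independent: duplicating the fragment set exactly leaves it
unchanged wherever defined.

Numerical pipeline per region:

1. **Pooling** — ratio of sums over ±5 positions (not mean of ratios: the NA
   condition is defined on the summed denominator); NA where the pooled
   denominator is 0; the region is undefined for a sample when > 90% of
   positions are NA. Edge positions pool over the available neighbors.
2. **Imputation** — interior NA runs linearly bridge the nearest defined
   values; leading/trailing runs extend the nearest value (the bridge is
   undefined at edges; nearest-value extension is the chosen rule).
3. **Smoothing** — degree-2 Savitzky–Golay, 151 bp window; edges use a
   polynomial fitted to the terminal window (scipy `mode="interp"`). Regions
   shorter than 151 bp are undefined.
4. **Nucleosome calling** — a position is a candidate iff it attains the
   maximum of the 151 bp window centered on it (ties all qualify);
   left-to-right chains of candidates with consecutive spacing ≤ 76 bp
   collapse to the rounded (half-up) midpoint of the chain extremes. The
   resulting centers are automatically pairwise > 76 bp apart. A flat
   profile degenerates to a single center and warns.
5. **Features** — for each adjacent nucleosome pair ≤ 300 bp apart, the
   minimum smoothed NPS in ±50 bp around the pair midpoint. Candidate
   detection and feature extraction both use the smoothed profile.

Region selection follows the development-sample protocol: candidate peaks
(externally supplied, or from the internal substitute caller: maximal runs of
pooled development coverage ≥ a threshold, merged within 100 bp) are ranked
by the across-sample median of mean per-base coverage and the top 200 kept,
ties broken by (chrom, start). The nucleosome map is built once from the
pooled development fragments and frozen — development samples never enter
training, and feature identity is constant across the cohort (schema hash).

## Classifier (`cfhmc.classify`)

`CfDNAClassifier(features, labels, covariates, weights).fit()` returns a
frozen `CfDNAClassifierResults` (statsmodels-style Model/Results split).
The training protocol:

1. Median-impute NAs; fit quantile + z-score normalization on training rows.
2. Exclude features significantly associated with technical covariates:
   simple-regression slope t-test per continuous covariate, one-way ANOVA
   F-test per categorical covariate, exclusion when any p < α (default 0.01,
   configurable; the published threshold is unstated). Constant features are
   excluded by a zero-variance pre-rule; single-level covariates are skipped
   with a warning.
3. Train an ensemble of 50 linear SVMs. Learner i draws a class-stratified
   80% subsample (seed = base_seed + i; a single-class subsample is redrawn
   with an offset seed and logged). The cost parameter C is chosen from
   {1e-3, 1e-2, 1e-1, 1, 10} by highest mean AUC over stratified tenfold CV
   inside the subsample (ties → smaller C). Probabilities come from Platt
   scaling fitted to out-of-fold decision values (internal 5-fold CV) —
   linear SVMs do not natively emit probabilities and the published
   procedure does not name a calibration, so Platt is the package's choice.
4. Each learner's held-out 20% yields an AUC; the **internal cross-validation
   AUC** is their mean. "Selected" features are those with |w| > 1e-8; the
   retained set is the union over learners (the published phrase admits
   union or intersection; union is the default and the quantity is exposed,
   not used for refitting).

Prediction averages the 50 calibrated probabilities; a sample is called CRC
strictly above 0.5. The fitted ensemble serializes to versioned JSON whose
MD5 digest is the model identifier; an append-only JSON-lines registry
mirrors the blinded-validation contract (prediction against an unregistered
or tampered model hash is refused). With one learner and an 80%→100%
subsample the ensemble provably reduces to a single CV-tuned SVM (tested).

Optional propensity weighting: a logistic model of class on the extended
covariates yields stabilized inverse-probability weights, truncated at the
1st/99th percentiles and renormalized to mean 1 per class; near-separation
falls back to a ridge-penalized fit with a warning.

## Performance statistics (`cfhmc.metrics`)

AUC uses the Mann–Whitney mid-rank formulation (ties count 1/2).
Sensitivity at fixed specificity takes the loosest cutoff whose empirical
specificity reaches the target. Confidence intervals are percentile
bootstrap over 2000 resamples of (score, label) pairs (the published method
names the replication count but not the flavor; BCa is not used), with
single-class resamples redrawn. Call-rate tables report, per (diagnosis,
stage) group, the percent called CRC with a **Wald** 95% interval: percent to
two decimals, half-width 1.96·√(p̂(1−p̂)/n), bounds clipped to [0, 100] and
rounded half-up to integers. This exact recipe — including the degenerate
(0, n) → (0, 0) interval that rules out Wilson or exact intervals — is the
only reading that reproduces every printed row of the published validation
call-rate table, and the full table is a regression test.

## Synthetic cohort generator (`cfhmc.simulate`)

The generator produces the statistical structure the analysis assumes, at
desk scale, with every draw keyed by (seed, sample_id, stream) so cohorts
are byte-reproducible and order-independent.

* **Genome** — 2 chromosomes × 10 Mb; genic and intergenic territory
  alternate in 500 kb blocks; 500 × 1 kb enhancers occupy random
  non-overlapping slots inside genic blocks; blacklist (2 × 50 kb/chrom) and
  one assembly gap per chromosome sit in intergenic blocks; peaks are padded
  enhancers plus broad genic domains, so peaks ⊇ enhancers.
* **Input libraries** — 50,000 fragments; midpoints uniform over the
  non-blacklisted genome; lengths a two-component normal mixture: a
  mononucleosomal mode at 166 bp (SD 10) and a shorter tumor mode at 145 bp
  (SD 10) whose weight is the sample's tumor fraction (0.1 for cancer
  samples, 0 for controls). The short-mode shift is what the fragmentomics
  features detect.
* **Pulldown libraries** — fragment midpoints drawn per region with weight
  proportional to 2^enrichment × length: per-bp weight 1 in clean intergenic
  territory, 1.8 in genic background (so the genic/intergenic RPKM ratio
  reproduces the observed ~1.8), and 2^e_r in enhancer r, where
  e_r ~ Normal(μ0 + δ·[case ∧ affected], σ0) per sample with μ0 = 2, σ0 = 0.5,
  and 10% of enhancers carrying the disease effect. Enrichment acts on
  sampling weights, not per-fragment labels, because the read-count ratio is
  the observable the features use.
* **Spike-ins** — counts only (every published use of spike-ins is a count
  ratio): input counts Poisson(500) per species; pulldown counts
  Poisson(500 × fold) with expected folds 88/267/658 for the 1/3/6-hmC
  positive controls and 1 / 0.38 for the 5mC and unmodified negatives.
* **Covariates** — age ~ N(64, 9²), sex (52% F), ethnicity, vendor, batch,
  and binary smoking/diabetes/statins/NSAIDs/alcohol flags; one confounding
  coefficient shifts case age (+5 y per unit) and smoking prevalence
  (+0.10 per unit), default 0 (independent).

**Effect size.** No quantitative case/control 5hmC effect size is published,
so the default δ is fixed by a declared rule rather than taste: under the
Gaussian-LDA approximation the optimal AUC on k affected features with
per-feature noise σ is Φ(δ√k/(σ√2)); requiring ≈ 0.99 with the empirically
measured null per-feature SD σ ≈ 1.9 (dominated at desk-scale depth by
shallow input coverage of ~2.5 fragments per enhancer) and k = 50 gives
δ = 2.326·√2·σ/√k ≈ 0.9, the frozen default. The generator was calibrated
once with this rule and not revisited.

**What the generator does not emulate** — sequence content, GC bias,
mappability, copy-number events, batch/plate technical effects on features,
stage-dependent effect sizes, and real enhancer biology. Passing tests
therefore demonstrate that the pipeline's machinery is correct and leakage-
free and that the classifier recovers planted signal at the stated strength;
they say nothing about the discriminative power of 5hmC in real plasma.

## Problem sizes used by the shipped analyses

The packaged acceptance analyses run, and the test suite asserts: a
strong-effect cohort of 200 cases + 200 controls for training with a fresh
100 + 100 validation cohort under the full 50-learner ensemble; a null
(δ = 0, no size shift) design of 40 + 40 training and 40 + 40 validation
samples repeated over 10 seeds with a 10-learner ensemble; 200 random NPS
instances (≤ 2 kb regions, ≤ 200 fragments) against the brute-force oracle;
and the complete published call-rate table. These sizes are the package's
default desk-scale choices; all of them are configurable upward.

## Known limitations

* The QC auxiliary-metric set is a stand-in for the unpublished 26-metric
  list; only its scoring mechanics are faithful.
* The internal coverage-threshold peak caller is a deliberately simple
  substitute for external MACS2/EPIC2 peak calls, which remain the intended
  input for real data.
* BAM handling is out of scope; fragments enter as BED-like intervals.
* Bootstrap percentile intervals mildly under-cover for extreme statistics
  at small n (inherent to the method; coverage is verified ≈ 95% at n = 200).
* Tumor-fraction estimation (ichorCNA) and pathway analysis are out of scope.
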