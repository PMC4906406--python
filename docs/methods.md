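# Methods

## Scope and model

`ctdnaprof` analyses targeted hybrid-capture deep sequencing of plasma
cell-free DNA (cfDNA) from EGFR-mutant lung-cancer patients under
third-generation EGFR TKI therapy. It operates downstream of alignment
and variant calling: its inputs are per-region mean depths over a
designed selector (BED intervals), per-sample variant tables with
VAF/depth/alt-read counts and functional annotation, and per-patient
clinical endpoints. Read-level processing (alignment, UMI handling, SNV
calling) and selector design are out of scope.

The central quantity is a plasma sample modelled as a two-component
mixture: a fraction *f* of tumour genome-equivalents in a diploid
background. For a gene with mean tumour copy number CN this predicts a
linear depth excess

    r = (1 − f) + f · CN / 2,

and for a variant carried on *m* copies per tumour cell in a clone that
is a fraction *c* of the tumour,

    E[VAF] = f·c·m / (2(1 − f) + f·CN).

Every estimator in the package is an inversion of a piece of this
model; the synthetic-data generator is its forward simulation, which is
what makes parameter-recovery testing meaningful.

## Depth normalization and the control model

Each sample's per-region depth is divided by the sample's selector-wide
autosomal median depth and log2-transformed. The median (not mean) is
used so that focal amplifications in the sample do not move the
normalizer; this works because genes under copy-number test are a small
share of the panel (22 of 242 regions in the default synthetic
selector, mirroring the minority share such genes hold on real
multi-hundred-region panels). Regions with zero depth map to a −∞
sentinel, are excluded from downstream statistics and reduce the
per-gene region count.

A healthy-control cohort (default n = 27) provides per-region means μᵢ
and standard deviations σᵢ of normalized depth (ddof = 1). Per-region
Shapiro–Wilk p-values are stored as QC metadata but do not exclude
regions by default; σᵢ = 0 regions are excluded (a z-score is undefined
there) and logged, never floored. Genes with no included regions are
marked uncallable rather than scored.

## Copy-number index and threshold calibration

Per-gene, region z-scores combine as C_g = Σ zᵢ / √n_g. This is
Stouffer's unweighted combination in form only: capture regions of one
gene are correlated, so C_g is not given a nominal normal reference.
Instead each gene's detection threshold t_g is the smallest observed
control index value at which the control false-positive rate (FPR,
counting C ≥ t) is below α (default 0.05); if no observed value
qualifies, the threshold is a sentinel one ULP above the control
maximum and the gene is flagged. Candidate thresholds are restricted to
observed control values plus that sentinel so calibration is exactly
reproducible from the stored control indices. Detection is non-strict
(C ≥ t). The index is signed; large negative values (losses) are
reported descriptively but never called — calibration covers gains
only.

**Out-of-sample calibration (design choice).** With n = 27 controls, an
index computed against μ/σ estimated from the same sample's cohort is
systematically narrower than the index of an unseen sample, so a
threshold calibrated purely in-sample delivers an out-of-sample FPR of
roughly 5–7% rather than the advertised < 5% (measured on held-out
synthetic cohorts). The default therefore scores each control against
leave-one-out means and standard deviations (closed form, no
refitting), which makes the calibration indices exchangeable with an
unseen sample; the expected held-out FPR of the resulting threshold is
≈ 1/(n+1) ≈ 3.6%. The literal fit-and-calibrate-in-sample procedure
remains available as `calibration="in_sample"`. Note that any threshold
that is an extreme order statistic of 27 draws has a widely dispersed
conditional FPR (≈ Beta(1, 27), sd ≈ 3.4%): single-gene specificities
on a few hundred held-out samples fluctuate by several points even
though the panel-wide rate is stable. Specificity claims in the tests
are therefore made panel-wide.

**Normalized copy number.** For a called gain, the linear relative
depth r is the mean over the gene's regions of 2^(d̂ᵢ − μᵢ) — the excess
over the control baseline, which cancels fixed per-region capture
efficiency and has a diploid baseline of exactly 1. Inverting the
mixture model gives CN = 2 + 2(r − 1)/f, clipped below at 0 and
computed only when the call is significant and a tumour fraction is
available. A conclusiveness gate accompanies every call: when the
sample's raw truncal/activating VAF is below 2% (configurable), a
negative copy-number result is marked inconclusive rather than treated
as absence of the alteration.

## ctDNA fraction and the T790M : activating ratio

The tumour genome-equivalent fraction is f = min(1, 2·VAF) of a
heterozygous-clonal anchor: a truncal TP53 mutation when present,
otherwise the EGFR-activating mutation corrected for excess EGFR
coverage. Gates that the analysis expresses in VAF units (the 2%
conclusiveness gate) are applied to the raw VAF; both raw and doubled
values are always carried (`ctdna_fraction_mode` selects which scale
`fraction` reports).

**Coverage correction.** When a significant EGFR gain is called, the
activating VAF is converted to its heterozygous-equivalent (the VAF it
would have at copy-neutral EGFR) under the model that every amplified
copy carries the activating mutation: corrected = raw · r / CN, which
equals f/2. When CN is itself unknown because f is (the
no-TP53-anchor case), substituting CN = 2 + 2(r−1)/f yields the closed
form f = raw·r − r + 1, used directly. T790M is never copy-number
corrected (single-copy assumption). Without a called gain the
correction is the identity.

**Censoring.** When the activating mutation is detected but T790M is
not, the T790M VAF is censored at the lower of (a) the binomial limit
of detection at the T790M locus depth — the smallest VAF v with
P[X ≥ s] ≥ 0.95 for X ~ Binomial(depth, v), closed form
1 − 0.05^(1/depth) at s = 1, solved by bracketed root-finding
otherwise (default s = 2, a minimal-supporting-evidence convention) —
and (b) the corrected activating VAF itself, so a censored ratio never
exceeds 1. Trajectories require T790M detectable pretreatment and the
activating mutation detected at both endpoints; a progression
activating VAF below 0.3% (configurable) makes the percent change
incalculable and the patient not evaluable.

**ROC cut-point.** Baseline ratios are dichotomized at the candidate
(midpoints of consecutive sorted unique ratios) maximizing Youden's J
for predicting partial response (≥ 30% target-lesion shrinkage), ties
to the smallest candidate.

## Germline filtering

Plasma-only designs cannot subtract matched germline, so three rules
stand in: removal of catalogued population variants (blacklist),
restriction to nonsynonymous substitutions, and a MAF-window rule
removing VAFs in [0.40, 0.60] or ≥ 0.90 — the signatures of
heterozygous and homozygous SNPs — while the tumour fraction is below
0.40 (the windows are meaningless once ctDNA approaches germline
levels; an unknown fraction conservatively keeps the windows active).
All removals carry provenance labels.

## Resistance rules

Candidate alterations are germline-filtered SNVs in panel genes plus
gene-level gains in the copy-number genes (EGFR, ERBB2, MET by
default). T790M and the activating EGFR mutation are excluded as
candidates — they are the treatment's target. Between pretreatment and
progression endpoints (intermediate timepoints are reported
descriptively only):

- **emergent** — undetected pretreatment, detected (SNV) or
  significant-and-conclusive (SCNA) at progression;
- **increasing** — detected at both endpoints with strictly increasing
  relative abundance (VAF over the raw truncal-anchor VAF for SNVs;
  normalized copy number, already per-ctDNA by construction, for
  SCNAs); an optional minimal fold-change knob defaults to 1.0 (any
  increase);
- **carried_forward** — a pre-existing SCNA whose progression
  copy-number analysis is inconclusive (< 2% activating VAF), or a
  pre-existing SNV when progression plasma has no detectable ctDNA.

Timing is innate when progression-free survival is under 3 months
(30.44 days/month; the exact boundary goes to acquired, with a 1e-9
month tolerance against float rounding). Patient mechanism categories
{SCNA only, SCNA+SNV, SNV only, none} are compared between timing
classes with the Freeman–Halton exact test: conditional on the observed
margins, the two-sided probability-ordering p-value sums multivariate
hypergeometric probabilities of all tables no more probable than the
observed one (relative tie tolerance 1e-7 in log space guards float
ties). Enumeration is exact up to a table-count guard (default 10⁷);
beyond it a seeded Patefield Monte-Carlo sampler with a +1/(n+1)
correction is available. Cohort endpoint comparisons (best RECIST
response by rank-sum, progression-free survival by Kaplan–Meier and
log-rank honouring censoring flags) delegate to scipy and lifelines;
groups with fewer than two members flag the tests as underpowered
rather than reporting p-values.

## In-silico spike-in benchmark

Tumour depth signal is diluted into healthy-control backgrounds at
defined ctDNA percentages. The package mixes in depth space rather than
at the read level: each row is scaled to its own autosomal median
(genome-equivalent equalization, the depth-space interpretation of an
input-mass adjustment), mixed linearly, and rescaled so the mixture's
autosomal median equals the control's — preserving exactly the quantity
the index consumes. The canonical design crosses 12 fractions (0.1,
0.3, 0.5, 0.75, 1, 1.25, 1.5, 1.75, 2, 2.5, 5, 10%) with 27
backgrounds: 324 spike samples per tumour profile. The bundled tumour
profile mirrors a lung-cancer line carrying ~13 MET copies (6.5×) and
~20 EGFR copies (10×). Specificity uses held-out controls by default;
scoring the calibration cohort itself (in-sample) is possible and is
bounded at ≥ 26/27 per gene by the calibration rule. Externally
computed depth matrices can be fed through the same grid runner, so an
empirical spike-in dataset can replace the synthetic backgrounds; no
download is performed by the package.

## Synthetic cohorts: what they emulate, and what they do not

`gen_control_cohort` draws depth(s, i) = mean_depth · eᵢ · 2^(σ·ε) with
per-region capture efficiencies eᵢ fixed across samples (drawn once per
selector; log2 sd 0.25) and ε standard normal per sample-region. The
defaults are the study conditions the analysis assumes: 27 controls,
mean depth 5,500×, and per-region log2 depth sd σ = 0.10. No magnitude
for σ is dictated by the depth-normality observation the model rests
on; 0.10 was chosen once as a realistic deep-capture panel noise level
at which a 10× gain is detectable from ≥ 2% ctDNA, and it is a config
knob. Tumour samples scale gene depths by the mixture model and draw
alt reads binomially at the realized locus depth (a beta-binomial
overdispersion knob exists, default off). Longitudinal scenarios plant
ground truth for recovery tests: `t790m_depletion` (T790M subclone
falls to 20–45% of its baseline fraction at progression — a median
ratio drop ≈ 67%), `emergent_met` (MET copy number 9 appearing at
progression), `increasing_snv` (a PIK3CA-mutant subclone growing from
10% to 40% of the tumour), `mixed_mechanisms` (MET 4 → 9 plus an
emergent KRAS clone), and `null`. Tumour fractions are drawn
uniformly from 5–20% at the endpoints with an on-treatment dip.

The generator does **not** emulate GC or mappability bias,
fragment-size structure, sequencing-error substitution noise,
overlapping subclone phylogenies (clones are disjoint fractions), or
sample-to-sample capture-efficiency drift. Passing tests therefore
demonstrate correctness of the estimators under the stated mixture
model, not robustness to those real-data artefacts; on real panels the
control model absorbs fixed region effects, but batch effects between
control and patient libraries would violate its assumptions.

All randomness flows through seeded generators; a single global seed
fans out per stage and per sample via SHA-256-derived substreams, so
inserting a stage or changing a cohort size does not reshuffle
unrelated draws, and identical seeds give byte-identical outputs.

## Numerical choices and test problem sizes

Threshold sentinels use one-ULP `nextafter`; LOD inversion uses brentq
on the binomial survival function (xtol 1e-14); model persistence
round-trips floats exactly (full-precision text, round-trip parsing).
The test suite exercises: null-index normality on 10,000 held-out
synthetic controls against a 500-control model (Kolmogorov distance
< 0.05); held-out FPR on 1,000 controls; exhaustive Freeman–Halton
agreement with a rational-arithmetic enumeration oracle over all 18,564
2×3 tables with N ≤ 12 plus 2×2 Fisher equivalence; copy-number
recovery over 100 replicates at f = 5% (±10%) and fraction recovery at
f = 2% (±20%); the clonal-selection signature over 100 replicates of
35-patient depletion cohorts (ratio decreases in ≥ 80% of patients and
the one-sided signed-rank test rejects at α = 0.0005 in ≥ 80% of
replicates); and mechanism recovery over 100 patients per scenario
(precision/recall ≥ 0.9 on mechanism-planting scenarios; the null
scenario is checked against the calibrated false-call budget of
~3 CN genes × 1/28 per patient, since a rule built on an α = 0.05
detector necessarily inherits its false-positive leak).

## Known limitations

- Per-gene calls only: focal amplification is not distinguished from
  polysomy, and no segmentation or allele-specific copy number is
  attempted.
- Copy-number losses are reported descriptively, never called.
- The coverage correction assumes all amplified EGFR copies carry the
  activating mutation; if the amplification is on the wild-type allele
  the corrected VAF underestimates f/2.
- The ctDNA fraction from a single anchor variant ignores anchor-gene
  copy-number changes other than the modelled EGFR case (TP53 is
  assumed copy-neutral).
- Resistance calling inherits the copy-number detector's α: on
  ctDNA-rich series expect of order 0.1 false mechanism calls per
  patient across three CN genes at default settings.
- With 27 controls, per-gene thresholds are extreme order statistics;
  single-gene out-of-sample FPRs are dispersed even though the panel
  mean is calibrated.
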