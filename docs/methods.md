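# Methods

## The problem

Affinity-purification mass spectrometry (AP-MS) against an unlabeled
control identifies the proteins that co-purify with a tagged bait — here
the archetype is a HaloTag-NRP1 bait on the surface and in the early
endosomes of endothelial cells, pulled down on streptavidin beads, with the
unlabeled pull-down as the control channel.  The package implements the
complete label-free scoring workflow from the intensity matrix to the
called interactor sets, the topology/location classification of those sets,
and the quantification of three downstream functional readouts (FRAP,
surface-biotinylation internalization ELISA, transendothelial tracer flux).
A synthetic-data module generates inputs with the statistical structure
every stage assumes, so the whole chain is testable without any raw MS
data.

## Interactor calling

The experimental design is three groups (surface-labeled at 4 °C,
endosome-containing after a 3-min 37 °C chase, unlabeled control) × 4
biological replicates.  The stages, in order:

1. **Validity filter** — keep proteins quantified in ≥ 3 of 4 replicates in
   at least one group.  Proteins below this in every group carry too little
   information for a 3-df t-test.
2. **log2 transform** of the LFQ intensities.
3. **Downshifted-normal imputation** — missing LFQ values are left-censored
   (low-abundance proteins fall below detection), so each missing cell in
   sample column *s* is drawn from Normal(μ_s − 1.8 σ_s, (0.3 σ_s)²), with
   μ_s, σ_s the mean and SD of the column's observed values.  Width 0.3 and
   downshift 1.8 are the conventional Perseus settings and the defaults
   here.  Imputation is per column (per MS run), respecting per-run depth;
   a single imputation seeded from the run seed, recorded in the report.
4. **Ratios** — replicate-paired log2 differences, compartment replicate i
   minus control replicate i (the replicates are paired biological
   experiments).  An unpaired mean-vs-mean mode is available
   (`CallingParams(paired=False)`).
5. **One-sample t-test** of the 4 ratios against 0, two-sided, t = m/(s/√n)
   with n−1 df.  Zero-SD rows are flagged `degenerate` (p = 0 if the mean
   is nonzero, p = 1 otherwise) rather than silently dropped.
6. **BH q-values** (step-up) are computed per compartment and reported
   alongside p.
7. **Calling** — interactor ⟺ mean fold change ≥ 1.5 (inclusive; i.e. mean
   log2 ratio ≥ log2 1.5 ≈ 0.585) AND raw p < 0.05 (strict).  Calling on
   raw p is the default because the published thresholds are stated on the
   volcano p values, with q reported in addition; `use_q=True` switches the
   significance condition to q.
8. **Background flagging** — proteins detected in ≥ 50% of
   contaminant-repository (CRAPome-style) negative-control runs are
   flagged.  The flag annotates; it never removes a call, because repository
   frequency is evidence of stickiness, not of absence of true interaction.
   The 0.5 threshold is a repository convention, exposed in config.

## Classification and enrichment

Topology terms "Single-pass type I membrane protein", "Single-pass type II
membrane protein", "Multi-pass membrane protein" define the transmembrane
subset; locations "Early endosome", "Late endosome", "Lysosome",
"Cytoplasmic vesicle(s)" define the endosome-located subset.  Matching is
case-insensitive substring matching on the annotation free text, tolerant of
composite strings ("Multi-pass membrane protein; Signal-anchor") and of the
singular/plural vesicle forms.  Transmembrane proteins are grouped into
"Membrane", "Focal adhesion", "Cell membrane", "Cell Junction" (multi-
membership allowed; the bare "Membrane" term deliberately does not match
"Cell membrane" text) for the chord-diagram export; unmatched proteins go
to "Other" with a warning.

Category enrichment of the interactors remaining after the transmembrane
and endosome-located branches are removed uses a one-sided hypergeometric
test per category (p = P(X ≥ k) for overlap k), BH across categories,
significance at q < 0.05.  The default universe is the set of proteins
passing the validity filter — a matrix-restricted background, unlike web
enrichment tools that default to a genome background; this is the honest
universe for a pull-down and is configurable.  Categories with fewer than
two universe members are skipped as degenerate.

## Assay estimators

**FRAP.**  Traces carry 2 pre-bleach, 2 bleach, 50 post-bleach frames every
1.4 s.  Normalization maps the pre-bleach mean to 100% and the first
post-bleach frame to 0%.  The mobile fraction is
Mf = (F_plateau − F₀)/(F_pre − F₀) with the plateau estimated as the mean
of the last 5 post-bleach frames; this is unbiased when the recovery time
constant τ is well below the post-bleach window (τ ≤ total/5 gives
< 0.2% truncation error) and is cross-checked against a single-exponential
fit mode (`method="expfit"`).  F₀ is the first post-bleach frame (optionally
a 2-frame average under noise), not the trace minimum, which would bias the
floor down.  Values are clipped to [0, 1]; the raw value is also reported.
No acquisition-photobleaching reference correction is applied by default.

**Internalization ELISA.**  Percent internalized =
(mean internalized OD − mean background OD)/(mean total OD − mean
background OD) × 100, where background is the strip-immediately control.
Scale-invariant in OD units.

**Permeability.**  Per-timepoint transported fraction = basal signal /
apical input, summarized by a least-squares slope through the origin
(fraction per hour).  When aliquot and basal volumes are supplied, the
amounts removed with earlier aliquots are credited back (sequential 50 µl
sampling depletes the basal compartment); otherwise raw signals are used.

**Comparison.**  percent_change = 100 (ctrl − treat)/ctrl, positive for
reductions, with a delta-method SE from the two estimates' SEMs.

## Synthetic-data generator

`simulate_apms` draws each protein's base log2 abundance from
Normal(25, 2²) (typical LFQ log2 range), adds replicate noise
(SD 0.3 log2 units), elevates planted interactors by `planted_log2fc` in
their compartment(s) only — background binders stick to beads in every
channel, so the control contains all proteins at base level — and censors
each cell independently with probability 1 − logistic(slope · (x −
midpoint)).  The defaults (midpoint 22.2, slope 1.0) give ≈ 15%
control-channel missingness, concentrated at low intensity, which is
exactly the regime the downshifted-normal imputation models.  The planted
counts default to 28 surface-only / 53 endosomal-only / 33 shared, matching
the published set cardinalities (61 surface, 86 endosomal, 33 shared), with
2000 background proteins.  One RNG stream is spawned per protein from the
scenario seed, so enlarging a scenario never reshuffles existing proteins.

`simulate_frap` generates recovery traces F(t) = b + Mf (1 − b)(1 −
e^(−t/τ)) with additive frame noise and optional between-cell spread of Mf.
`simulate_assays` generates paired ELISA plates (internalized OD =
surface_signal · fraction + background, multiplicative CV noise) and
cumulative-flux timecourses.

The shipped paired scenarios encode the published effect sizes as planted
truth: `frap_vecad_nrp1_kd` (control Mf 0.75, knockdown 0.63 × control →
37% reduction; τ 10 s, floor 0.25, frame noise 0.03, cell SD 0.06, 24 cells
per condition, i.e. 3 experiments × 8 cells), `internalization_vecad_nrp1_kd`
(control fraction 0.30, 26% reduction), `endocytosis_nrp1_miniwars` (0.25,
19%), `endocytosis_vecad_miniwars` (0.25, 18%); ELISA plates use surface
signal 1.2 OD, background 0.05 OD, 5% CV, 3 replicates (three independent
experiments).  Control fractions, ODs and noise levels are realistic
stand-ins chosen once; only the reductions are published quantities.

### What the generator does *not* emulate

No peptide/spectrum level, no protein-inference ambiguity, no
batch/run-order effects, no correlated contaminant structure, no
acquisition photobleaching in FRAP, no transwell edge effects.  Passing
tests therefore validate the estimators against the stated statistical
model, not against every failure mode of real data.

## Operating characteristics and known limitations

- Under a null scenario (no planted interactors, MNAR dropout, 2000
  background proteins) the per-compartment false-call rate is ≈ 0.3–0.5%,
  far below the 5% p threshold, because the ≥ 1.5 fold-change condition and
  the t-test jointly gate the calls; imputation-induced outlier ratios
  inflate the within-protein SD and are caught by the t-test.
- With planted log2 fold change ≥ 2, noise ≤ 0.3 and no dropout, ≥ 95% of
  planted interactors are recovered and high-SNR scenarios recover the
  surface/endosomal/shared partition exactly.  With MNAR dropout enabled at
  log2fc = 2 recovery drops to ≈ 85%: planted proteins whose base abundance
  sits below the detection midpoint are censored in the control *and* often
  in their compartment, so their imputed ratios shrink toward zero.  This
  is a genuine property of left-censored LFQ data, not an implementation
  artifact.
- The percent-change estimator is slightly biased low (≈ 0.3 points at 26%)
  because the noisy control estimate enters the denominator; the bias is
  quadratic in the control's relative error and negligible at the shipped
  noise levels.
- Exact reproduction of the published interactome counts (966 quantified,
  114/61/86/33 called) requires the deposited raw data and the original
  annotation snapshot; the acceptance suite checks the set algebra on
  stand-in lists with the published cardinalities and validates the
  statistical machinery by oracle and simulation instead.

## Problem sizes

Simulation-based tests use 150–4000 proteins, 20 Monte-Carlo seeds, 24-cell
FRAP conditions and 3-replicate plates; the acceptance script averages 100
FRAP and 400 ELISA simulated experiments per target, which puts the
Monte-Carlo SE of each reported percent reduction below 0.3 points.
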