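# Methods

## The assay model

The package models an in vitro omalizumab-response assay on peripheral
blood. Each donor contributes four samples: unchallenged control (CTRL),
omalizumab pre-treatment only (OMA), allergen challenge (ALG), and
omalizumab pre-treatment followed by allergen challenge (ALG+OMA).
Basophils are defined cytometrically as CD45⁺CD123⁺HLA-DRⁿᵉᵍ singlets;
activation is surface CD63. Omalizumab sequesters free IgE and can only
prevent loading of unoccupied FcεRI, so blockade is partial and
donor-specific; the latent blockade strength is a single parameter
ρ ∈ [0, 1] that scales down the allergen-induced activation increment
(and, because activation drives the scatter alteration, the
altered-scatter increment) in the ALG+OMA arm.

### Corrected activity

Let b and c be the total-basophil and CD63⁺⁺-basophil fractions of CD45⁺
leukocytes. Strong activation displaces part of the basophil pool out of
the singlet scatter band ("missing" basophils), which deflates both b and
c. The loss is quantified per culture arm as m = max(b_ref − b_chall, 0)
against the arm's own unchallenged sample (CTRL for untreated, OMA for
omalizumab-treated), and the corrected activity of a challenged sample is
A = (c + m)/(b + m): lost basophils are counted as activated. Properties
used by the tests: A ∈ [0, 1]; A is non-decreasing in m whenever c < b;
m = 0 recovers the uncorrected ratio c/b exactly. The clamp at m = 0 is
deliberate — a loss is defined as a decrease, and sampling fluctuation in
the other direction must not create negative corrections.

The allergen fold change divides A(ALG) by the control activity c/b of
CTRL (the control has m = 0 by construction, so corrected and uncorrected
denominators coincide). The BAT fold change divides A(ALG+OMA) by A(ALG);
lower = stronger in vitro response. BAT positivity follows the clinical
convention and uses a different denominator on purpose: the CD63⁺⁺
fraction *of basophils* (c/b) under allergen must exceed 5%.

### Exclusions and classification

Non-reactive donors (positivity failure) are flagged first; the
Tukey-hinge outlier rule (fences H1 − 1.5·IQR, H3 + 1.5·IQR) then runs on
the BAT Fc values of the reactive donors only — the order matters and is
fixed, so a non-reactive sample can never distort the fences. Hinges are
medians of the lower/upper halves with the overall median included in both
halves at odd n (not interpolated quartiles); the convention is tested
against hand-worked values. With fewer than 4 reactive donors the outlier
step is skipped with a warning. Classification is conservative toward
non-response: the odd-n rank split assigns the median donor to poor/non,
and the margin rule assigns the boundary value (BAT Fc = margin, default
0.6) to poor/non.

## Gating

The singlet gate keeps events whose FSC-H/FSC-A ratio lies in the closed
band [center·(1−w), center·(1+w)], where the center is the median ratio of
all FSC-A > 0 events and w defaults to 0.15. A ratio band was chosen over
a rotated ellipse as the simplest geometry that is exactly invertible for
reverse gating. Events with FSC-A ≤ 0 are dropped and counted in the
diagnostics. Marker gates are closed-interval thresholds (CD45 ≥ 800,
CD123 ≥ 500, HLA-DR ≤ 300, CD63 ≥ 800 in the linear units of the synthetic
channel model). Real instruments require sample-specific thresholds; an
optional `auto_valley` mode places the CD45 and CD63 thresholds at the
minimum of a kernel-density estimate between the two dominant modes.
CD123/HLA-DR bound a rare population where a valley estimate is
unreliable, so they always stay fixed. Fixed thresholds are the default
because they are deterministic and the generator's populations are
separated by > 4 lognormal sigmas from every threshold.

Reverse gating applies the marker gates to all events without the singlet
pre-gate and then splits the marker-positive events by the same ratio
band: inside = intact, outside = altered scatter. Because intersection
commutes, the intact count equals the forward-gated basophil count exactly
(asserted, not approximately). Intact counts alone feed b and c; altered
events influence the readout only through m.

No compensation or pre-gating transform is applied: the generator emits
linear intensities from a small panel, and an arcsinh transform exists
only in the display helpers.

## The synthetic generator

### Event layer

Each sample is a multinomial mixture of six populations — CD45ⁿᵉᵍ debris
(2%), doublets (3%, ratio displaced low), non-basophil CD45⁺ leukocytes,
intact basophils split CD63ⁿᵉᵍ/CD63⁺⁺, and altered-scatter basophils that
retain the marker phenotype but sit outside the ratio band. Channel
intensities are lognormal with per-population medians and CVs from a
single table (`CHANNEL_MODEL`). Altered basophils retain their markers and
shift only scatter, so reverse gating is by construction the correct
recovery mechanism. The altered-scatter share of the putative basophil
pool is 6.57% in unchallenged samples and 14.73% under allergen (the
assay's published operating point), interpolated by 1 − ρ in the ALG+OMA
arm; inter-donor variability of these shares is *not* modeled, which makes
the binomial-recovery tests sharp.

Donor parameters: basophil frequency ~ U(0.005, 0.02) of CD45⁺ events,
baseline activation ~ U(0.01, 0.05) of basophils, allergen reactivity
(activation ceiling) uniform in a window whose mean is derived analytically
so that the expected cohort-mean allergen fold change equals 7.89:
E[fc] = E[A(ALG)]·E[1/a₀] for independent reactivity and baseline a₀, and
the corrected-activity model gives A(ALG) = ((1−m_a)p + (m_a−m_c))/(1−m_c).
With the defaults this puts reactivity in ≈ (0.06, 0.18) and the realized
per-donor fold changes span ≈ 2.8–25, straddling the published 2.07–26.3
range. Per-donor BAT-Fc targets are a jittered, shuffled linspace over
(0.3, 1.5) — guaranteeing both responder classes in every cohort — and are
inverted to ρ through the activity model (targets above the attainable
ceiling clip to ρ = 0). A knob for per-arm reactivity jitter (`arm_cv`)
exists for realism studies but defaults to 0: latent-level jitter directly
degrades the ρ-recovery calibration below.

Seeding: one global seed expands to per-sample substreams via
SeedSequence(seed, crc32(donor_id), crc32(condition)) — samples are
individually reproducible and mutually uncoupled. Channel draws are
float32 (event tables are large; thresholds sit orders of magnitude above
float32 resolution).

### Event depth (error budget)

The correction differences two basophil fractions of order
f ≈ 0.012 of CD45⁺ events, with true loss m ≈ 0.08·f ≈ 1e-3. The
counting error of each fraction is √(f/N), so
σ(m) ≈ √(2f/N) and the relative error of A propagates as ≈ √(3/(fN))/A.
At 50k events/sample this gives a BAT-Fc estimator noise of ~0.3–0.5
against a latent signal spread of ~0.26 — the per-cohort Spearman between
1−ρ and the estimated BAT Fc then plateaus near 0.5 no matter how the
pipeline is tuned. A depth scan (20 seeds, n = 22) gave min-over-seeds
Spearman of 0.27 / 0.66 / 0.77 / 0.81 / 0.83 at 50k / 200k / 500k / 700k /
800k events. The default is therefore **800,000 events per sample**, at
which every cohort in the scan reaches ≥ 0.8. This is a counting-
statistics requirement of the differencing correction itself: assays that
only report the CD63⁺⁺ fraction can work at far lower depth, but resolving
a ~0.1% absolute loss cannot.

### Expression layers

Counts are negative binomial (dispersion 0.10 for targets and background
genes; 0.02 for the B2M/GAPDH/RNA18SN5 references — housekeeping genes are
chosen for stability) with lognormal per-sample size factors (sd 0.15) and
a mean library of 50k over 200 genes. RSAD2's log2 mean is
9 − 2·(BAT Fc); all other genes, including the remaining targets HERC5,
APOBEC3B and OAS3, are independent of the response. The slope/dispersion
operating point was set by an attenuation calculation before the
Monte-Carlo tests were run: signal sd ≈ 2·sd(BAT Fc) ≈ 0.5 log2 units
against ≈ 0.5 log2 units of NB-plus-qPCR noise predicts a sample Spearman
near −0.7 at n = 19 and ≥ 70% power for a BH-adjusted rejection across the
four-gene panel — the magnitude regime reported for this class of assay.

Ct values follow Ct = 38 − log2(count) + N(0, 0.1); zero counts and Ct
above 40 are censored wells and propagate as missing, never as zero
expression. The 2^−ΔΔCt quantification uses the arithmetic mean of the
three reference Cts as the internal control — this equals geometric-mean
normalization of the reference quantities in linear space; taking the
geometric mean of the Ct values themselves would differ slightly, and the
linear-space reading was chosen and is stated here because the phrase is
ambiguous in common usage. The default calibrator is the per-gene mean ΔCt
across samples (expression relative to the cohort average); a named
calibrator sample must have uncensored target Cts.

The longitudinal clinical generator emulates whole-blood expression at 0,
3 and 6 months of therapy: both groups rise by 3 months; responders return
toward baseline by 6 months while non-responders stay elevated, and
responders start ~0.7 log2 units higher at baseline.

## Statistics

* **DE screen**: per-gene Welch t-test on log2-CPM
  (log2((count+0.5)/(libsize+1)·1e6)), log2FC = mean(poor/non) −
  mean(better), significance |log2FC| > 2 and raw p < 0.05, BH-adjusted p
  reported alongside. This is a deliberate, documented stand-in for a
  mean-variance-moderated linear model: it exercises the thresholds, the
  contrast and the adjustment, and its gene counts at the thresholds will
  not match a moderated analysis of the same data. Library-scaling
  invariance holds up to the pseudocount (exact in the large-count limit).
* **Benjamini-Hochberg** is implemented directly (step-up with
  min-over-suffix), tested against an independent brute-force oracle and
  statsmodels.
* **Exact small-sample tests**: Mann-Whitney p is exact (via scipy's exact
  null) for min(n) ≤ 8 without ties; Wilcoxon matched-pairs drops zero
  differences and is exact for n ≤ 15 without tied |d|; Spearman p is an
  exact permutation enumeration for n ≤ 10 (matches R's exact values) and
  a t-approximation above. Tie-corrected normal approximations are used
  otherwise. All tests are two-sided at α = 0.05.
* **ROC**: AUC is the rank statistic (ties count ½), identical by algebra
  to the normalized Mann-Whitney U (asserted on every tested input). The
  95% CI is DeLong's placement-variance interval truncated to [0, 1],
  cross-checked against R pROC; the threshold table enumerates all
  observed cutoffs with sensitivity/specificity. A DeLong interval was
  chosen because the assay literature's named CI method for AUCs is not a
  reproducible algorithm; the divergence is intentional and confined to
  the interval, not the AUC.

## Numerical conventions and degenerate inputs

Closed gate intervals; m clamped at 0; A flagged NaN when b + m = 0; p63
flagged NaN when a sample has no basophils; samples without CD45⁺ events
are invalid and propagate as flagged profiles that stay unassigned;
constant vectors give NaN Spearman with a warning; zero-difference
Wilcoxon input is flagged undefined rather than given a p-value. Ties in
the rank split break by donor id so runs are reproducible.

## What the generator does and does not emulate

It reproduces the compositional structure the pipeline depends on
(population mixture, marker separation, scatter displacement,
activation/blockade arithmetic, NB counts, Ct censoring) with calibrated
effect sizes. It does not model compensation/spillover, batch or
instrument drift, inter-donor variability in the altered-scatter shares,
basophil-releasability phenotypes (every donor reactive by construction
under default settings), doublet substructure, or biological correlation
among background genes. Passing tests therefore demonstrate correctness of
the analytical chain under the stated statistical model, not performance
on real instrument data — in particular, real assays need sample-specific
gate placement, and fold-change noise will be larger when acquisition
depth is limited.

## Problem sizes used by the test suite and acceptance script

Unit tests run reduced cohorts (≤ 5 donors, 10–60k events). The
acceptance suite runs: gating recovery on 20 cohorts × 4 donors at 50k
events with pooled-count z-statistics (|z| < 3); latent-response recovery
on 20 cohorts of n = 22 at the default 800k events; bimodal rank-split
recovery on two 100-donor cohorts; 100-instance enumeration oracles per
exact test; 200-replicate calibration/power Monte Carlo at n = 19. The
acceptance script simulates one discovery-sized cohort (n = 6) and nine
validation-sized replicate cohorts (n = 22) at default depth and reports
medians of the biomarker statistics across replicates.
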