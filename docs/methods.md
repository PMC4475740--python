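# Methods

## Analysis model

Functional connectivity is edge-wise Pearson correlation of conditioned
regional time series, carried through Fisher's r-to-z transform
z = atanh(r), whose sampling distribution is approximately normal with
variance ≈ 1/(T−3) for serially independent data. All statistics operate on
the N(N−1)/2 upper-triangle edges; the diagonal is stored as 0 and excluded
everywhere. With the bundled 90-region atlas that is 4005 edges per subject.

Group-altered edges are defined by a dual criterion between one control and
one patient group:

- **(a) within-group existence** — one-sample two-tailed t-test of mean z
  against zero, Bonferroni-corrected with m = 4005 within each group
  separately; the edge passes if either group rejects. This excludes edges
  whose apparent group difference sits on connectivity indistinguishable
  from noise in both groups. "At least one group" is taken over the two
  groups being compared.
- **(b) between-group difference** — two-sample two-tailed t-test per edge,
  Benjamini–Hochberg FDR at q = 0.05 over all 4005 p-values.

The two-sample test defaults to the classical pooled-variance Student's t
(df = nA + nB − 2), the convention of the era's neuroimaging toolchains;
Welch's form is a config switch (`equal_var=False`). The same machinery
serves NC↔MCI, MCI↔AD, and NC↔AD. Direction labels come from signed group
mean z even where |z| is used for display. Degenerate zero-variance edges
never abort a run: they receive limit p-values (0 for a nonzero mean, 1
otherwise) and a log entry.

Mean connectivity strength per subject is the mean over the 4005 |z| values
(Fig-2-style "mean absolute z"); a signed variant exists because it is not
obvious which enters a global group comparison, and the default is
documented here rather than hidden. The group comparison is a one-way ANOVA
(df1 = k−1, df2 = N−k; 27/27/35 ⇒ F(2, 86)) with pairwise two-sample t post
hocs. A published post hoc of this design reports F with 52 error df where
the two-group arithmetic gives 35+27−2 = 60; the discrepancy (possibly
covariate adjustment or subsampling in the original toolkit) is noted here
and not reproduced.

Cognition: for each altered edge, Pearson r between subject z and MMSE over
MCI, AD, and pooled MCI+AD subjects (pooled = pooled observations, never an
average of per-group r), two-tailed p at uncorrected 0.05 — deliberately
exploratory, and the report header says so. MMSE enters as the raw integer
score; z (not raw r) is the correlated strength, with raw r available via
the stack if wanted.

## Signal conditioning

Order is fixed: nuisance regression, then temporal filtering. The design
matrix holds an intercept, a linear drift term, six rigid-body motion
parameters, and mean white-matter and CSF signals (10 columns); with no
nuisance set available (synthetic regional data) it degrades to
intercept + drift, and the degradation is logged. The intercept is included
even though only drift is conventionally listed, because the projection is
otherwise ill-posed; residuals are mean-zero and exactly orthogonal to every
regressor, making the operation idempotent. Global-signal regression is
deliberately absent. The filter is a 2nd-order Butterworth band-pass
(0.01–0.08 Hz) run forward-backward (`sosfiltfilt`, reflective padding):
zero phase, ≈ unit gain mid-band (a 0.04 Hz probe passes within 5%), strong
stop-band attenuation (a 0.2 Hz probe retains < 10% amplitude, measured
< 2%). The filter family and the stage order are package conventions — the
upstream description names only the band — and a regression test pins the
order so it cannot drift silently.

Regional extraction averages a 4D image over voxels per integer label, in
atlas order; label codes absent from the atlas are ignored with a warning
(background 0 always), while an atlas region with zero voxels is an error.

## Synthetic cohort generator

The generator emulates the empirical regularities the analysis assumes, not
BOLD physiology:

| parameter | default | meaning |
|---|---|---|
| base_correlation | 0.10 | generic edge background |
| homologue_correlation | 0.60 | interhemispheric homologous pairs |
| intralobe_correlation | 0.30 | same-lobe pairs |
| affected_correlation | 0.60 | planted long-distance edges, NC level |
| effect sizes | 0.15 (MCI), 0.30 (AD) | subtraction at planted edges |
| strength_jitter_sd | 0.10 | per-subject perturbation of the planted level |
| ar_coefficient | 0.40 | shared AR(1) coefficient |
| T, TR | 200, 2 s | a 6 min 40 s acquisition |
| group sizes | 27 NC / 27 MCI / 35 AD | study-sized cohort |
| MMSE model | intercepts 22.6/22.5/17.0, slope 10, noise sd 2 | score = round(intercept + 10·strength + ε), clamped to [0, 30] |

The effect sizes are package conventions (no empirical effect estimates
exist for these edges); group MMSE means come out ≈ 28.6 / 27.0 / 20.0. The
per-subject jitter, shared across a subject's planted edges, is what makes
"connectivity strength" a subject-level latent trait: it feeds both the
subject's target matrix and the MMSE model, so the strength–cognition
correlation is a real population quantity (≈ 0.4 within patients after
sampling attenuation) rather than an artifact of group separation alone.

Temporal model: stationary AR(1), x_t = φ x_{t−1} + √(1−φ²) L ε_t with
L Lᵀ the target correlation matrix and x_0 drawn from the stationary law, so
the lag-0 cross-correlation equals the target exactly for any shared
φ ∈ [0, 1). Autocorrelation (and the band-pass) inflate the variance of
sample correlations relative to the 1/(T−3) baseline; the between-subject
t-tests absorb this because they estimate variance across subjects.

Target matrices built from the rules above need not be positive definite
(sparse +0.5 bumps at planted edges can push the smallest eigenvalue well
below zero). Repair clips eigenvalues from below at ε = 1e−6 and
renormalizes the diagonal, iterating to convergence. The repair *shrinks*
strongly perturbed entries — the NC planted level 0.60 realizes near 0.53 —
so the recorded ground truth stores the realized post-repair per-edge
targets (what sample correlations actually converge to) alongside the
nominal levels. Recovery tests compare against the realized values.

Randomness: one integer seed feeds `SeedSequence([seed, group_code, k])`,
one stream per subject, so resizing one group never reshuffles another
group's subjects.

What the generator does **not** model: hemodynamic response, physiological
noise, head motion, spatial smoothness, registration error, site effects.
Passing tests therefore demonstrate the statistical machinery (error
control, power at planted effects, bookkeeping), not robustness to real
acquisition artifacts.

## Validation design and problem sizes

- False-discovery control: 100 null cohorts (identical generative structure
  in both groups; 20 regions, 15 vs 15 subjects, T = 150). On a fully null
  cohort every selection is false, so the per-replicate FDP is the indicator
  of any selection; its mean is compared with q = 0.05 plus two Monte-Carlo
  standard errors. Typical observed values: 0.02–0.06.
- Recovery: the default 90-region cohort at study sample sizes. All 20
  planted edges are typically recovered and labeled decreased; the
  acceptance threshold is 80%.
- Group ordering: with 20 affected edges among 4005, the planted effect
  moves the whole-brain mean strength by ≈ 0.0016 z against a per-group
  standard error of ≈ 0.004 — about 0.4 SE, unresolvable in one cohort (and
  consonant with the weak, non-significant global group effect such designs
  report). The ordering is therefore asserted (i) on the planted-edge mean
  z at 2 SE in independent cohorts, and (ii) for the whole-matrix
  expectation with common-random-number paired cohorts (identical
  innovation streams across groups), a variance-reduction device that
  isolates the expected gap.
- Calibration: the pooled two-sample test on iid normal null edges rejects
  at 0.050 ± MC error (≈ 5000 edges in the acceptance script).
- Oracles: BH-FDR is cross-checked against a brute-force step-up
  enumeration (every k examined explicitly) on 1000 random p-vectors
  including tied values; Fisher z against atanh to 1e−12; both t statistics
  against hand formulas on fixed toy vectors and against scipy on random
  data.

## Numerical choices and degenerate inputs

- |r| is clipped at 1 − 1e−7 before atanh so duplicate signals stay finite;
  clips are logged.
- Correlation matrices are symmetrized and clipped to [−1, 1] post
  `corrcoef` to absorb last-ulp asymmetry; zero-variance regions are a
  named error.
- The BH implementation delegates to statsmodels' `fdr_bh`; ties share
  their fate by construction. The brute-force oracle lives only in tests.
- Text serialization uses 17 significant digits and round-trip float
  parsing, so write→read is bit-exact; identical config + seed gives
  byte-identical artifacts.
- The bundled atlas uses a conventional six-lobe grouping (frontal, limbic,
  occipital, parietal, subcortical, temporal); lobe vocabulary is open and
  read from the atlas file, so alternative parcellations and lobe
  assignments are a user-supplied table away.

## Known limitations

- Slice timing, realignment, spatial normalization and reslicing are out of
  scope: inputs must already be in atlas space (tables, or label-aligned
  images).
- No partial correlation, coherence, sliding-window connectivity, or
  graph-theoretic metrics; no cluster-level or permutation inference.
- The pooled-variance default assumes comparable group variances; switch to
  Welch when that is doubtful.
- MMSE correlations are uncorrected by design and should be read as
  exploratory screening, not confirmatory inference.
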