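# Methods

## Growth model and fate rule

Lesion volumes V(t) (μm³, biweekly imaging sessions) are modelled as
log2-linear in time: log2 V = a + b·t with t in weeks, fit by ordinary least
squares over uncensored sessions (≥ 3 required). r² follows the standard
definition and is set to 0 for a zero-variance response. The fate rule is
evaluated in a fixed order:

1. **regressing** — endpoint volume ≤ `endpoint_frac` (0.25) × peak volume;
   *complete* if the endpoint is below the detection floor (a censored
   endpoint counts as below floor), else *partial*;
2. **progressing** — r² > 0.5 and b > 0.1 (log2 μm³ per week);
3. **stable** — everything else.

Regression is tested before progression because the regressing category is
defined purely by endpoint/peak: a lesion that grew and then collapsed should
not be called progressing on the strength of its early fit. The published
stable criterion (r² < 0.5 *and* b < 0.1) leaves two corner regions of the
(r², b) plane unassigned when the endpoint stays above 25 % of peak; both fall
through to stable via the else branch, completing the rule without changing
any boundary. Weekly percent growth is the back-transformed slope,
(2^b − 1)·100, so a slope of 1 is a doubling (+100 %) per week. Peak is the
maximum observed volume and endpoint the last session; the endpoint/peak
ratio is capped at 1. All thresholds are constructor parameters of
`LesionFateClassifier`.

Cohort fate proportions are computed per mouse first, then averaged
unweighted across mice (SD with ddof = 1; a single mouse reports SD 0),
pooling partial and complete regression.

## Segmentation

The segmenters emulate surface detection as practised in commercial
intravital software: Gaussian smoothing at a physical scale (`smoothing_um`,
default 3 μm for the GFP channel, 10 μm for SHG), a *local* threshold
implemented as intensity minus a large-scale Gaussian background estimate
(`background_sigma_um`, default 30 μm GFP / 60 μm SHG; ≤ 0 disables the
background term and the threshold becomes absolute), 26-connected 3D
labelling (8-connected in 2D), and removal of components below `min_voxels`
(default 10). Smoothing scales are interpreted in micrometres and converted
per axis to voxel sigmas. The collagen segmenter keeps only the largest
connected component ("largest surface"). Component volume is exactly
voxel count × voxel volume; centroids are reported in μm. Components at or
above 5000 μm³ are niche-forming; the boundary value itself counts as
niche-forming (the printed rule leaves the tie open). Myeloid displacement is
total myeloid component volume inside the lesion over lesion volume, ×100,
clipped to [0, 100] with a warning, and undefined (error) for zero lesion
volume. Manual lesion outlining is replaced by ground-truth masks from the
generator or user-supplied mask files.

The exact semantics of the proprietary "smoothing" and "local threshold" are
not public; parameter values are carried over nominally and validation rests
on ground-truth recovery (flood-fill oracle equivalence; Dice = 1.0 on
noiseless phantoms when smoothing is disabled — smoothing necessarily erodes
4 μm cells relative to binary ground truth and is meant for noisy data).

## Organizational state

Four states are assigned by a deterministic cascade over segmentation-derived
features: basal fraction ≥ 0.8 → *basally confined*; else largest-component
share ≥ 0.5 of intratumoral myeloid volume with ≥ 1 niche → *confluent*; else
≥ 2 niche-forming components → *multifocal*; else *scattered*. The basal band
defaults to 15 μm (one cell diameter) above the basement membrane. The
original study scored states by eye; these thresholds are validated by exact
recovery on single-state phantoms and by the expected monotone displacement
ordering across states. All thresholds are constructor parameters.

The recruitment index is the mean GFP in a 250 μm-radius disk centred on the
(future) lesion divided by the mean over the tongue mask, computed on sum
projections; the tongue-wide normalization is the sole cross-session
intensity correction. Cluster area fraction sums 8-connected suprathreshold
components ≥ `min_area_um2` as a percent of the region area. The NADH profile
divides mean lesion NADH by the mean in an adjacent healthy-epithelium
reference per session; decline onset is the first week the ratio drops below
0.8 × its first-session baseline and stays below for ≥ 2 consecutive
sessions (both parameters configurable; the underlying observation was
reported qualitatively, so this detector is a defined operationalization).

## Transition dynamics and statistics

Transitions are consecutive-session state pairs per lesion. Conditional
frequencies are estimated per mouse (states without outgoing transitions in a
mouse are excluded from that mouse's average for that state), then averaged
unweighted across mice with the SEM of that mean; per mouse, maintenance plus
change probabilities sum to 1 exactly. A pooled estimator is available and is
what the parameter-recovery checks use.

The Cochran–Armitage trend statistic is Z = (T − E[T])/√Var T with T the
score-weighted success count and the variance conditional on the margins
(hypergeometric, including the N/(N−1) factor); two-sided p from the normal
approximation. Scores default to age-bin midpoints in weeks. An exact
conditional permutation p (full enumeration over tables with the observed
margins) is available and intended for total n ≲ 30; note the permutation
distribution is discrete, so exact and asymptotic p agree closely only away
from heavily tied tables. Z is invariant under affine score transformations,
and at K = 2 satisfies Z² = (N−1)/N × Pearson χ². Maintenance-vs-age can be
grouped by lesion age (default) or treatment week.

Group comparisons use the tie-corrected Kruskal–Wallis omnibus (statistic 0,
p = 1 by convention for all-identical data) with two-sided Mann–Whitney post
hocs, Benjamini–Hochberg adjusted by default (Holm available).

## Spatial profiling

Counts are upper-quartile normalized (per-AOI Q3 over positive counts,
rescaled by the geometric mean of Q3s) — the common default for this
platform; the original normalization is unstated. Each gene is assigned to
the AOI class (myeloid/epithelial/other) with the highest mean normalized
expression; ties break toward myeloid > epithelial > other and carry a flag.
For differential expression the published analysis used an unspecified linear
mixed model; here AOIs are aggregated to lesion-level means of
log2(normalized + 1), respecting within-lesion correlation, and lesion means
are compared per gene by Welch's t-test (a random-intercept model is the
natural extension). log2FC is clustered minus scattered; significance
requires |log2FC| > 1 and p < 0.05. At least 2 lesions per group are
required.

## Synthetic generators

The generators encode the study conditions and are the source of ground truth
for every test:

- **Trajectories.** Per mouse, Poisson lesion counts per fate (means
  3.8/1.2/0.95 — 3–5 progressing, 1–2 regressing, ~1 stable per animal,
  expected mix ≈ 64/20/16 %). Progressing lesions grow multiplicatively with
  a per-lesion weekly rate ~ N(24, 10) % (the cohort condition); regressing
  lesions grow, peak, then decay geometrically to an endpoint ≤ 25 % of peak
  (complete regressors, probability 5/11, fall below the detection floor —
  the reported split is 6 partial / 5 complete with no stated rule); stable
  lesions follow a driftless log2 random walk (sd 0.1/session). Volume noise
  is multiplicative log-normal (CV 0.1 by default): imaging gain varies
  session to session, positivity is preserved and log2 fits stay
  linear-Gaussian — the true measurement-noise model of the original data is
  unknown, so this is a stand-in. Onsets are uniform on weeks 4–12, sessions
  biweekly to week 24; observations below the detection floor (10⁴ μm³) are
  reported at the floor and flagged censored. When session noise would push a
  regressing endpoint above its target ratio, the endpoint is clamped so the
  ≤ 25 % invariant holds by construction.
- **Behavior sequences.** First-order Markov chains with per-state change
  probabilities 0.49/0.32/0.58/0.59 (basally confined / scattered /
  multifocal / confluent, the reported per-session rates); 60 % of change
  mass reverts to basally confined (the reported directional bias), the rest
  splits evenly; uniform initial state.
- **Phantoms.** 75×128×128 voxels at 2×1×1 μm (150 μm depth, 2 μm z-step —
  the acquisition geometry), flat basement membrane at 60 μm, collagen slab
  beneath, ellipsoidal lesions, spherical myeloid cells (r = 4 μm) placed per
  state with separation margins so planted objects are distinct components;
  multifocal clusters and the confluent aggregate are rendered as larger
  spheres. Ground-truth component volumes equal voxel count × voxel volume
  exactly. Optional Gaussian + scaled-Poisson noise. Not modelled: PSF,
  papillae, membrane curvature, registration artifacts — tests on phantoms
  validate the arithmetic and rules, not robustness to real microscopy.
- **Recruitment.** Background field plus Gaussian hotspots whose amplitude
  ramps linearly over the 2 weeks before each lesion's onset (the reported
  lead time) inside an elliptical tongue mask; validated against the
  closed-form disk-averaged Gaussian.
- **DSP counts.** Negative-binomial counts (mean 50, dispersion k = 2, so
  var = m + m²/k) with per-gene log-normal mean spread, per-AOI size factors
  (removed by normalization), 4-fold compartment enrichment, and planted
  clustered-vs-scattered effects on the interferon-program genes
  (Cxcl9/Cxcl10/Isg15/Irf7, up in clustered) and the lipid/remodelling genes
  (Mmp12/Apoe/Lipa, up in scattered). Gene and AOI counts (120/230/50 genes,
  24 AOIs per class at 3 per lesion) are scaled down from the full experiment
  (~20k genes, 153 AOIs) to keep simulations fast; the class structure and
  compartment proportions echo the real partition, and the default design
  (4 + 4 myeloid lesions) gives the planted |log2FC| = 2 effects ~90 % power
  under lesion-level testing.

One seed per config spawns independent substreams (`numpy` SeedSequence);
all generators are bit-reproducible given (config, seed).

## Numerical conventions and limitations

OLS via closed-form least squares; bisections to 1e-6–1e-7 on decision
boundaries; component labelling uses full 26/8-connectivity structuring
elements; saturated (constant positive) volumes return a single component
with a warning; empty inputs return empty tables rather than errors where a
volume can legitimately contain nothing. The pipeline analyses given masks
and volumes — it does not register sessions, model optics, or replicate the
proprietary segmentation bit-for-bit, and the state-classifier thresholds,
NADH detector and DE model are defined operationalizations of analyses the
original study performed qualitatively or left unspecified.
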