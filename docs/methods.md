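# Methods

## Motif counting and enrichment

Hotspot occurrences are counted by sliding a window over the forward
strand and matching against an explicit word list. Both built-in lists
(the 8 WRC/GYW trimers and the 4 WGCW tetramers) are closed under reverse
complement, so forward-strand counting covers both DNA strands; this is a
package invariant, property-tested against an independent regex-lookahead
oracle. All overlapping occurrences count — this is what makes WGCW, a
tetramer containing hotspots on both strands, meaningful. Windows
containing non-ACGT characters (e.g. N) are skipped but their positions
still contribute to region length, a conservative convention for partially
ambiguous sequences. A window is attributed to the region containing its
start; since regions are counted as extracted segments, windows spanning a
region boundary are not counted at all — boundary windows are rare
relative to segment lengths and this keeps per-region counts independent
of neighboring regions.

The species-level enrichment statistic averages per-sequence region
indices across sequences, then takes mean(CDR1, CDR2)/mean(FR1, FR2, FR3).
Whether one should average per-sequence indices or pool counts per region
is a genuinely open choice; both are implemented (`pooled=True`), with
per-sequence averaging the default because it weights sequences equally
regardless of length. CDR3 is always excluded by default: it is created by
V(D)J recombination and carries no germline hotspot signal. If the FR mean
index is zero the ratio is reported as undefined (`None`) rather than
infinite.

## Kinetics, binding, and derived comparisons

Velocity data are fitted to v = Et·kcat·X/(Km+X) by
`scipy.optimize.least_squares` with Et held fixed, optimizing (kcat, Km)
in log space with wide box bounds (8 decades around the initial values).
Initialization: Km₀ = median substrate concentration, kcat₀ = max observed
velocity / Et. Log-space optimization is what makes the same code robust
across enzymes whose efficiencies span four orders of magnitude; the fit
is cross-checked in the test suite against an exhaustive log-grid search
(400×400) plus Nelder–Mead refinement, a deliberately different
optimization route. Non-convergence is reported in the fit object, never
silently replaced. The binding fit (Bmax, Kd) uses the same machinery.

Units: internal canonical units are nM, minutes and nM/min. Substrate
amounts given in fmol convert to nM through the reaction volume
(1 fmol/µl = 1 nM); the default volume is 10 µl, matching the deamination
assay scale, and is a spec field, not a constant. Enzyme-site
concentration Et (nM) is mass concentration (µg/ml) divided by molecular
weight; average protein masses come from Biopython's table. With these
conventions kcat is genuinely per-minute and kcat/Km per-minute-per-nM;
the efficiency is invariant under any consistent rescaling of velocity
units and Et (tested).

Derived comparisons are simple arithmetic kept as named operations so
reports are traceable: fold_change(a,b) = a/b, percent_reduction(a,b) =
100·(1 − b/a) (so percent_reduction = 100·(1 − 1/fold_change), tested),
group means are plain arithmetic means with catalytically dead enzymes
entering as exactly 0 (they cannot be fitted, but they belong in lineage
averages). Substrate-panel relative efficiencies divide each substrate's
activity by the panel mean, so they always average to exactly 1.

## Thermal / pH optimum

The optimum estimator is deliberately nonparametric: the grid value
maximizing replicate-mean activity, because experimental optima are
reported at grid resolution and a parametric peak fit would inject a curve
shape the data do not constrain. Ties resolve to the lower value (numpy's
first-argmax); a maximum on the grid edge is flagged as a boundary
optimum; a flat profile yields an undetermined optimum. Profiles are also
returned rescaled to percent of maximum mean activity, the standard
normalization for comparing enzymes of different absolute activity.

## Dilution endpoints

The endpoint of a serial-dilution detection series is the largest dilution
factor at which at least half the replicate experiments are positive (the
fraction is configurable). The fold difference between two enzymes is the
ratio of their endpoints, and is quoted with the interval
[fold/step, fold·step] where step is the local grid ratio — on a decade
grid a fold of 100 means "between 10 and 1000", which is the honest
resolution of the assay.

## Ancestral consensus and variants

Method profiles are combined as a weighted per-site average, renormalized.
"Higher emphasis on the Bayesian method" is implemented as default weights
mrbayes:raxml:protasr = 2:1:1 — the emphasis is real but unquantified in
the field, so the weights are fully configurable and a single-method run
is just weight 1 on that method. Statistical uncertainty at a site is
1 − p_max of the combined profile; a site is ambiguous when that reaches
the 0.2 threshold, and each non-consensus residue with combined posterior
≥ 0.2 becomes one single-substitution variant (multi-site combinations are
not enumerated — variants model individually synthesized mutants).
Threshold comparisons carry a 1e−9 slack so sites exactly at the threshold
up to float rounding qualify. Consensus ties (equal top probabilities)
resolve lexicographically and are logged. Sites are 1-based in all tables
and labels (F209I-style nomenclature); storage is 0-based.

## Synthetic-data generators

The generators define the conditions under which the estimators are
validated; their defaults are the experimental designs of the assays they
emulate.

* **IgV sequences.** Background bases are drawn i.i.d. at the requested GC
  content (default 0.5); spontaneous motif occurrences are removed by
  resampling individual background bases; then exactly
  round(density × region length) motif words are planted per region at
  uniformly random positions with a minimum 1-nt gap (stars-and-bars
  sampling, so all admissible placements are equally likely). The gap
  guarantees no junction window can form an unplanned motif, so realized
  per-region counts equal planted counts exactly. Consequence: on short
  regions the realized density is the rounded one (24-nt CDRs quantize
  0.06/nt to 1 motif), so density-recovery tests use region lengths for
  which density × length is an integer. Default region lengths (75, 24,
  51, 24, 114 nt for FR1, CDR1, FR2, CDR2, FR3) are typical IMGT-style
  V-gene subsegment lengths. The scrubbing step makes realized GC deviate
  slightly from the request; GC is a background parameter, not a planted
  truth.
* **Kinetics.** v = Et·kcat·X/(Km+X) times multiplicative lognormal noise
  with mean 1 and the requested CV (σ² = ln(1+CV²)); activities are
  positive, which is why noise is multiplicative. Default substrate design
  is the two-fold series 0.0625–100 fmol in 10 µl, duplicates. With that
  design and Km ≈ 50 nM the data sit below Km, so kcat and Km are
  individually weakly identified while kcat/Km — the quantity of interest —
  is well identified; the recovery tests check the ratio.
* **Thermal profiles.** A Gaussian in temperature (peak activity at t_opt,
  sd = breadth, default 8 °C) with multiplicative noise, clipped to
  [0, 100] %. The Gaussian is the simplest unimodal shape sufficient for
  optimum-recovery testing; real thermal performance curves are typically
  left-skewed, which the generator does not emulate — passing recovery
  tests show the estimator finds a planted unimodal peak under noise, not
  that real curves are Gaussian. Default grid −10…40 °C in 2 °C steps,
  duplicates, 5 % CV. At that noise level neighboring grid points within
  ~2 °C of a broad peak differ by only ~3 % activity, so single-run optima
  can land one grid step off; recovery claims are therefore grid-exact
  only in expectation, not for every seed.
* **Posteriors.** Per method, probability 1.0 on the true residue except
  at planted ambiguous sites carrying a specified two-residue split.
  Identical across methods by construction (combination is then
  idempotent, which the tests exploit).
* **Dilution series.** An enzyme with relative activity r is detectable up
  to dilution r × reference_endpoint (default 10⁴, the middle of the
  1/2–1/10⁶ assay grid); each replicate call flips with probability
  detection_noise. The step-function detection model is a simplification —
  real endpoint assays have a soft detection curve — sufficient for
  endpoint-shift arithmetic.

All generators are deterministic given spec + seed (byte-identical
serialized output, tested).

## Problem sizes

Validation runs use deliberately small problems: 3–5 sequences of
~250-nt regions for enrichment recovery, 12-point duplicate kinetics
series (50 seeded repeats for the oracle cross-check, 20 for recovery
statistics), 26-point duplicate thermal grids, and 10–40-residue
posterior profiles. These sizes already give the estimators their
asymptotic behavior (planted-truth recovery is exact or within stated
tolerances) while keeping the full suite under a minute.

## Known limitations

* No de novo CDR/FR annotation: region maps are inputs.
* The paper-style species tables (per-ortholog efficiencies, per-species
  enrichment values) require curated external sequence sets and wet-lab
  measurements; the package validates its estimators on planted synthetic
  truth instead.
* Statistical significance testing (ANOVA/Kruskal–Wallis) is out of
  scope; reports carry the quantities, not p-values.
* The noise structures of the emulated assays are not published;
  lognormal-CV (kinetics, thermal) and symmetric miscall (dilution) are
  reasonable stand-ins, not inferences from data.
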