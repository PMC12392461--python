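# Methods

## Scope and model

The package quantifies the in vitro hazard of BPA substitutes along two
axes: *how potent* a compound is relative to BPA (REP), and *how broadly
and specifically* it activates a six-endpoint assay battery (Σ-SR-Score).
Everything rests on benchmark concentrations read off fitted
concentration–response curves, normalised by cytotoxicity so that
"effects" occurring only at cell-killing concentrations are not mistaken
for specific biology.

### Concentration–response model

Effect data are fitted by ordinary least squares with a three-parameter
log-logistic curve, y = top / (1 + (EC50/c)^h), bottom fixed at 0,
parameterised in (top, log10 EC50, h) and fitted in log10-concentration
space (`scipy.optimize.curve_fit`, bounds top ∈ (0, 200], h ∈ [0.05, 10],
log10 EC50 within the tested range ± 3 decades). The free `top` is
essential: most actives in this chemical class are partial agonists
(plateaus of 12–80% of the reference compound's maximum), so a fixed-top
model would misplace every benchmark. Benchmarks are obtained by exact
inversion, c = EC50 · (top/y − 1)^(−1/h), at y = 10 on the
reference-normalised scale (EC10/IC10). The threshold refers to the
*reference* maximum, not the compound's own plateau; a compound whose
fitted plateau is ≤ 10 never crosses the threshold and is censored
(inactive), not extrapolated.

Benchmark standard errors come from first-order (delta-method)
propagation of the fit covariance through the inversion formula. On
simulated data these SEs are well calibrated (median standardised error
≈ 0.8, >90% of errors within 3 SE; see the test suite).

The oxidative-stress endpoint reports an induction ratio (IR) rather than
a normalised percentage. Its benchmark EC_IR1.5 is derived from a
zero-intercept linear fit of (IR − 1) against concentration over the
low-effect region (IR ≤ 5), because the untreated control defines IR = 1
exactly and the assay's informative range is the initial linear rise;
EC_IR1.5 = 0.5/slope. A log-logistic fit can be requested instead.

Cytotoxicity masking: points at concentrations ≥ the compound's IC10 in
the matching cell line are removed before effect curves are fitted. A
censored IC10 ("> highest tested") masks nothing. If masking leaves no
points, the benchmark is censored.

### Baseline toxicity and speciation

The minimal cytotoxicity any chemical exerts by accumulating in cell
membranes is predicted from the critical membrane burden of
0.026 mol/L_membrane (uniform across chemicals and cell types) divided by
the liposome–water distribution ratio D_lipw, with optional corrections
for sorption to medium protein (D_BSAw · VF_protein) and lipid
(D_lipw · VF_lipid). Medium volume fractions default to zero (the
pure-membrane limit) because the medium compositions of the specific
assays are configuration, not constants; both are overridable per run.
Assay pH defaults to 7.4 (physiological). The neutral-species fraction of
mono- and diprotic acids follows Henderson–Hasselbalch speciation.
D_lipw is primarily a direct input; the helper mapping log K_ow to
log D_lipw requires explicit user-supplied coefficients (slope, intercept,
anion discount in log units) because published regressions are
class-specific and none is privileged here.

### Ratio metrics and scoring

TR, SR, REP, TK-Ratio and C_parent-Ratio are plain ratios of positive
concentrations; a censored input leaves the ratio undefined and flagged,
never zero. The SR-Score is the logistic transform 1/(1 + e^−(SR−5)).
The midpoint 5 is a fixed property of the metric, chosen so that SR = 5
scores 0.5 while SR = 1 (effect at cytotoxic concentrations) scores
≈ 0.018 and SR = 10 scores ≈ 0.993. The transform is deliberately not
clipped at 1; its asymptote is treated as rounding in reports. The
cumulative score sums SR-Scores over active endpoints only — an endpoint
is active iff an uncensored benchmark exists below the masking threshold —
so its ceiling equals the battery size (6 here).

When the experimental IC10 of the matching cell line is censored, SR
falls back to the predicted baseline IC10 and the record carries
`sr_source="baseline"`. SRs computed from the *median* IC10 across cell
lines (all the packaged summary panel carries) are labelled median-based:
they reproduce the qualitative specificity pattern but not per-cell-line
SR values, which require the per-assay cytotoxicity data.

Substitution call: a candidate whose cumulative SR-Score is ≥ the
reference compound's *and* whose cytotoxicity REP exceeds 1 is flagged
"regrettable". With scores computed from the packaged panel the flag is a
screening aid, not a regulatory conclusion.

### Oxidation ratios

TK-Ratio SEM uses first-order propagation on the linear concentration
scale, as the before/after SEs arrive on that scale; against Monte-Carlo
propagation it agrees within 10% relative for CVs up to ~10%, beyond
which the ratio distribution grows heavy-tailed and a first-order number
under-reports (a limitation inherited from the n = 2 experimental
design, not corrected here). The inconsistency flag fires when a mix
turns > 2-fold more cytotoxic while ≥ 90% of the parent remains — the
"very potent metabolite or benchmark artifact" situation; the 0.9 cut is
configurable.

### Structural grouping

ECFP4 (radius-2 Morgan) fingerprints, 1024 bits, Tanimoto distance,
agglomerative clustering with average linkage (complete and Ward
available), dendrogram cut at k = 5 groups. Bit length and linkage are
reasonable defaults rather than reproductions of any particular tool's
settings, so group boundaries for borderline members may differ between
implementations; the robust feature — the two cyclobutanediols separating
from every bisphenol-like structure — does not depend on these choices.
The packaged structures are curated by compound name; labels are
meaningful only up to permutation.

## Synthetic data

The generator emulates what the downstream statistics assume: a
log-logistic mean response over a geometric dilution series (default 12
concentrations, 2× dilution, 3 replicates) plus i.i.d. additive Gaussian
noise with SD 5 on the normalised-% scale, seeded and bit-reproducible.
Responses are left unclipped by default: truncating the noise at 0 would
bias low-concentration means upward and with them every recovered EC10
(a lognormal multiplicative option exists for CV-type noise). Oxidation
experiments perturb true before/after benchmarks with mean-one lognormal
noise so the expected ratio equals the ground-truth TK-Ratio.

What the generator does *not* emulate: assay-specific biology (receptor
kinetics, cell growth, solvent effects), plate-position effects,
heteroscedastic noise, or correlated replicates. Passing recovery tests
therefore demonstrates the correctness and calibration of the fitting and
scoring machinery, not the field performance of the assays.

A note on attainable precision: with 12 × 3 points and additive noise
SD 5, the Fisher information of the design bounds the EC10's relative SE
at roughly 0.15–0.21 for typical partial agonists (plateau 40–80,
h = 1) — the estimator here empirically sits at that bound — so the
median relative EC10 recovery error under these study conditions is
~11–15%, while plateau recovery is much tighter (± a few percentage
points). Steeper or fuller curves are recovered proportionally better.

## Problem sizes

All analyses run on the 27-compound panel; recovery suites use 50 seeded
simulated curves; Monte-Carlo SEM checks use 10⁵ draws. Each driver under
`analysis/` completes in seconds on a laptop.

## Known limitations

- Per-cell-line cytotoxicity is not part of the packaged panel, so
  printed per-cell-line SR and cumulative-score values are approximated
  by median-based counterparts (clearly labelled).
- The linear EC_IR1.5 rule assumes the low-effect region is sampled; very
  steep inducers may need the log-logistic option.
- Censored benchmarks propagate as "undefined, flagged" through every
  ratio; no imputation is attempted.
- The baseline-toxicity model covers membrane narcosis only; reactive or
  receptor-mediated cytotoxicity appears as TR > 10, not as a mechanism.
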