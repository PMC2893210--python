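# Methods

## The model

Each animal group *g* (a strain × genotype combination) is exposed to
increasing doses *d* of house-dust-mite extract (0 = PBS, 5, 25, 100 µg).
For each analyte *a* (cytokine/chemokine mRNA), every mouse yields one
PBS-normalized fold change *y*. The working model is a linear mean response

  E[y] = 1 + β·d

with the PBS level anchored at 1 by the normalization. The question the
score answers is not "how big is β" but "is there a dose response at all,
and how unambiguous is it": the evidence is the two-sided p-value of the
OLS t-test of β ≠ 0, and the composite score per group is

  S = 1 / mean(−log₁₀ p_a),  a ∈ {IL-4, IL-13, CCL7, CCL11}.

S is strictly increasing in every p: strong, consistent dose responses give
S ≪ 1, flat responses give S ≫ 1. The classification cutoff is the score of
a hypothetical group sitting exactly at the significance threshold on every
analyte, 1/(−log₁₀ α), i.e. 0.77 (2 d.p.) at α = 0.05; S below the cutoff ⇒
susceptible, above ⇒ resistant. The cutoff is analytic — it involves no
data — which is what makes the classification portable across studies.

## Stages and their conventions

**Comparative C_T quantification.** ΔC_T = mean target C_T − mean reference
C_T within a sample (replicate wells averaged first); ΔΔC_T subtracts the
calibrator ΔC_T; fold = 2^(−ΔΔC_T). The calibrator is the *mean ΔC_T of the
PBS (dose 0) samples of the same group*, so each strain is expressed
relative to its own unexposed controls and the PBS group has expected fold
1. A per-sample calibrator was rejected because group-level normalization
is the convention the downstream regression assumes. Amplification
efficiency is fixed at 2; Pfaffl-style efficiency correction and
multi-reference normalization are out of scope. The reference gene defaults
to GAPDH and is configurable.

**Slope fits.** OLS on raw dose and raw fold change (fold-change data are
conventionally log-plotted, but the slope is estimated on untransformed
values; a log-log option exists and is off by default). PBS points are
excluded by default: fold 1 at dose 0 is the normalization anchor, not a
measured response — `include_dose_zero=True` restores them. Each mouse is
one point (no within-dose averaging), so df = n − 2 reflects animals. The
p-value is two-sided for slope ≠ 0; a one-sided option exists. A
zero-residual fit reports p = 0 with a `perfect_fit` flag when the slope is
nonzero — downstream clamping absorbs it — and p = 1 when the response is
exactly constant (a constant carries no evidence of a slope). Minimum
usable design: 3 points spanning 2 distinct doses.

**Score.** p-values are clamped into [1e−300, 1] before taking logs, so a
perfect fit maps to the most-susceptible finite score rather than dividing
by infinity. If every p equals 1 the mean log is 0 and S = +∞, an
unambiguous resistant sentinel; for clustering it is replaced by
(max finite score + 1) and the replacement is logged. When all clamped
−log₁₀ p values are identical the mean is taken as that common value
directly, making replication invariance — S({p,…,p}) = S({p}) — exact in
floating point; without it the α-boundary tie (score exactly at cutoff)
can round off. Ties at the cutoff classify as resistant, the conservative
non-disease call. IFN-γ can be appended to the analyte set by flag; its
flat, Th2-atypical response only shrinks the separation between groups.
Fisher/Stouffer-style p-combination is deliberately absent: the method is
defined by this specific transform.

**Clustering.** The group scores are scalars; agglomerative clustering uses
Euclidean distance with average (UPGMA) linkage by default — on scalars the
topology is insensitive to linkage for well-separated scores. The tree is
serialized to Newick with branch lengths equal to merge-height differences.

**AHR AUC.** Trapezoidal integration of Rrs over the methacholine
concentration axis on a *linear* scale (the AUC's units,
cm H₂O/mL × mg/mL, are only meaningful linearly; a log-axis variant is not
provided because no convention fixes its units). No extrapolation below the
lowest concentration; a PBS/0 point is used if present. Group dispersion is
the n−1 SD, reported as 0 for single-mouse cells.

## The synthetic cohort generator

`simulate_responses` draws y = (1 + β·d) · 2^(σZ) (multiplicative
log-normal, default) or y = 1 + β·d + σZ (additive gaussian, used where an
exact oracle is convenient), Z ~ N(0,1) per mouse × analyte, with a 1e−6
positivity floor. `simulate_ct` re-encodes the same cohort as cycle
thresholds (target C_T = reference C_T + base ΔC_T − log₂ fold), which the
quantification stage inverts exactly in the noiseless case; per-sample
reference-C_T jitter cancels in ΔC_T by construction. `simulate_ahr`
generates Rrs = baseline + gain·c/(c + c₅₀) + noise with c₅₀ = 25 mg/mL
over 0–100 mg/mL, the gain scaled weakly by HDM dose (factor
1 + 0.005·dose) to reflect the limited dose dependence of this readout.

`reference_scenario` is the four-group reference design: a strong
responder (slopes 0.05–0.12 per µg across the Th2 analytes), a moderate
responder (~5× weaker), a small-but-nonzero responder (~15× weaker), and a
zero-slope group; IFN-γ slopes are near zero throughout. Defaults: 5 mice
per dose (a typical murine cohort) and σ = 0.35 on the log₂ scale (~27%
geometric CV, ordinary inter-mouse variability for lung qPCR panels).
These defaults were fixed at design time from the qualitative contrasts the
method is meant to resolve; with them, the pipeline labels the three
responder groups susceptible and the zero-slope group resistant, and orders
the scores strong < moderate < small, in well over 90% of simulated
cohorts.

What the generator does *not* emulate: correlation between analytes within
a mouse (each mouse × analyte draw is independent), heteroscedasticity
beyond what the multiplicative noise implies, nonlinear (saturating)
cytokine dose responses (a convex `mean_shape="power"` stress-test option
exists), litter/cage effects, and measurement failure/dropout. Passing
tests therefore demonstrate the statistical machinery under the assumed
design, not robustness to those real-data features.

## Numerical choices

* Perfect-fit detection: residual SS ≤ 1e−12 × max(1, Σy²).
* p-clamp floor 1e−300 (documented above); score +∞ sentinel only when all
  p = 1.
* CSV reading uses round-trip float parsing so read(write(x)) = x exactly;
  pipeline outputs are byte-identical across runs with identical inputs and
  configuration.
* Newick leaf labels are sanitized (spaces → underscores; Newick
  metacharacters stripped).
* Type-I calibration of the slope test was verified by simulation: under
  β = 0 with additive gaussian noise (σ = 0.25) and 5 mice per dose at
  {5, 25, 100} µg, the rejection rate at α = 0.05 over 2,000 cohorts falls
  within 0.05 ± 0.02 (see `tests/test_acceptance.py`).

## Known limitations

* OLS assumes homoscedastic errors; under the multiplicative noise model
  strong responders are heteroscedastic, so their standard errors are
  approximate (the score uses the p-values ordinally, which is forgiving,
  but the per-cell SEs should not be over-read).
* With a *truly* zero-slope group the four slope p-values are uniform, so
  that group's score is heavy-tailed above the cutoff (median ≈ 2.4 under
  the reference design). Its distance to the susceptible groups on the
  score line is therefore large and variable, and on a one-dimensional
  dendrogram it is typically the outermost leaf — score-based clustering
  conveys *which susceptible groups resemble each other* more reliably
  than it conveys adjacency of a resistant group.
* The score has no uncertainty attached; it is a point summary by design.
* One score per group assumes pooled fits over all animals; per-experiment
  scoring with averaging is not implemented.
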