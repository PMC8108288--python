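# Methods

## The ODE model of monocyte cytokine production

Six cytokines secreted by monocytes in PBMC culture are dynamical states:
TNF, IL-1α, IL-1β, IL-6, IL-10, IL-23. IFN-γ is treated purely as an
exogenous input (it is supplied as recombinant protein in the perturbation
panel and is not produced at relevant levels by the modelled compartment),
so it can source regulatory edges but has no state equation.

Each node i follows

    dC_i/dt = β_i(cond) · A_i(C̃) · R_i(C̃) − δ_i · C_i

with production β_i(cond) = β_i⁰ + β_iᴸ·1[stimulus], multiplicative
saturating modulation A_i = Π₍j→i,+₎ (1 + w_e·h(C̃_j)) and
R_i = Π₍j→i,−₎ 1/(1 + w_e·h(C̃_j)), h(C) = C/(K + C) (Hill exponent 1),
and linear decay. This functional form guarantees non-negative
trajectories (production is positive, decay linear), bounded activation
(the multiplier saturates at 1 + w), and symmetric treatment of
activation and inhibition. It is the package's declared reference form:
it realises every qualitative behaviour the analyses require —
negative feedback, essential positive drive, blockade equivalence — with
one parameter per edge.

Condition semantics: an added cytokine contributes its dose to the
effective regulator concentration C̃_j = C_j + dose; a ligand blockade, or
a receptor blockade through the receptor→ligand map (IL-1R1 → {IL-1α,
IL-1β}, IL-10R → {IL-10}, …), sets C̃_j = 0 for every target. Receptor
blockade is therefore *exactly* equivalent to simultaneously blocking all
mapped ligands, and blocking a ligand is exactly equivalent to deleting
its outgoing edges — both are tested as contracts.

Endpoints are read at the culture horizon T = 16 h. Two simulation modes
agree to ~1% for the default δ = 1/h (δ·T = 16 ≫ 1): `timecourse`
(LSODA from C(0) = added doses) and `steady_state` (damped fixed-point
iteration C ← ½C + ½·βA R/δ, relative tolerance 1e-10, capped at 5000
iterations, error carrying the last residual on failure). Steady-state
mode is the default inside model ranking for speed; dynamics-sensitive
quantities use the timecourse.

### Parameters, units, identifiability

| parameter | unit | default | role |
|---|---|---|---|
| β_i⁰ | pg/mL/h | fit (bounds 10⁻²–10⁴) | unstimulated production |
| β_iᴸ | pg/mL/h | fit (bounds 10⁻²–10⁵) | stimulus-induced production |
| δ_i | 1/h | fixed 1.0 | decay/dilution |
| w_e | — | fit (bounds 0–50) | edge strength |
| K | pg/mL | fixed 100 | shared half-saturation |
| T | h | 16 | culture horizon |
| ε | pg/mL | 1 | detection floor before log10 |

Only β/δ is identifiable from endpoint-only concentrations, so δ is fixed
at 1/h and β carries the scale; K is weakly identified from a single
non-saturating dose level and is fixed by default (`fit_half_saturation`
frees it). The free-parameter count k used by AIC is 2·(number of nodes)
plus the number of edges (+1 if K is fitted).

### Fitting

Observed panels are reduced to donor-averaged condition profiles
(geometric mean across donors after flooring at ε — the noise model is
multiplicative, so the geometric mean is the natural location estimate).
The objective is Σ [log10(obs + ε) − log10(sim + ε)]² over (condition,
analyte). Optimisation is bounded least squares (trust-region reflective)
from multiple starts: the first start is a *collocation* estimate — each
node's parameters are fitted separately with its regulators held at their
observed concentrations, a separable problem whose optimum coincides with
the global one on noiseless data — and the remainder are Latin-hypercube
draws (default 16 restarts for standalone fits; model ranking uses the
collocation start plus polish, which suffices at desk scale and keeps
exhaustive ranking fast). Convergence tolerances are 1e-10 on the
objective, step and gradient.

AIC uses the Gaussian profile-likelihood form n·ln(RSS/n) + 2k with RSS
floored at 1e-9 per observation. Without the floor the criterion diverges
to −∞ on noiseless synthetic data, where every superset of the true edge
set also reaches RSS ≈ 0 up to numerical precision; at the floor
(per-residual ≈ 3·10⁻⁵ log10 units, far below assay resolution) the 2k
penalty alone separates nested perfect fits. AICc is available for small
panels.

## Candidate screening, enumeration, ranking, weights, mediation

An ordered pair (j → i) is testable when the condition panel contains a
donor-paired pair of conditions differing only by addition (preferred) or
single-ligand blockade of j; the paired Wilcoxon on analyte i across that
contrast, BH-corrected across all tested pairs, decides admissibility at
FDR < 0.05. Signs follow the effect direction (+1 if adding j raises i or
blocking j lowers it). This operationalises the a-priori exclusion of
most of the configuration space: only admissible edges enter enumeration.
Note the screen intentionally admits *indirect* effects (adding IFN-γ
raises IL-23 through IL-10 suppression); distinguishing direct from
mediated influence is precisely the model-selection step's job.

The configuration space is every non-empty subset of admissible edges
(2^E − 1 without constraints; counted analytically, iterated only when E
is at most a hard cap of 24 or `max_edges` bounds the subsets). Ranking
fits every configuration and sorts by AIC; a forward-backward stepwise
search by ΔAIC is the fallback for large E. Failed fits rank last.

Edge weights of a chosen configuration are leave-one-edge-out:
w(e) = max(0, AIC(config − e, refit) − AIC(config)), normalised to sum 1
(a ΔRSS variant is selectable; a single-edge model has weight 1 by
convention). Weights are recomputed per configuration — they are a
property of the model, not of the edge.

Mediation: for a perturbation (e.g. adding IFN-γ on an LPS background),
total effect = Δ target endpoint; the direct effect repeats the
perturbation with the mediator clamped to its unperturbed endpoint (its
derivative zeroed, its value fixed in the regulator terms); mediated =
total − direct. Clamping the perturbed node itself is rejected.

## Secretome screen

Fold-change is the **mean of per-donor ratios** (test/ref, reference
floored at ε), not the ratio of mean concentrations — the two differ
strongly under donor heterogeneity, and only the former respects the
paired design. Significance is the two-sided paired Wilcoxon signed-rank
test: exact null distribution up to n = 25 without ties, normal
approximation with tie and continuity correction above; all zero
differences give p = 1 with a degeneracy flag. BH correction runs across
the analytes of one contrast (not across contrasts). An analyte passes at
fold-change ≥ 4 and adjusted p < 0.05; the gene-expression variant uses
the same logic gene-wise at fold-change ≥ 1.5.

## Single-cell signature derivation

Counts are normalised to counts-per-10k and log1p-transformed (no batch
alignment — alignment of real data is out of scope). A gene belongs to
the target condition's signature iff, against **every** other condition,
it clears a BH-adjusted two-sided rank-sum test (α = 0.05, BH across
genes within a contrast) and log2 fold-change ≥ log2(1.5) (means of
normalised expression, pseudocount 1), and is detected in ≥ 10% of
target-condition cells. These filters are a reproducible surrogate for a
partly manual curation; all thresholds are exposed.

## Tissue modules, eigengenes, partition

Module detection is a reduced WGCNA: signed adjacency ((1 + r)/2)^β with
soft power β = 6, unsigned topological-overlap dissimilarity,
average-linkage hierarchical clustering cut at a fixed height, clusters
below 30 genes left unassigned. The default cut height is 0.7: on
cohorts with realistic within-module noise the average-linkage TOM
dendrogram merges module members at heights up to ~0.5 and separates
modules above ~0.8, so the cut sits in the middle of that plateau (the
full dynamic tree cut is deliberately not reimplemented; the cut height
is configurable).

A module eigengene is the first principal component of the standardised
module submatrix, unit-norm across samples, sign-oriented to positive
mean correlation with the module's genes; it equals the
leading-eigenvector construction from the module correlation matrix
(checked to 1e-8). Module–trait association is Pearson correlation of the
eigengene with numerically coded traits, BH-corrected across module ×
trait pairs.

A signature gene "correlates" with an eigengene iff r ≥ 0.3 and
BH-adjusted p < 0.05 (BH across signature genes × 2 eigengenes),
yielding the classes inflammatory_only / both / lymphoid_only /
unassigned. The r threshold operationalises a drawn boundary on a
continuous scatter and is configurable; correlations use all samples.

## Per-gene AUPRC evaluation

Each gene is a single-feature classifier with fixed orientation (higher
expression predicts the positive class — the signature is
inflammation-induced). AUPRC is computed in the step-wise
average-precision form (no trapezoidal interpolation, which is known to
over-estimate); tied scores form blocks whose positives receive the
precision at the block end, so constant scores score exactly the
prevalence — which is also the random-classifier baseline reported
alongside. Note the *expectation* of AP under a random ranking exceeds
the prevalence by O(1/n); the baseline is the n → ∞ value. Subset
comparisons are two-sided Mann-Whitney tests on per-gene AUPRC lists
(genes are unpaired across subsets), BH-corrected.

## Synthetic generators: what they emulate, and what they do not

**Cytokine panels** — endpoint concentrations from the ground-truth ODE
model × a per-donor lognormal scale factor (σ = 0.3) shared across
conditions (this shared factor is what makes paired tests the right
analysis) × per-well lognormal measurement noise (σ = 0.25), floored at
the 1 pg/mL detection limit downstream. Defaults: 28 donors, the
16-condition panel with 10 ng/mL additions and antibody blockades. The
default ground truth is the 4-edge core — IL-10 ⊣ IL-23 (w = 8),
IL-1β → IL-23 (w = 20), IL-10 ⊣ IL-1α (w = 4), IFN-γ ⊣ IL-10 (w = 3) —
with LPS-induced production rates in the 30–800 pg/mL/h range. The
IL-1β edge is strong because IL-1 signalling is essential for IL-23
production: receptor blockade collapses rather than trims the endpoint.
The measurement-noise model (lognormal) is a package choice; assays
report concentrations spanning orders of magnitude and the analyses work
on fold-changes.

**Tissue cohorts** — log2-scale expression from two independent latent
factors (inflammatory-cytokine, lymphocyte-differentiation) with N(1,
0.2²) gene loadings over 80-gene modules, additive N(0, 0.3²) noise, 200
pure-noise genes, and 30 planted signature genes with loadings (1,0) /
(0.7,0.7) / (0,1). Strata (control, CD non-inflamed, CD inflamed; 60 /
60 / 80 samples) shift the inflammatory factor by −1 / 0 / +1.2;
diagnosis and anti-TNF non-response labels are Bernoulli draws from a
logistic link on the inflammatory factor with log-odds slopes 2.0 and
1.5. Both labels are noisy functions of the same factor — by design, so
inflammatory-tracking genes predict both tasks and lymphoid-tracking
genes neither.

**Single cells** — negative-binomial counts (dispersion θ = 2; Poisson
in the θ → ∞ limit) around cluster × gene means: 8 clusters, of which 3
are shared across conditions, 2 emerge under LPS and 3 only under
LPS + anti-IL-10R; 35 planted signature genes are elevated 12-fold in the
blockade-exclusive clusters; 250 cells per condition, 400 genes with
lognormal baseline means.

What the generators do **not** emulate: realistic gene-gene correlation
beyond the planted factors, batch and donor effects in expression data,
compositional/depth artefacts of sequencing, dropout beyond what the NB
implies, non-inflammatory confounders of anti-TNF response, and any
quantitative calibration to the real cohorts or accessions. Passing the
round-trip tests therefore shows the *methods* are correct and mutually
consistent under their stated assumptions — not that the biological
parameter values would be recovered from real tissue.

## Numerical choices and degenerate inputs

Log floor ε = 1 pg/mL shared between generator and fit; RSS floor 1e-9
per observation in AIC (above); steady-state damping 0.5; identical-
distribution genes get p = 1 without testing; constant genes are dropped
from module detection with a warning and rejected in eigengenes when the
whole module is constant; constant traits are reported as undefined
rather than zero; subsets with fewer than 2 genes are excluded from
rank-test comparisons with a warning; edge-weight normalisation of an
all-zero raw vector returns a flat profile.

## Problem sizes

Desk-scale defaults keep every stage exact rather than approximate: the
exhaustive ranking surface uses E = 8 candidate edges (255
configurations) over a 16-condition, 6-donor noiseless panel; FDR control
uses 200 replicate null cohorts of 20 donors; the deconvolution round
trip uses 390 genes × 200 samples; the signature round trip 750 cells ×
400 genes. The 2^31 − 1 configuration count is computed analytically —
enumeration at that scale is refused by design, with the greedy stepwise
search as the documented fallback for large admissible sets.

## Known limitations

The ODE functional form and its parameterisation are a declared reference
choice, not a reconstruction of unpublished equations; per-donor fitting
(rather than fitting donor-averaged profiles) is available but not
default; the WGCNA reduction uses a static tree cut; signature curation
thresholds are surrogates for partly manual rules; AUPRC is evaluated
per gene, never as composite scores; and none of the reported numbers
are estimates of the real cohorts' values — the pipeline's claims are
about method behaviour under the synthetic study conditions.
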