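# Methods

## Data model

The analysis operates on a rooted phylogeny with branch lengths (newick;
molecular trees are accepted as-is, no ultrametric assumption or rescaling)
and a species-by-trait table joined to the tips by exact label match after
trimming whitespace and mapping spaces to underscores. No fuzzy matching is
attempted; every dropped species is logged with its reason (absent from
tree, absent from table, or missing a required value), and any analysis
needs at least three complete cases. Polytomies are allowed throughout.

The phylogenetic covariance C has C[i,j] = shared root-to-MRCA path length
of tips i and j and diagonal equal to root-to-tip depths. Pagel's λ scales
only the off-diagonal entries, so C(0) is diagonal (phylogenetic
independence) and C(1) is the raw Brownian covariance. Zero-length terminal
edges would make C singular when tips are duplicated at depth; before any
inversion-bearing step they are raised to a configurable ε (default
1e-8 × tree depth) and the substitution is logged, rather than silently
reshaping the tree.

## Allometric baseline and LQ

The baseline is an ordinary least-squares fit of log10(longevity) on
log10(mass) over a reference table of non-flying placental mammals,
restricted to acceptable-quality records with medium or large sample sizes
— maximum lifespan is an order statistic, so poorly sampled records bias
it low. The packaged default coefficients (0.5609, 0.1868, n = 804) are the
published mammalian values, letting LQ be computed with no reference table
on hand. The baseline is deliberately non-phylogenetic: it is a fixed
yardstick, not an inference target.

## Squared-change parsimony

Internal-node values minimize Σₑ (x_parent − x_child)²/lenₑ (weighted,
default) or the unweighted analogue. The objective is strictly convex, so
the normal equations — a weighted graph Laplacian over internal nodes —
have a unique solution obtained by one sparse solve; no iteration, hence
bit-for-bit determinism. The weighted optimum equals the joint ML ancestral
reconstruction under Brownian motion, which the tests verify against an
independent closed-form GLS oracle on small random trees.

Origins of extreme trait values are counted on edges: a node above the
threshold whose parent is not (or the root itself, if above) roots one
origin. Counting edges rather than nodes means a paraphyletic scatter of
high-value tips yields several origins, which is the intended reading of
"evolved at least k times". The threshold is a parameter (default LQ 4.2),
not baked-in logic.

## Pagel's λ and Fritz–Purvis D

λ is estimated by maximizing the multivariate-normal likelihood with mean
μ·1 and covariance σ²C(λ), profiling μ and σ² analytically; the remaining
one-dimensional problem on [0,1] is bracketed on a 21-point grid and
refined by bounded Brent search (xatol 1e-6) — the profile can be nearly
flat, and the grid guards against stopping on a shoulder. A star tree makes
the likelihood constant in λ; the estimator returns 0 with an explicit
degeneracy warning. ML rather than REML is used throughout so that
likelihoods are comparable across fixed-effect structures in model
selection.

For a binary trait, the observed d is the sum over internal nodes of
|node − child| of nodal estimates computed in one postorder pass with each
node the unweighted mean of its children (on bifurcations this is exactly
the sister-clade difference; the form generalizes to polytomies). Branch
lengths do not enter the observed or permuted d; they do enter the
Brownian reference, which simulates Brownian liabilities on the tree and
rank-thresholds each replicate at the observed prevalence (preserving state
counts exactly). D scales d_obs between the mean permuted d (D = 1) and
the mean Brownian d (D = 0); both references default to 1000 replicates and
are driven by a mandatory seed, making every D reproducible to the last
bit.

## PGLS

For fixed λ, β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V = C(λ) via Cholesky; λ is then
profiled exactly as above. R² = 1 − RSS_gls/TSS_gls with the total sum
taken from the GLS intercept-only fit under the same C(λ̂), so R² is
internally consistent at the estimated λ. Two residual-variance conventions
coexist deliberately: the log-likelihood (and hence AICc) uses the ML
σ̂² = RSS/n, while reported standard errors use RSS/(n−k), which reduces
exactly to textbook OLS standard errors when λ = 0 on a unit-depth star
tree. Rank-deficient designs raise an error naming the collinear columns;
silent dropping is never done.

## Model selection and averaging

All subsets of the main effects are enumerated, plus each interaction in
every subset containing both its main effects (marginality). Each model is
fitted with its own profile-ML λ; the AICc parameter count is
k = coefficients + 1 (residual variance), with λ̂ *not* counted — the
convention of the comparative toolchain this analysis mirrors (caper +
MuMIn). Counting λ would shift every model's AICc by the same +1-parameter
correction term and can reorder close models; the choice is therefore
documented here prominently.

Ranking ties break deterministically (smaller k, then lexicographic term
list), weights are computed stably (min-subtracted exponentials) over the
full enumeration, and the candidate set is ΔAICc ≤ 4 by default. Averaged
coefficients are *conditional*: each variable is averaged only over
candidate models containing it, with weights renormalized within the
candidate set (a flag switches to full-enumeration weights, since the
renormalization convention is genuinely ambiguous in the literature);
importance is the sum of renormalized candidate weights of models
containing the variable; unconditional standard errors follow
Burnham–Anderson, Σ w′ₘ √(SEₘ² + (βₘ − β̄)²). Models that fail to fit
(e.g. a constant column within a stratum) are excluded from weights and
logged, never imputed.

The split analysis prunes tree and table to each level of a binary
variable (hibernation by default), drops that variable and its interactions
from the candidate list, and re-runs the dredge independently, refusing
strata too small to support the largest model (n < k_max + 2).

## Synthetic data

The generator emulates the study's inputs with known truth: pure-birth
trees (dendropy's sampler, terminal branches extended by the Exp(nλ_birth)
waiting time to the next speciation so no zero-length terminals arise,
then rescaled to unit height so variances read per unit depth); continuous
traits as MVN draws over σ²C(λ); binaries by rank-thresholded Brownian
liabilities; and a response assembled as Xβ plus a Brownian error draw.
Every generator is a pure function of (inputs, seed); per-component seeds
are spawned deterministically from the one config seed.

The shipped demo conditions (67 species, matching the real study's sample
size) place strong signal on mass (λ 0.88) and weak signal on dimorphism
(λ 0.32), mirror the study's signal range, and generate log10(longevity)
from intercept 0.70, mass 0.28, hibernation 0.05, hibernation × latitude
0.010, cave use 0.13 and dimorphism −0.8, with Brownian error σ² 0.012 at
λ 0.8 — effect sizes chosen once to produce LQ spreads, R² values (~0.6–0.9)
and candidate-set sizes of the magnitude a real bat comparative dataset
shows. What the generator does *not* emulate: realistic co-distributions of
bat life-history traits (predictors are mutually independent given the
tree), measurement error, and sampling-effort bias in maximum lifespan. A
passing calibration therefore demonstrates estimator correctness under the
stated model, not robustness to those real-data pathologies.

## Numerical and test-size choices

Cholesky factorizations back all solves; a 1e-12-scaled jitter stabilizes
simulation draws only (never fits). Likelihoods of exact fits (RSS = 0) are
clamped finite. The calibration tests use the sizes their statistics need
and nothing more: 30 random trees of 4–6 tips for the parsimony/GLS
equivalence, 200 replicates of 150-tip datasets for coefficient recovery
and coverage, 200 replicates at 200 tips for λ calibration, and 100 data
replicates × 1000 permutations at 100 tips for D calibration; the whole
suite runs in about a minute on one core.

## Known limitations

Only Brownian/λ covariance structures (no OU or early-burst); no
measurement-error model; λ confidence intervals and D p-values are not
computed (point estimates are what the downstream analysis consumes); the
D statistic's nodal estimates use the unweighted child mean, one of several
constructions in use for polytomous trees. The cave-use orientation issue
is general: binary predictors enter as 0/1 with the mapping declared
explicitly in the analysis config (`binary_codings`), never inferred from
label order, because a flipped indicator silently negates its coefficient.
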