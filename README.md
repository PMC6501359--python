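# batlife

Phylogenetic comparative analysis of longevity in bats: how many lineages
have evolved extreme, size-corrected lifespans, and which ecological and
life-history factors predict longevity once shared ancestry is accounted
for.

## What it computes

**Longevity quotient (LQ).** Maximum lifespan scales allometrically with
body mass. Against the mammalian baseline

```
log10(longevity, years) = 0.5609 + 0.1868 · log10(body mass, g)
```

(fitted to 804 non-flying placental mammals), a species' LQ is its observed
maximum lifespan divided by the lifespan predicted for its mass; LQ = 1 is
typical for size, LQ = 8 is an eightfold excess.

**Ancestral reconstruction.** LQ is reconstructed over a rooted phylogeny
by branch-length-weighted squared-change parsimony — minimizing
Σₑ (Δₑ)²/lenₑ over internal-node values, a single sparse linear solve whose
solution coincides with the joint ML ancestral states under Brownian
motion. Lineages whose reconstructed LQ crosses a threshold (default 4.2)
upward on their root edge count as independent origins of extreme
longevity.

**Phylogenetic signal.** Pagel's λ (ML, profile likelihood over the
λ-scaled Brownian covariance C(λ)) for continuous traits; the Fritz–Purvis
D statistic — the observed sum of sister-clade differences scaled between
its tip-shuffle mean (D = 1) and its Brownian-threshold mean (D = 0) — for
binary traits.

**PGLS model selection.** y = Xβ + ε with ε ~ N(0, σ²C(λ)), λ estimated by
profile ML per model. Every marginality-respecting subset of nine candidate
predictors (log₁₀ mass, |median latitude|, hibernation, hibernation ×
latitude, cave use, diet, progeny/year, log₁₀ aggregation size, sexual size
dimorphism log₂(male-TL/female-TL), data source) is fitted, ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), and the models within ΔAICc ≤ 4 are
combined by conditional model averaging with Akaike weights, unconditional
standard errors per Burnham–Anderson, and per-variable importances. The
analysis is then repeated within hibernators and non-hibernators.

A seeded synthetic-data module (pure-birth trees, Brownian traits with
tunable λ, threshold-model binaries, a longevity response with known
coefficients and phylogenetically correlated error) generates the demo
dataset and grounds every calibration test.

## Worked example

The numbered scripts under `analysis/` run the whole study on the shipped
synthetic demo (67 species, seed 42), writing tables under `results/`:

```
python analysis/01_simulate_dataset.py
python analysis/02_longevity_quotients.py
python analysis/03_ancestral_reconstruction.py
python analysis/04_phylogenetic_signal.py
python analysis/05_model_selection.py
python analysis/06_hibernation_split.py
```

Selected output (verbatim):

```
reconstructed ancestral (root) LQ: 4.121
11 independent origins of LQ > 4.2: ['node0', 'T21', 'T26', ...]

           variable       type statistic     value  n_species
         log10_mass continuous    lambda  0.883259         67
         dimorphism continuous    lambda  0.264325         67
           cave_use     binary         D -0.324991         67

640 models fitted on 67 species; 5 within 4 AICc of the best
                       variable  estimate       se  importance
                     log10_mass  0.266278 0.026444    1.000000
hibernation:abs_median_latitude  0.010688 0.001182    1.000000
                     dimorphism -0.870977 0.139513    1.000000
```

The generating truth for this dataset had a mass coefficient of 0.28, a
hibernation × latitude interaction of 0.010 and a dimorphism coefficient of
−0.8, with mass simulated at λ = 0.88 and dimorphism at λ = 0.32 — the
pipeline recovers the effects that were put in and assigns low importance
(< 0.15) to the null predictors.

The same workflow runs on real data from the command line:

```
batlife simulate --seed 42 --out results/demo      # or your own tree + CSV
batlife run --config analysis.yaml
```

where the YAML config names the newick tree, the trait CSV (`species`,
`longevity_years`, `body_mass_g`, `hibernation`, `abs_median_latitude`,
`cave_use`, `diet`, `progeny_per_year`, `aggregation_size`, `dimorphism`,
`data_source`), the output directory, thresholds, binary codings and the
seed.

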