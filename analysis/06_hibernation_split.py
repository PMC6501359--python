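"""Separate model selection within hibernators and non-hibernators, plus
the residual-longevity tables.

The hibernation-by-latitude interaction motivates splitting the data by
hibernation and re-running the all-subsets analysis in each stratum
(without hibernation or its interaction). Also writes the PGLS residuals of
log10(longevity) on log10(mass) + cave use, and on log10(mass) alone, used
for residual-longevity plots against latitude, cave use and dimorphism.
"""

from batlife.trees import read_tree, read_traits, add_log_columns, align
from batlife.modelsel import split_analysis, averaged_frame
from batlife.pgls import pgls_fit, pgls_residuals
from batlife.pipeline import DEFAULT_VARIABLES

RESPONSE = "log10_longevity"
SPLIT = "hibernation"

tree = read_tree("results/demo/tree.nwk")
traits = add_log_columns(read_traits("results/demo/traits.csv"))
tree_m, traits_m = align(tree, traits, [RESPONSE] + DEFAULT_VARIABLES)
tree_m = tree_m.with_min_terminal_length()

split_vars = [v for v in DEFAULT_VARIABLES if v != SPLIT]
out = split_analysis(tree_m, traits_m, RESPONSE, SPLIT,
                     variables_by_level={0: split_vars, 1: split_vars})

for level, name in ((1, "hibernator"), (0, "nonhibernator")):
    mset, avg, n_sp = out[level]
    mset.to_frame().to_csv(f"results/models_{name}.csv", index=False,
                           float_format="%.10g")
    averaged_frame(avg).to_csv(f"results/averaged_{name}.csv", index=False,
                               float_format="%.10g")
    print(f"{name}: {n_sp} species, {len(mset.candidates)} candidate models, "
          f"best model R2 = {mset.records[0].fit.r_squared:.2f}")
    print(averaged_frame(avg).to_string(index=False), "\n")

for predictors, name in ((["log10_mass", "cave_use"], "mass_cave"),
                         (["log10_mass"], "mass")):
    fit = pgls_fit(tree_m, traits_m, RESPONSE, predictors)
    res = pgls_residuals(fit)
    res[SPLIT] = traits_m[SPLIT].to_numpy()
    res.to_csv(f"results/residuals_{name}.csv", index=False, float_format="%.10g")
    print(f"residuals of {RESPONSE} ~ {' + '.join(predictors)}: "
          f"lambda={fit.lambda_hat:.2f}, R2={fit.r_squared:.2f}")
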