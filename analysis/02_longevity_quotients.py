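"""Longevity quotients from the allometric mammalian baseline.

Uses the published 804-species baseline log10(longevity) = 0.5609 +
0.1868 * log10(mass) to predict each species' lifespan from body mass and
writes observed/predicted ratios (LQ) to results/lq.csv. LQ = 1 is a
typical lifespan for the species' size.
"""

from batlife.allometry import DEFAULT_MODEL, predict_longevity, lq_table
from batlife.trees import read_traits

traits = read_traits("results/demo/traits.csv")
lq = lq_table(traits, DEFAULT_MODEL)
lq.to_csv("results/lq.csv", index=False, float_format="%.10g")

print(f"baseline: a={DEFAULT_MODEL.intercept}, b={DEFAULT_MODEL.slope}, "
      f"n={DEFAULT_MODEL.n_reference} reference mammals")
print(f"e.g. a 10 g mammal is predicted to live {predict_longevity(10.0):.3f} years")
print(f"LQ range {lq.LQ.min():.2f}-{lq.LQ.max():.2f}, median {lq.LQ.median():.2f}")
print(f"{(lq.LQ > 4.2).sum()} of {len(lq)} species exceed LQ 4.2")
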