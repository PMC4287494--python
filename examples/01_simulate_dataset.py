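"""Generate a synthetic areal prevalence study and inspect its structure.

Builds a 71-region lattice dataset: seven correlated covariates (ordinal
socio-economic decile plus six lifestyle proportions), Poisson case counts
from a spatial GLMM, and block-structured missingness in which the
lowest-population regions lose all survey covariates at once.
"""

import numpy as np

import spatmiss as sm

data, truth = sm.make_study_dataset(seed=1, family="poisson")

print(f"regions: {data.n_regions}, covariates: {data.n_covariates}")
print(f"population range: {data.n.min()} .. {data.n.max()}")
print(f"missing outcome counts: {int(np.isnan(data.Y).sum())} regions")
complete = (~data.mask.any(axis=1)).sum()
print(f"regions with complete covariates: {complete}")
for name in data.covariate_names:
    j = data.covariate_index(name)
    n_miss = int(data.mask[:, j].sum())
    obs = data.X[~data.mask[:, j], j]
    print(f"  {name:<10} missing {n_miss:>2}  observed mean {obs.mean():.3f} sd {obs.std():.3f}")

screen = sm.pearson_correlation_screen(data, threshold=0.2)
print(f"covariate pairs with |r| > 0.2: {screen.n_above_threshold}/{screen.n_pairs}")
print("generating SES coefficient:", truth.beta[0])
# The block missingness is monotone in population: suppressed survey cells
# come from the smallest regions, so missingness is *not* at random.
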