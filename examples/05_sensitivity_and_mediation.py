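"""Prior sensitivity grid and the SES mediation screen.

Refits the model under five prior configurations x two families and checks
that the socio-economic association survives every choice; then asks
whether any lifestyle covariate mediates the SES association (a >10%
coefficient change when added to the univariate SES model).
"""

import spatmiss as sm
from spatmiss.sensitivity import (
    PriorGridSpec,
    mediation_frame,
    mediation_screen,
    run_prior_grid,
)

data, _ = sm.make_study_dataset(seed=1, missingness=False)

grid = run_prior_grid(
    data,
    PriorGridSpec(models=(1, 3, 4), families=("poisson",),
                  iters=2000, burnin=800, chains=2, seed=1),
)
cols = ["family", "model", "beta_ses", "beta_ses_lo", "beta_ses_hi", "beta_ses_sig", "DIC"]
print(grid.table[cols].round(4).to_string(index=False))
# Concordant negative, zero-excluding SES estimates across prior choices
# mean the association is not an artefact of the prior.

records = mediation_screen(
    data, exposure="ses",
    config=sm.ModelConfig(family="poisson", imputation="none",
                          iters=2000, burnin=800, chains=2, seed=1),
)
print("\nmediation screen (change of SES coefficient when adding each covariate):")
print(mediation_frame(records).round(3).to_string(index=False))
flagged = [r.covariate for r in records if r.flagged]
print(f"potential mediators (|change| > 10%): {flagged or 'none'}")
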