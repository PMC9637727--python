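"""Predicting age from envelope spectra with an elastic net.

Simulates a 176-subject cohort whose low-sigma 0.25 Hz rhythmicity
declines with age (and a beta-band ~1 Hz rhythm that increases), then:
(1) screens features with per-bin correlations under FDR control, and
(2) fits an elastic net on 800 spectral predictors with the
maximal-variance every-8th-subject hold-out.
"""

import numpy as np

import sleepenv as se
from sleepenv.predict import build_feature_matrix

effects = tuple(
    se.CohortEffect("low_sigma", f, f, "age", -0.4) for f in (0.24, 0.25, 0.26)
) + tuple(se.CohortEffect("beta", f, f, "age", 0.4) for f in (0.98, 0.99, 1.0))
spectra, phenotypes = se.make_cohort(
    se.CohortSpec(n_subjects=176, effects=effects, seed=1)
)

X, meta = build_feature_matrix(spectra)
print(f"{X.shape[0]} subjects x {X.shape[1]} predictors "
      "(100 envelope frequencies x 8 bands)")

frame = se.phenotype_correlations(X, phenotypes, columns=("age",))
hits = frame.loc[frame.reject]
print(f"{len(hits)} features significant after FDR; strongest:")
for _, row in hits.reindex(hits.r.abs().sort_values(ascending=False).index).head(4).iterrows():
    band, freq = meta[int(row.feature)]
    print(f"  {band:9s} {freq:.2f} Hz  r = {row.r:+.2f}")

fit = se.run_prediction(X, phenotypes.age.to_numpy(), list(phenotypes.subject), seed=0)
print(f"train/validation split: {fit.meta['n_train']}/{fit.meta['n_validation']}")
print(f"elastic net validation r = {fit.validation_r:.2f}")
print("the hold-out correlation estimates how well the whole spectrum,")
print("not any single bin, carries the phenotype.")
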