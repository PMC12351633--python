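"""Predicting montage transfer from scalp-measurable anatomical features.

Generates a cohort with anatomical features (geodesic scalp perimeters from
the Nz/Iz/LPA/RPA/Cz landmarks and per-tissue volumes from the head mesh),
evaluates each subject's personalized montage on everyone else, and asks how
much of the transferred outcome is explained by anatomical differences —
pooled pairwise regression plus leave-one-subject-out prediction.
"""

import pandas as pd

from tesgroup import (
    CohortSpec,
    Montage,
    OptimizationConfig,
    feature_diffs,
    features_table,
    fit_feature_regression,
    ga_optimize,
    generate_cohort,
    loso_predict,
    nerni,
)

cohort = generate_cohort(
    CohortSpec(n_subjects=10, seed=21, surface_subdivisions=2, tet_subdivisions=2)
)
config = OptimizationConfig(ga_population=80, seed=21)
montages: dict[str, Montage] = {
    s.subject_id: ga_optimize(s, config=config).montage for s in cohort
}

features = features_table(cohort)
print("anatomical features (first rows):")
print(features[["sagittal_perimeter", "coronal_distance", "gm_vol_norm"]].head(3).round(3))

# donor -> recipient transfer outcomes with donor-minus-recipient feature diffs
pairs = []
for donor in cohort:
    diffs = feature_diffs(cohort, donor.subject_id)
    outcome = pd.Series(
        {
            s.subject_id: nerni(montages[donor.subject_id], s)
            for s in cohort
            if s.subject_id != donor.subject_id
        },
        name="nerni",
    )
    pairs.append(diffs.join(outcome))
pooled = pd.concat(pairs)

# spherical heads make many features exact functions of the four shell radii
# (e.g. sagittal == coronal), so the design is collinear: regress on
# principal components, the standard remedy
X = pooled.drop(columns="nerni")
fit = fit_feature_regression(X, pooled["nerni"], order=1, use_pca=True, pca_components=4)
print(f"\npairwise regression of transferred NERNI on feature differences "
      f"(4 PCs): R^2 = {fit.r_squared:.2f} (F-test p = {fit.f_pvalue:.1e})")

# per-donor average transferred outcome, predicted from the donor's features
response = pooled["nerni"].groupby(level=0).mean().reindex(features.index)
preds, obs, r2 = loso_predict(
    features, response.to_numpy(), order=1, use_pca=True, pca_components=4
)
print(f"leave-one-subject-out prediction of a donor's average transferred "
      f"NERNI: R^2 = {r2:.2f}")
for sid, p, o in list(zip(features.index, preds, obs))[:5]:
    print(f"  {sid}: predicted {p:.3f}, observed {o:.3f}")
print("(held-out prediction is weak at n = 10; anatomical prediction needs "
      "cohort-scale samples)")
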