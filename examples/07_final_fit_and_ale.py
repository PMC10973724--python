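"""Deployable pipeline + Accumulated Local Effects interpretation.

The deployment protocol fits the selected pipeline on a stratified 90% of
the cohort and calibrates it on the held-out 10%.  ALE curves on the
calibrated disease probability then show which glycan peaks drive risk;
age and sex should be inert on a properly matched cohort.
"""

from glycostrat import (ale_all_features, covariate_zero_check, final_fit,
                        generate_cohort, nonzero_ale_features,
                        small_search_space, strong_signal_spec)

cohort, truth = generate_cohort(strong_signal_spec(200), seed=3)
pipe = final_fit(cohort, space=small_search_space(learners=("RF", "LR")),
                 n_trials=4, seed=1)
print(f"selected pipeline: {pipe.config.learner} / scaler={pipe.config.scaler}")

feats = cohort.feature_matrix()
score = lambda Z: pipe.calibrator.predict_p_pos(pipe.raw_score(Z))  # noqa: E731

curves = ale_all_features(score, feats, n_intervals=15)
gp_curves = [c for c in curves if c.feature.startswith("GP")]
drivers = nonzero_ale_features(gp_curves, tol=0.02)
print(f"peaks with ALE amplitude > 0.02: {drivers}")
print(f"truly perturbed peaks:           {sorted(truth['class_effect'])}")

audit = covariate_zero_check(score, feats, tol=0.05)
print(audit.to_string(index=False))
print("inert age/sex ALE confirms the classifier leans on glycan changes, "
      "not on residual covariate imbalance")
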