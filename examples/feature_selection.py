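"""Feature selection: permutation importance + recursive cABC analysis.

A synthetic two-class dataset has 2 informative features among 20.  The
pipeline sets aside a stratified 20% holdout, averages cross-validated
permutation importances on the training part, runs recursive cABC on the
mean importances, and evaluates every selection level on repeated 80%
draws of the holdout (median balanced accuracy with a nonparametric 95%
CI).  A permuted-target control — the same pipeline on shuffled labels —
shows the chance level.  Scaled-down CV settings keep the demo quick.
"""

from sklearn.ensemble import RandomForestClassifier

from cabc import PipelineConfig, classification_dataset, select_features

data = classification_dataset(n_cases=100, n_features=20, n_informative=2,
                              effect_size=1.5, seed=5)
config = PipelineConfig(
    cv_splits=3, cv_repeats=3, importance_permutations=10, eval_draws=60,
    classifier_factory=lambda s: RandomForestClassifier(n_estimators=50,
                                                        random_state=s),
    seed=5)

report = select_features(data, config)
print(report.to_markdown())
print(f"\nrecommended level: {report.recommended} -> {report.final_features}")
print("the planted 'signal' features survive the recursion; the permuted-"
      "target row hovers around the 0.5 chance level")
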