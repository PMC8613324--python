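"""A small end-to-end grid experiment with best-model comparison.

Runs two selectors x two k values x two classifiers (plus the constant
baseline) under both schemes on one synthetic dataset, then reports the
study-level bias: best model by AUC-ROC under Scheme A minus best under
Scheme B, with bootstrap p-values, and the per-combination bias matrix.
"""

from cvleak import DatasetSpec, ExperimentConfig, run_experiment

config = ExperimentConfig(
    datasets=[
        DatasetSpec(n_samples=100, n_features=500, prevalence=0.5,
                    n_informative=5, effect_size=0.5, seed=1)
    ],
    selector_methods=("t_score", "mim"),
    k_grid=(8, 32),
    classifier_names=("logistic", "naive_bayes", "constant"),
    grid_overrides={"logistic": {"C": [0.1, 1.0]}},
    n_folds=10,
    seed=1,
    n_boot=500,
)
output = run_experiment(config)

name, comp = next(iter(output.comparisons.items()))
print(f"dataset {name}: {len(output.results)} grid cells evaluated")
print(f"best Scheme A AUC-ROC: {comp.best_a.auc_roc:.3f}")
print(f"best Scheme B AUC-ROC: {comp.best_b.auc_roc:.3f}")
for metric in ("auc_roc", "auc_pr", "accuracy"):
    print(f"  bias in {metric}: {comp.delta[metric]:+.3f} "
          f"(bootstrap p = {comp.p_values[metric]:.3g})")

print("\nper-combination mean bias in AUC-ROC (selector x classifier):")
for sel in output.combination_bias.index:
    for clf in output.combination_bias.columns:
        cell = output.combination_bias.loc[sel, clf]
        if cell is not None:
            print(f"  {sel:8s} x {clf:12s}: {cell['mean']:+.3f}")
print("\nInterpretation: even with some true signal present, the leaky "
      "scheme overstates the best model's performance; the constant "
      "baseline column is exactly zero because it ignores features.")
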