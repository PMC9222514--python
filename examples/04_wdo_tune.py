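"""Wind Driven Optimization of the classifier's training hyperparameters.

Tunes epochs, batch size and learning rate by minimising the classification
error rate on an internal 75/25 validation split, then retrains on all data.
"""

from osteosae import TrainConfig, WDOConfig, tune_dssae
from osteosae.synthetic import FeatureGenSpec, generate_features

X, y = generate_features(FeatureGenSpec(n_per_class=(150, 150, 150), dim=10,
                                        separation=6.0, seed=0))
best, model, result = tune_dssae(
    X, y,
    config=WDOConfig(population_size=10, iterations=10, seed=0),
    hidden_dims=(64, 32, 16, 8),
    base_train=TrainConfig(seed=0),
)

print(f"evaluations: {result.n_evaluations}")
print(f"best validation error rate: {result.best_fitness:.2f}%")
print(f"best hyperparameters: {best}")
print()
print(result.history[["iteration", "best_fitness", "mean_fitness"]].to_string(index=False))
print()
print("best_fitness is the lowest validation error seen so far (monotone");
print("non-increasing); mean_fitness tracks the whole parcel population.")
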