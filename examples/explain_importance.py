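"""Local-surrogate feature importance of a trained prioritizer.

Labels are generated from a known logistic model in which only three
features matter; after training, perturbation-based local surrogates are
fitted around 30 instances and aggregated into relative importances — the
three generating features should dominate.
"""

import numpy as np

from geneprio.models import aggregate_importance, explain, train_model
from geneprio.synthetic import simulate_labeled_features
from geneprio.types import FEATURE_NAMES

true_w = np.zeros(14)
true_w[[4, 10, 12]] = 3.0  # Nonsynonymous_snp, Expression, QTAL
X, y, _ = simulate_labeled_features(1000, true_w, seed=0)
model = train_model("lr", X, y, seed=0, fit_scaler=True)

weights = [explain(model, X[i], X, n_perturb=500, seed=i) for i in range(30)]
importance = aggregate_importance(weights)

order = np.argsort(importance)[::-1]
print("relative feature importance (max = 100%):")
for i in order[:6]:
    planted = " <- generating feature" if true_w[i] != 0 else ""
    print(f"  {FEATURE_NAMES[i]:20s} {importance[i]:6.1f}%{planted}")
print("\nThe surrogate weights recover exactly the features the labels were "
      "\ngenerated from; the rest stay near zero.")
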