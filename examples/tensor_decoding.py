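"""Kruskal-tensor regression and population decoding on planted groups.

Builds a neurons x time x conditions tensor with two disjoint planted
neuron groups, fits the rank-2 multinomial tensor regression (picking
the restart that minimizes the joint-loading penalty J), validates with
axis shuffles, and runs the group-rate LDA decoding with its controls.
"""

import numpy as np

from cuedreach.decoding import CONDITIONS, DecodeConfig, decode_accuracy
from cuedreach.tensor import (ConditionTensor, KruskalConfig, select_model,
                              validate_shuffles)

rng = np.random.default_rng(0)
N, T = 40, 50
t = 0.1 * np.arange(T)


def make_tensor(noise_rng):
    X = np.zeros((N, T, 4))  # success, failure, cued success, cued failure
    for n in range(N // 2):
        X[n, :, 0] = 2.5 * np.exp(-t / 1.2)
        X[n, :, 2] = 3.2 * np.exp(-t / 1.2)
    for n in range(N // 2, N):
        X[n, :, 1] = 2.2 * (1 - np.exp(-t))
        X[n, :, 3] = 1.8 * (1 - np.exp(-t))
    X += 0.25 * noise_rng.standard_normal(X.shape) + 1.0
    return ConditionTensor(X, tuple(f"u{i}" for i in range(N)), t)


train, test = make_tensor(rng), make_tensor(rng)
sel = select_model(train, ranks=(2,), runs_per_rank=10,
                   cfg=KruskalConfig(max_epochs=8000), seed=1)
A = sel.model.neuron_factors
print("rank-2 restarts (loss, J):")
print(sel.loss_table.round(4).to_string(index=False))
for name, rows in (("planted group 1", A[:N // 2]),
                   ("planted group 2", A[N // 2:])):
    load = rows.sum(axis=0)
    print(f"{name}: {100 * load.max() / load.sum():.0f}% of loading mass "
          "on one factor")

acc = validate_shuffles(sel.model, test, seed=2)
print("success-vs-failure test accuracy:",
      {k: round(v, 3) for k, v in acc.items()})

# simple group-rate decoding on matched planted rates
g1 = {c: 2.0 + (1.5 if "success" in c and "failure" not in c else 0.0)
      + 0.4 * rng.standard_normal((N // 2, 30)) for c in CONDITIONS}
g2 = {c: 2.0 + (1.5 if "failure" in c else 0.0)
      + 0.4 * rng.standard_normal((N // 2, 30)) for c in CONDITIONS}
cfg = DecodeConfig(n_boot=100, seed=3)
print(f"LDA 3-way accuracy (200 units): "
      f"{decode_accuracy(g1, g2, 200, cfg):.3f}; "
      f"group shuffle: "
      f"{decode_accuracy(g1, g2, 200, cfg, 'shuffle_group_identity'):.3f}; "
      f"label shuffle: "
      f"{decode_accuracy(g1, g2, 200, cfg, 'shuffle_condition_labels'):.3f}")

# Low J marks restarts whose two components load disjoint neuron groups;
# shuffling neurons or labels destroys the structure the decoders use.
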