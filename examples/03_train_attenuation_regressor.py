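"""Train the B-mode-guided attenuation regressor on a small phantom set.

Deliberately tiny (60 phantoms, a few minutes on one CPU) so it runs as a
demonstration; the acceptance protocol uses 400 phantoms and three seeds.
The printed MNAE is the mean absolute AC error as a percentage of the
1.0 dB/cm/MHz ground-truth range; the baseline always predicts the
training-set mean.
"""

from sonoac import PhantomSpec, ProbeConfig
from sonoac.network import reduced_network_config
from sonoac.pipeline import TrainConfig, build_dataset, evaluate, train

spec = PhantomSpec(grid_shape=(320, 128), cell_size=0.25)
print("simulating 60 phantoms ...")
ds = build_dataset(60, spec, ProbeConfig(), seed=3)

tcfg = TrainConfig(lr=1.5e-3, l2_weight=1e-5, batch_size=12,
                   max_epochs=60, patience=15, seed=0)
model, history = train(ds, reduced_network_config(), tcfg, verbose=False)
print(f"trained {len(history['train_l1'])} epochs, "
      f"best validation L1 {history['best_val_l1']:.3f} dB/cm/MHz")

report = evaluate(model, ds)
print(f"held-out MNAE: {report.mnae:.1f}%  "
      f"(mean-predictor baseline: {report.baseline_mnae:.1f}%)")
import numpy as np

q25, q50, q75 = np.percentile(report.per_sample_errors, [25, 50, 75])
print(f"per-sample |error| quartiles (dB/cm/MHz): {q25:.3f} / {q50:.3f} / {q75:.3f}")
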