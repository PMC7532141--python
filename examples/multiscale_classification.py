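"""Train the dense dilated-causal network on a task that needs two scales.

Each of the four classes is the sum of a short-period (12 or 20 samples) and
a long-period (160 or 240 samples) sinusoid in noise; neighbouring classes
share one of the two components, so separating all four requires features at
both scales.  A shrunk two-stage model is trained for 30 epochs and scored
on 100 held-out waveforms.
"""

import numpy as np

from chronodense import (
    ModelConfig, SynthSpec, TrainConfig, build_model, confusion_metrics, fit,
    gen_multiscale,
)

spec = SynthSpec(task="multiscale-multiclass", n_samples=400, n_classes=4,
                 sequence_length=512, noise_sigma=0.3, seed=11)
x, y = gen_multiscale(spec)
x_train, y_train, x_test, y_test = x[:300], y[:300], x[300:], y[300:]

config = ModelConfig(input_channels=1, num_classes=4,
                     blocks_per_stage=(1, 2), growth_rate=8)
model = build_model(config, seed=0)
print(f"model: {sum(len(s) for s in model.stages)} dense blocks, "
      f"{model.num_parameters()} parameters, receptive field "
      f"{model.receptive_field()} samples")

result = fit(model, (x_train, y_train), (x_test, y_test),
             TrainConfig(learning_rate=1e-3, epochs=30, batch_size=64, seed=0))
model.set_state(result.best_state)

report = confusion_metrics(y_test, model.predict_scores(x_test).argmax(axis=1), 4)
print(f"held-out accuracy: {report.accuracy:.3f}  macro f1: {report.macro_f1:.3f}")
print("confusion matrix (rows = true class):")
print(np.array2string(report.confusion))
print("Accuracy near 1.0 means the dilated stages resolved both the short "
      "and the long period; a short-context model stays near chance on the "
      "long-scale half of the label grid.")
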