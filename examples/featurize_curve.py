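"""Turn one synthetic sensor trace into the 32-parameter feature vector.

Simulates a single cancer-class response curve (15000 samples, 120 s at
125 Hz), preprocesses it, and prints every named feature: the five
characteristic-point voltages, seven slopes, four differences, seven ppm
estimates, eight statistics and the sensor/socket identifier.
"""

import numpy as np

from enose import (
    FEATURE_NAMES,
    SyntheticConfig,
    featurize,
    load_sensor_models,
    simulate_curve,
)

config = SyntheticConfig(seed=7)
rng = np.random.default_rng(7)
curve = simulate_curve(class_label=1, patient_effect=0.0, config=config, rng=rng, socket_index=3)
print(f"curve: {curve.samples.size} samples at {curve.sample_rate} Hz, sensor {curve.model_id}")

models = load_sensor_models()
vector = featurize(curve, models[curve.model_id])
for name, value in zip(FEATURE_NAMES, vector):
    print(f"  {name:>16} = {value:.6g}")
print(
    "\nVB is the smoothed, baseline-corrected peak voltage; ppm_* invert the\n"
    "sensor's power law at VB (0.0 marks gases without a usable inversion);\n"
    "the identifier encodes (sensor model, socket) as model*100 + socket."
)
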