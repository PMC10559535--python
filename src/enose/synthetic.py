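"""Synthetic acquisition generator with the cohort's redundancy structure.

Real acquisitions are voltage responses of 32 MOS sensors to the headspace
of urine samples: a clean-air baseline, a rise after gas injection, a peak
between the fixed characteristic times, then a decay.  The generator
emulates that shape with a double-exponential pulse

    v(t) = b + a * (exp(-(t - t0)/tau_d) - exp(-(t - t0)/tau_r)) / g_peak,

normalized so the pulse maximum equals the drawn amplitude ``a``.  Class
membership shifts the amplitude mean; each patient carries an additive
amplitude offset shared across all of that patient's files, which is what
makes a patient-disjoint split a meaningful leakage test.  Additive
Gaussian sample noise models acquisition noise.

The output uses exactly the acquisition CSV/JSON dialect of
:mod:`enose.curves`, at the canonical 15000 samples (120 s at 125 Hz), so
every downstream stage can be exercised without any clinical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import (
    CURVE_LENGTH,
    SAMPLE_RATE,
    Provenance,
    ResponseCurve,
    default_socket_map,
    write_acquisition,
)
from .calibration import DividerCircuit, SensorModel, load_sensor_models
from .dataset import Instance, ManifestEntry, enumerate_cohort


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design and curve-shape parameters.

    Defaults mirror the clinical acquisition design (4 containers per
    patient, 5 acquisitions per container, 120 s at 125 Hz) with a clearly
    separable class contrast: cancer curves peak ~1 V higher on average
    than benign ones against ~0.1 V of patient-to-patient spread and
    0.02 V sample noise.
    """

    n_patients_per_class: int = 20
    containers_per_patient: int = 4
    acquisitions_per_container: int = 5
    sample_rate: float = SAMPLE_RATE
    duration: float = 120.0
    baseline_volts: float = 0.5
    amplitude_mean: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 2.0})
    amplitude_jitter_sd: float = 0.05
    peak_time_mean: float = 80.0
    peak_time_sd: float = 5.0
    rise_tau: float = 12.0
    decay_tau: float = 45.0
    noise_sd: float = 0.02
    patient_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_patients_per_class,
            self.containers_per_patient,
            self.acquisitions_per_container,
        ) < 1:
            raise SyntheticError("design counts must be >= 1")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise SyntheticError("sample_rate and duration must be positive")
        if self.rise_tau <= 0 or self.decay_tau <= 0 or self.rise_tau >= self.decay_tau:
            raise SyntheticError("need 0 < rise_tau < decay_tau")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def peak_delay(self) -> float:
        """Time from injection to pulse maximum (closed form)."""
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * math.log(d / r)


def _pulse(t: np.ndarray, t0: float, cfg: SyntheticConfig) -> np.ndarray:
    """Unit-peak double-exponential pulse starting at injection time t0."""
    dt = np.clip(t - t0, 0.0, None)
    g = np.exp(-dt / cfg.decay_tau) - np.exp(-dt / cfg.rise_tau)
    tp = cfg.peak_delay
    g_peak = math.exp(-tp / cfg.decay_tau) - math.exp(-tp / cfg.rise_tau)
    out = g / g_peak
    out[t < t0] = 0.0
    return out


def simulate_curve(
    class_label: int,
    patient_effect: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    socket_index: int = 0,
    model_id: str | None = None,
    provenance: Provenance | None = None,
) -> ResponseCurve:
    """One sensor-channel trace for a patient of the given class.

    The pulse amplitude is class mean + patient effect + jitter; the peak
    time is drawn around ``peak_time_mean``; Gaussian sample noise of
    ``noise_sd`` volts is added throughout.
    """
    if class_label not in config.amplitude_mean:
        raise SyntheticError(f"no amplitude mean for class {class_label}")
    t = np.arange(config.n_samples) / config.sample_rate
    amp = config.amplitude_mean[class_label] + patient_effect
    if config.amplitude_jitter_sd > 0:
        amp += rng.normal(0.0, config.amplitude_jitter_sd)
    amp = max(amp, 0.05)
    peak_time = config.peak_time_mean
    if config.peak_time_sd > 0:
        peak_time += rng.normal(0.0, config.peak_time_sd)
    t0 = peak_time - config.peak_delay
    v = config.baseline_volts + amp * _pulse(t, t0, config)
    if config.noise_sd > 0:
        v = v + rng.normal(0.0, config.noise_sd, size=v.shape)
    socket_map = default_socket_map()
    return ResponseCurve(
        samples=v,
        sample_rate=config.sample_rate,
        socket_index=socket_index,
        model_id=model_id or socket_map[f"s{socket_index:02d}"],
        provenance=provenance,
    )


def simulate_cohort(config: SyntheticConfig, out_dir: str | Path) -> list[ManifestEntry]:
    """Write a full synthetic cohort in the acquisition dialect.

    File count = 2 * n_patients_per_class * containers * acquisitions, each
    holding 32 curves.  The per-patient amplitude offset is drawn once per
    patient and shared across all of that patient's files.  Fully seeded:
    the same config regenerates byte-identical files.
    """
    if config.n_samples != CURVE_LENGTH:
        raise SyntheticError(
            f"cohort files must hold {CURVE_LENGTH}-sample curves; "
            f"got duration*rate = {config.n_samples}"
        )
    out_dir = Path(out_dir)
    manifest = enumerate_cohort(
        out_dir,
        config.n_patients_per_class,
        config.containers_per_patient,
        config.acquisitions_per_container,
    )
    rng = np.random.default_rng(config.seed)
    patient_ids = sorted({e.patient_id for e in manifest})
    effects = {pid: rng.normal(0.0, config.patient_effect_sd) for pid in patient_ids}
    socket_map = default_socket_map()
    for entry in manifest:
        prov = Provenance(entry.patient_id, entry.container, entry.acquisition)
        traces = np.empty((CURVE_LENGTH, 32))
        for s in range(32):
            curve = simulate_curve(
                entry.label,
                effects[entry.patient_id],
                config,
                rng,
                socket_index=s,
                provenance=prov,
            )
            traces[:, s] = curve.samples
        entry.path.parent.mkdir(parents=True, exist_ok=True)
        write_acquisition(
            entry.path, traces, prov, socket_map, sample_rate=config.sample_rate
        )
    return manifest


def simulate_instances(
    config: SyntheticConfig,
    models: dict[str, SensorModel] | None = None,
    circuit: DividerCircuit = DividerCircuit(),
) -> list[Instance]:
    """In-memory shortcut: simulate the cohort and featurize every curve
    without touching disk.

    Draws from the same seeded stream in the same order as
    :func:`simulate_cohort`, so the feature tables agree with the
    file-based path up to CSV rounding.  Curves of any length are allowed
    here (the 15000-sample constraint only binds the file dialect).
    """
    from .curves import featurize

    models = models or load_sensor_models()
    manifest = enumerate_cohort(
        Path("."),
        config.n_patients_per_class,
        config.containers_per_patient,
        config.acquisitions_per_container,
    )
    rng = np.random.default_rng(config.seed)
    patient_ids = sorted({e.patient_id for e in manifest})
    effects = {pid: rng.normal(0.0, config.patient_effect_sd) for pid in patient_ids}
    instances = []
    for entry in manifest:
        prov = Provenance(entry.patient_id, entry.container, entry.acquisition)
        for s in range(32):
            curve = simulate_curve(
                entry.label, effects[entry.patient_id], config, rng,
                socket_index=s, provenance=prov,
            )
            instances.append(
                Instance(
                    features=featurize(curve, models[curve.model_id], circuit),
                    label=entry.label,
                    patient_id=entry.patient_id,
                    container=entry.container,
                    acquisition=entry.acquisition,
                    socket=s,
                )
            )
    return instances
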