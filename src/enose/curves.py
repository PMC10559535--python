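"""Response-curve processing and the 32-parameter featurization.

Each acquisition channel delivers a 15000-sample voltage trace (120 s at
125 Hz) of one MOS sensor exposed to the headspace gas of a urine sample.
The trace is smoothed, baseline-corrected, and reduced to 32 features:

* 5 characteristic-point voltages VA (t=40 s), VD (60 s), VB (curve
  maximum), VE (100 s), VC (120 s);
* 7 pairwise slopes between those points (V/s);
* 4 differences of VB against the other points (V);
* 7 gas-concentration estimates (ppm) obtained by inverting the sensor's
  power-law calibration at VB;
* 8 distribution statistics of the corrected trace;
* 1 integer identifier encoding (sensor model, socket).

The feature order is frozen (``FEATURE_NAMES``) so trained models remain
portable across dataset rebuilds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .calibration import (
    GASES,
    MODEL_IDS,
    DividerCircuit,
    SensorModel,
    resistance_from_voltage,
)

#: canonical curve length and sampling rate: 15000 points over a 120 s window
CURVE_LENGTH = 15000
SAMPLE_RATE = 125.0

#: fixed characteristic-point times (s); VB floats to the curve maximum
T_A, T_D, T_E, T_C = 40.0, 60.0, 100.0, 120.0

#: concentrations above pure gas are physically meaningless
PPM_MAX = 1e6

SLOPE_NAMES = ("slope_AB", "slope_BC", "slope_AD", "slope_DE", "slope_EC", "slope_BE", "slope_DB")
DIFF_NAMES = ("dif_BA", "dif_BC", "dif_BD", "dif_BE")
STAT_NAMES = ("p75", "std", "mode", "mean", "median", "iqr", "cv", "skewness")

FEATURE_NAMES: tuple[str, ...] = (
    ("VA", "VB", "VC", "VD", "VE")
    + SLOPE_NAMES
    + DIFF_NAMES
    + tuple(f"ppm_{g}" for g in GASES)
    + STAT_NAMES
    + ("identifier_code",)
)
assert len(FEATURE_NAMES) == 32


class CurveError(ValueError):
    """Invalid curve input or configuration."""


class Provenance(NamedTuple):
    """Where a curve came from: patient, urine container (1-4), acquisition run (1-5)."""

    patient_id: str
    container: int
    acquisition: int


@dataclass(frozen=True)
class ResponseCurve:
    """A single sensor-channel voltage trace with its provenance."""

    samples: np.ndarray
    sample_rate: float = SAMPLE_RATE
    socket_index: int = 0
    model_id: str = MODEL_IDS[0]
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise CurveError("samples must be a nonempty 1-D array")
        if self.sample_rate <= 0:
            raise CurveError("sample_rate must be positive")
        if not 0 <= self.socket_index <= 31:
            raise CurveError("socket_index must lie in [0, 31]")
        if self.model_id not in MODEL_IDS:
            raise CurveError(f"unknown sensor model {self.model_id!r}")

    @property
    def duration(self) -> float:
        """Time span covered by the samples (s): N / rate."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FilterConfig:
    """Smoothing and baseline-correction settings.

    Median window (samples, odd) knocks out single-sample spikes; the
    moving average (samples, odd) removes residual high-frequency noise;
    the offset is the mean of the first ``offset_seconds`` of the smoothed
    trace and is subtracted throughout.
    """

    median_window: int = 5
    average_window: int = 25
    offset_seconds: float = 1.0


@dataclass(frozen=True)
class CharacteristicPoints:
    """The five anchor voltages of a response curve and their times."""

    VA: float
    VD: float
    VB: float
    VE: float
    VC: float
    tB: float
    tA: float = T_A
    tD: float = T_D
    tE: float = T_E
    tC: float = T_C


def time_to_index(t: float, sample_rate: float, n: int) -> int:
    """Sample index for time ``t``, clamped so t = span maps to the last sample."""
    return min(int(round(t * sample_rate)), n - 1)


def preprocess(curve: ResponseCurve, config: FilterConfig = FilterConfig()) -> ResponseCurve:
    """Median + moving-average smoothing, then baseline (offset) subtraction.

    The offset is estimated as the mean of the first second of the smoothed
    trace, assuming the sensor sits at its clean-air baseline before gas
    injection.  Returns a new curve of identical length.
    """
    n = curve.samples.size
    if config.median_window > n or config.average_window > n:
        raise CurveError("filter window longer than curve")
    smoothed = ndimage.median_filter(curve.samples, size=config.median_window, mode="reflect")
    smoothed = ndimage.uniform_filter1d(smoothed, size=config.average_window, mode="reflect")
    n_off = max(1, min(n, int(round(config.offset_seconds * curve.sample_rate))))
    offset = float(smoothed[:n_off].mean())
    return replace(curve, samples=smoothed - offset)


def extract_points(curve: ResponseCurve) -> CharacteristicPoints:
    """Read VA/VD/VE/VC at the fixed times and VB at the global maximum.

    Ties in the maximum are broken toward the earliest time.  Requires the
    curve to span at least 120 s.
    """
    v = curve.samples
    n = v.size
    if curve.duration < T_C - 1e-9:
        raise CurveError(f"curve spans {curve.duration:.3f} s; need at least {T_C} s")
    idx = {t: time_to_index(t, curve.sample_rate, n) for t in (T_A, T_D, T_E, T_C)}
    b_idx = int(np.argmax(v))  # argmax returns the first maximum
    return CharacteristicPoints(
        VA=float(v[idx[T_A]]),
        VD=float(v[idx[T_D]]),
        VB=float(v[b_idx]),
        VE=float(v[idx[T_E]]),
        VC=float(v[idx[T_C]]),
        tB=b_idx / curve.sample_rate,
    )


def _slope(v1: float, v0: float, t1: float, t0: float, name: str) -> float:
    dt = t1 - t0
    if abs(dt) < 1e-9:
        warnings.warn(f"{name}: time base {dt:.3g} s below resolution, slope set to 0")
        return 0.0
    return (v1 - v0) / dt


def compute_slopes(p: CharacteristicPoints) -> dict[str, float]:
    """The seven pairwise slopes between characteristic points (V/s).

    Each is the finite-difference rise over its time base, e.g.
    slope_AB = (VB - VA) / (tB - tA).  A degenerate time base (|dt| < 1 ns)
    yields slope 0 with a warning rather than an infinity.
    """
    return {
        "slope_AB": _slope(p.VB, p.VA, p.tB, p.tA, "slope_AB"),
        "slope_BC": _slope(p.VC, p.VB, p.tC, p.tB, "slope_BC"),
        "slope_AD": _slope(p.VD, p.VA, p.tD, p.tA, "slope_AD"),
        "slope_DE": _slope(p.VE, p.VD, p.tE, p.tD, "slope_DE"),
        "slope_EC": _slope(p.VC, p.VE, p.tC, p.tE, "slope_EC"),
        "slope_BE": _slope(p.VE, p.VB, p.tE, p.tB, "slope_BE"),
        "slope_DB": _slope(p.VB, p.VD, p.tB, p.tD, "slope_DB"),
    }


def compute_differences(p: CharacteristicPoints) -> dict[str, float]:
    """Voltage drops from the maximum VB to each fixed point; nonnegative
    whenever VB really is the global maximum."""
    return {
        "dif_BA": p.VB - p.VA,
        "dif_BC": p.VB - p.VC,
        "dif_BD": p.VB - p.VD,
        "dif_BE": p.VB - p.VE,
    }


def compute_statistics(curve: ResponseCurve, mode_bin_width: float = 0.01) -> dict[str, float]:
    """Eight distribution statistics of the (preprocessed) trace.

    Quantiles use linear interpolation; the mode is the center of the most
    populated ``mode_bin_width``-volt histogram bin (lowest bin on ties);
    CV = std/mean guarded to 0 near zero mean; skewness is the adjusted
    Fisher-Pearson coefficient, 0 for a (near-)constant trace.
    """
    v = curve.samples
    mean = float(v.mean())
    std = float(v.std(ddof=0))
    p75, median, p25 = (float(q) for q in np.percentile(v, [75, 50, 25]))
    span = float(v.max() - v.min())
    if span < mode_bin_width:
        mode = float(v.min()) + span / 2.0
    else:
        nbins = int(np.ceil(span / mode_bin_width))
        counts, edges = np.histogram(v, bins=nbins, range=(float(v.min()), float(v.min()) + nbins * mode_bin_width))
        k = int(np.argmax(counts))  # first (lowest) bin on ties
        mode = float((edges[k] + edges[k + 1]) / 2.0)
    cv = std / mean if abs(mean) >= 1e-12 else 0.0
    skewness = float(stats.skew(v, bias=False)) if std > 1e-12 else 0.0
    return {
        "p75": p75,
        "std": std,
        "mode": mode,
        "mean": mean,
        "median": median,
        "iqr": p75 - p25,
        "cv": cv,
        "skewness": skewness,
    }


def estimate_ppm_features(
    points: CharacteristicPoints,
    model: SensorModel,
    circuit: DividerCircuit = DividerCircuit(),
) -> dict[str, float]:
    """Per-gas ppm estimates from the peak voltage VB.

    VB is converted to a resistance through the load divider, rescaled by
    the circuit's reference resistance onto the calibration tables' scale,
    and inverted through each gas's power law.  Gases without a usable
    inversion (no datasheet characterization, alpha = 0, or VB outside the
    divider's valid range) contribute a 0.0 sentinel so the feature vector
    stays numeric.  Estimates are clipped to the physical range
    [0, 1e6] ppm (a million ppm is pure gas); the clip also keeps
    near-zero exponents, whose inversion is numerically explosive, finite.
    """
    out = {}
    vb_valid = 0.0 < points.VB < circuit.supply_voltage
    rs = (
        resistance_from_voltage(points.VB, circuit) / circuit.reference_resistance
        if vb_valid
        else None
    )
    log_max = math.log(PPM_MAX)
    for gas in GASES:
        cal = model.calibrations[gas]
        if rs is None or not cal.available or cal.alpha == 0:
            out[f"ppm_{gas}"] = 0.0
            continue
        # log-space evaluation of (rs/A)**(1/alpha), clipped before exp
        log_c = (math.log(rs) - math.log(cal.A)) / cal.alpha
        out[f"ppm_{gas}"] = math.exp(min(log_c, log_max))
    return out


def encode_identifier(model_id: str, socket_index: int) -> int:
    """Deterministic integer code for a (sensor model, socket) pair.

    code = model_ordinal * 100 + socket_index; injective over the 4x32 grid.
    """
    if model_id not in MODEL_IDS:
        raise CurveError(f"unknown sensor model {model_id!r}")
    if not 0 <= socket_index <= 31:
        raise CurveError("socket_index must lie in [0, 31]")
    return MODEL_IDS.index(model_id) * 100 + socket_index


def featurize(
    curve: ResponseCurve,
    model: SensorModel,
    circuit: DividerCircuit = DividerCircuit(),
    filter_config: FilterConfig = FilterConfig(),
    preprocessed: bool = False,
) -> np.ndarray:
    """Assemble the full 32-value feature vector in ``FEATURE_NAMES`` order.

    Unless ``preprocessed`` is set, the curve is smoothed and offset-corrected
    first; points, slopes, differences, ppm estimates and statistics are all
    computed on the corrected trace.
    """
    if model.model_id != curve.model_id:
        raise CurveError(
            f"model {model.model_id} does not match curve's {curve.model_id}"
        )
    if not preprocessed:
        curve = preprocess(curve, filter_config)
    p = extract_points(curve)
    values: dict[str, float] = {"VA": p.VA, "VB": p.VB, "VC": p.VC, "VD": p.VD, "VE": p.VE}
    values.update(compute_slopes(p))
    values.update(compute_differences(p))
    values.update(estimate_ppm_features(p, model, circuit))
    values.update(compute_statistics(curve))
    values["identifier_code"] = float(encode_identifier(curve.model_id, curve.socket_index))
    vec = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, x in zip(FEATURE_NAMES, vec) if not np.isfinite(x)]
        raise CurveError(f"non-finite features {bad}")
    return vec


# --------------------------------------------------------------------------
# Acquisition file dialect: CSV trace matrix + JSON provenance sidecar
# --------------------------------------------------------------------------

SOCKET_COLUMNS = tuple(f"s{i:02d}" for i in range(32))


def default_socket_map() -> dict[str, str]:
    """Board layout: 32 sockets in four blocks of eight, one sensor model per block."""
    return {f"s{i:02d}": MODEL_IDS[i // 8] for i in range(32)}


def write_acquisition(
    path: str | Path,
    traces: np.ndarray,
    provenance: Provenance,
    socket_map: Mapping[str, str] | None = None,
    sample_rate: float = SAMPLE_RATE,
) -> None:
    """Write one acquisition: a (15000, 32) voltage matrix as CSV with header
    ``time,s00,...,s31`` plus a ``.json`` sidecar holding provenance and the
    socket-to-sensor-model map."""
    path = Path(path)
    traces = np.asarray(traces, dtype=float)
    if traces.shape != (CURVE_LENGTH, 32):
        raise CurveError(f"traces must be ({CURVE_LENGTH}, 32), got {traces.shape}")
    socket_map = dict(socket_map or default_socket_map())
    t = np.arange(CURVE_LENGTH) / sample_rate
    df = pd.DataFrame(traces, columns=list(SOCKET_COLUMNS))
    df.insert(0, "time", t)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "patient_id": provenance.patient_id,
        "container": provenance.container,
        "acquisition": provenance.acquisition,
        "sample_rate": sample_rate,
        "sockets": socket_map,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_acquisition(path: str | Path) -> list[ResponseCurve]:
    """Read one acquisition file into 32 :class:`ResponseCurve` objects.

    Validates the exact header, the 15000-row shape, and the sidecar's
    socket map before returning curves in socket order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected_cols = ["time"] + list(SOCKET_COLUMNS)
    if list(df.columns) != expected_cols:
        raise CurveError(f"{path}: bad header {list(df.columns)[:3]}...")
    if len(df) != CURVE_LENGTH:
        raise CurveError(f"{path}: expected {CURVE_LENGTH} rows, got {len(df)}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    socket_map = sidecar["sockets"]
    if set(socket_map) != set(SOCKET_COLUMNS):
        raise CurveError(f"{path}: sidecar socket map must cover s00..s31")
    prov = Provenance(sidecar["patient_id"], int(sidecar["container"]), int(sidecar["acquisition"]))
    rate = float(sidecar.get("sample_rate", SAMPLE_RATE))
    return [
        ResponseCurve(
            samples=df[col].to_numpy(),
            sample_rate=rate,
            socket_index=i,
            model_id=socket_map[col],
            provenance=prov,
        )
        for i, col in enumerate(SOCKET_COLUMNS)
    ]
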