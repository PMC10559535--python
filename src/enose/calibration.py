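"""Power-law gas calibration for Figaro MOS sensors.

A metal-oxide-semiconductor gas sensor responds to a gas concentration
``C`` (ppm) with a sensing-element resistivity

    Rs = A * C**alpha

where ``A`` and ``alpha`` are per-(sensor model, gas) constants obtained by
log-log regression of the manufacturer's sensitivity curves.  This module
houses those constants for the four Figaro models mounted on a 32-socket
e-nose board, the forward model, its inversion to ppm, refitting from
(concentration, resistivity) pairs, and the load-divider circuit that turns
a measured output voltage into a resistance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

GASES = ("methane", "isobutane", "hydrogen", "propane", "ethanol", "air", "co")
MODEL_IDS = ("TGS-2611E00", "TGS-2611C00", "TGS-2610C00", "TGS-2620")


class CalibrationError(ValueError):
    """Base class for calibration-domain errors."""


class NoCalibrationError(CalibrationError):
    """The requested (model, gas) pair has no datasheet characterization."""


class NonInvertibleError(CalibrationError):
    """alpha = 0 makes Rs independent of concentration; ppm is undefined."""


@dataclass(frozen=True)
class GasCalibration:
    """One gas's (A, alpha) pair for one sensor model.

    ``available=False`` marks gases the datasheet does not characterize;
    such entries carry no constants and every evaluation raises
    :class:`NoCalibrationError` instead of silently propagating zeros.
    """

    gas_name: str
    A: float | None = None
    alpha: float | None = None
    available: bool = True

    def __post_init__(self) -> None:
        if self.gas_name not in GASES:
            raise CalibrationError(f"unknown gas {self.gas_name!r}")
        if self.available:
            if self.A is None or self.alpha is None:
                raise CalibrationError("available calibration needs A and alpha")
            if self.A <= 0:
                raise CalibrationError("A must be strictly positive")
        elif self.A is not None or self.alpha is not None:
            raise CalibrationError("unavailable calibration must not carry constants")


@dataclass(frozen=True)
class SensorModel:
    """A Figaro sensor model with its full 7-gas calibration map."""

    model_id: str
    calibrations: Mapping[str, GasCalibration]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise CalibrationError(f"unknown sensor model {self.model_id!r}")
        if set(self.calibrations) != set(GASES):
            raise CalibrationError("calibration map must cover exactly the 7 gases")

    @property
    def ordinal(self) -> int:
        return MODEL_IDS.index(self.model_id)


@dataclass(frozen=True)
class DividerCircuit:
    """Load-resistor divider turning sensor output voltage into resistance.

    The sensing element sits in series with a load resistor ``RL`` across a
    supply ``Vcc``; the acquisition channel reads the voltage over ``RL``.
    ``reference_resistance`` rescales the ohmic result onto the dimensionless
    scale of the shipped calibration tables (the datasheet curves are
    normalized resistivities, not ohms).
    """

    supply_voltage: float = 5.0
    load_resistance: float = 10_000.0
    reference_resistance: float = 1_000.0

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0 or self.load_resistance <= 0:
            raise CalibrationError("supply voltage and load resistance must be positive")
        if self.reference_resistance <= 0:
            raise CalibrationError("reference resistance must be positive")


def resistivity_from_concentration(cal: GasCalibration, c: float) -> float:
    """Evaluate the forward power law Rs = A * c**alpha.

    Parameters
    ----------
    cal
        An available gas calibration.
    c
        Gas concentration in ppm, strictly positive.
    """
    if not cal.available:
        raise NoCalibrationError(f"no calibration for {cal.gas_name}")
    if c <= 0:
        raise CalibrationError("concentration must be strictly positive")
    return cal.A * c**cal.alpha


def concentration_from_resistivity(cal: GasCalibration, rs: float) -> float:
    """Invert the power law: c = (rs / A)**(1/alpha).

    Raises :class:`NonInvertibleError` when alpha = 0 (resistivity carries
    no concentration information, as for air on several models).
    """
    if not cal.available:
        raise NoCalibrationError(f"no calibration for {cal.gas_name}")
    if cal.alpha == 0:
        raise NonInvertibleError(f"alpha = 0 for {cal.gas_name}: Rs is constant")
    if rs <= 0:
        raise CalibrationError("resistivity must be strictly positive")
    return (rs / cal.A) ** (1.0 / cal.alpha)


def fit_power_law(
    points: Sequence[tuple[float, float]], gas_name: str = "methane"
) -> GasCalibration:
    """Fit (A, alpha) by ordinary least squares on (ln c, ln Rs).

    This is the spreadsheet-trendline regression used to digitize the
    datasheet sensitivity curves: exact on noiseless power-law data.
    """
    if len(points) < 2:
        raise CalibrationError("need at least 2 (concentration, resistivity) points")
    c = np.asarray([p[0] for p in points], dtype=float)
    rs = np.asarray([p[1] for p in points], dtype=float)
    if np.any(c <= 0) or np.any(rs <= 0):
        raise CalibrationError("concentrations and resistivities must be positive")
    slope, intercept = np.polyfit(np.log(c), np.log(rs), 1)
    return GasCalibration(gas_name=gas_name, A=float(math.exp(intercept)), alpha=float(slope))


def resistance_from_voltage(v_out: float, circuit: DividerCircuit = DividerCircuit()) -> float:
    """Sensor resistance from the divider output voltage.

    Rs = RL * (Vcc - v_out) / v_out; monotone decreasing in ``v_out``.
    """
    if not 0 < v_out < circuit.supply_voltage:
        raise CalibrationError(
            f"v_out must lie in (0, {circuit.supply_voltage}) V, got {v_out}"
        )
    return circuit.load_resistance * (circuit.supply_voltage - v_out) / v_out


def _parse_table(model_id: str, gases: Mapping[str, dict]) -> SensorModel:
    cals = {}
    for gas, entry in gases.items():
        if entry.get("available", True):
            cals[gas] = GasCalibration(gas, A=entry["A"], alpha=entry["alpha"])
        else:
            cals[gas] = GasCalibration(gas, available=False)
    return SensorModel(model_id, cals)


def load_sensor_models(path: str | None = None) -> dict[str, SensorModel]:
    """Load the calibration tables (shipped JSON resource, or an override file).

    Returns a map model_id -> :class:`SensorModel` covering all four Figaro
    models and all seven gases each.
    """
    if path is None:
        raw = json.loads(
            resources.files("enose.data").joinpath("figaro_calibrations.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {mid: _parse_table(mid, gases) for mid, gases in raw["models"].items()}
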