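"""Resistive seat-sensor transfer functions and the pressure-frame container.

The sensing element is a 32x32 flexible array of strain-gauge cells. Each
cell's resistance ``R_ij`` drops as the applied pressure rises; the readout
chain measures the voltage across an impedance-matching resistor::

    u_o = V_ref * R_ij / (R_ij + R_IM)

and pressure is recovered from the empirical calibration fit
``p = fit_a / R - fit_b``. Resistances are in kilo-ohms throughout, matching
the 200 kOhm matching resistor; pressures are in the (arbitrary) units of the
calibration fit and are clamped to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "POSTURE_CLASSES",
    "SensorSpec",
    "PressureFrame",
    "resistance_to_voltage",
    "resistance_to_pressure",
    "pressure_to_resistance",
    "voltage_to_resistance",
    "apply_collection_threshold",
]

#: Fixed posture-class order used everywhere (confusion matrices, tie-breaks).
POSTURE_CLASSES: tuple[str, ...] = ("LC", "RC", "LL", "LR", "WB", "SS")


@dataclass(frozen=True)
class SensorSpec:
    """Geometry and electrical constants of the seat-pressure array.

    Parameters
    ----------
    rows, cols
        Grid size of the sensing array (32x32 cells).
    v_ref
        Supply/reference voltage in volts.
    r_im
        Impedance-matching resistance in kilo-ohms.
    fit_a, fit_b
        Coefficients of the pressure-resistance calibration ``p = a/R - b``.
    collection_threshold
        Pressures below this value are zeroed during acquisition (suppresses
        seat-foam deformation); 0 disables the filter.
    """

    rows: int = 32
    cols: int = 32
    v_ref: float = 5.0
    r_im: float = 200.0
    fit_a: float = 1690.0
    fit_b: float = 3.379
    collection_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.v_ref <= 0:
            raise ValueError("v_ref must be positive")
        if self.r_im <= 0:
            raise ValueError("r_im must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


@dataclass
class PressureFrame:
    """One snapshot of seat-contact pressure.

    ``values`` is a non-negative ``(rows, cols)`` array in calibration-fit
    units; ``label`` (if present) is one of :data:`POSTURE_CLASSES`.
    """

    values: np.ndarray
    label: Optional[str] = None
    subject_id: Optional[str] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"frame must be 2-D, got {self.values.ndim}-D")
        if np.any(self.values < 0):
            raise ValueError("pressure values must be non-negative")
        if self.label is not None and self.label not in POSTURE_CLASSES:
            raise ValueError(f"unknown posture class {self.label!r}")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_load(self) -> float:
        """Sum of all cell pressures (proportional to sitter weight)."""
        return float(self.values.sum())


def _check_resistance(r_ij) -> np.ndarray:
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be positive")
    return r


def resistance_to_voltage(r_ij, spec: SensorSpec = SensorSpec()):
    """Readout voltage of one cell: ``V_ref * R / (R + R_IM)``.

    Strictly increasing in ``R`` and bounded in ``(0, V_ref)``; equals
    ``V_ref / 2`` at ``R = R_IM``. Accepts scalars or arrays (kOhm).
    """
    r = _check_resistance(r_ij)
    out = spec.v_ref * r / (r + spec.r_im)
    return float(out) if np.isscalar(r_ij) else out


def resistance_to_pressure(r_ij, spec: SensorSpec = SensorSpec(), clamp: bool = True):
    """Calibrated pressure of one cell: ``fit_a / R - fit_b``.

    Strictly decreasing in ``R``. The fit goes negative for very large
    resistances (unloaded cells); with ``clamp=True`` (default) those values
    are reported as 0 to honour the frame's non-negativity contract.
    """
    r = _check_resistance(r_ij)
    p = spec.fit_a / r - spec.fit_b
    if clamp:
        p = np.maximum(p, 0.0)
    return float(p) if np.isscalar(r_ij) else p


def pressure_to_resistance(p_ij, spec: SensorSpec = SensorSpec()):
    """Inverse of the calibration fit: ``R = fit_a / (p + fit_b)`` (kOhm).

    Defined for ``p > -fit_b``; the generator uses it to push synthetic
    pressures through the electrical chain.
    """
    p = np.asarray(p_ij, dtype=float)
    if np.any(p <= -spec.fit_b):
        raise ValueError(f"pressure must exceed -fit_b = {-spec.fit_b}")
    r = spec.fit_a / (p + spec.fit_b)
    return float(r) if np.isscalar(p_ij) else r


def voltage_to_resistance(u_o, spec: SensorSpec = SensorSpec()):
    """Invert the voltage divider: ``R = R_IM * u / (V_ref - u)`` (kOhm)."""
    u = np.asarray(u_o, dtype=float)
    if np.any(u <= 0) or np.any(u >= spec.v_ref):
        raise ValueError(f"voltage must lie strictly inside (0, {spec.v_ref})")
    r = spec.r_im * u / (spec.v_ref - u)
    return float(r) if np.isscalar(u_o) else r


def apply_collection_threshold(frame: PressureFrame, spec: SensorSpec = SensorSpec()) -> PressureFrame:
    """Zero out cells below ``spec.collection_threshold``; idempotent."""
    v = frame.values.copy()
    v[v < spec.collection_threshold] = 0.0
    return PressureFrame(v, label=frame.label, subject_id=frame.subject_id,
                         weight_kg=frame.weight_kg)
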