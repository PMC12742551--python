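"""Ionization-chamber stack model and synthetic measurements.

A stack of 24 small-volume (PinPoint-type) ionization chambers — 6 rows of 4
chambers on three height levels — is placed in the water phantom and reads
out absolute dose at 24 points per field.  ``planned_doses_at_chambers``
interpolates the planned grid at the chamber effective points;
``simulate_measurement`` adds the uncertainty sources that limit this kind of
measurement: volume averaging over the sensitive volume, stack positioning
error, per-chamber noise, a session background offset, calibration bias, and
optional gross human-error modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dose import DoseGrid

__all__ = [
    "ChamberSpec",
    "ICStackLayout",
    "ErrorModel",
    "MeasurementSession",
    "MeasuredSet",
    "default_stack_layout",
    "planned_doses_at_chambers",
    "simulate_measurement",
    "POINT_CHAMBER",
]

N_CHAMBERS = 24


@dataclass(frozen=True)
class ChamberSpec:
    """Dosimetric properties of one chamber.

    kQ and the air-density correction are carried for completeness; they are
    assumed exactly compensated in routine operation (readings are already in
    dose-to-water), so they only matter via the gross-error modes.
    """

    sensitive_volume_mm3: float = 30.0       # PinPoint-class volume
    half_widths_mm: tuple[float, float, float] = (1.45, 1.45, 2.5)
    effective_point_offset_mm: float = 0.0   # along A
    calibration_factor: float = 1.0          # Gy per reading unit
    kq: float = 1.026
    air_density_correction: float = 1.0

    def __post_init__(self):
        if self.calibration_factor <= 0 or self.kq <= 0:
            raise ValueError("calibration_factor and kQ must be positive")


POINT_CHAMBER = ChamberSpec(sensitive_volume_mm3=0.0,
                            half_widths_mm=(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class ICStackLayout:
    """Positions of the 24 chambers relative to the stack reference point."""

    offsets: np.ndarray            # (24, 3) mm, columns (A, B, C)
    chamber_diameter_mm: float = 5.7

    def __post_init__(self):
        object.__setattr__(self, "offsets",
                           np.asarray(self.offsets, dtype=float))
        if self.offsets.shape != (N_CHAMBERS, 3):
            raise ValueError(f"layout must contain exactly {N_CHAMBERS} chambers")
        heights = np.unique(self.offsets[:, 1])
        if len(heights) != 3:
            raise ValueError("chambers must sit on exactly three height levels")
        d = self.offsets[:, None, :] - self.offsets[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() <= self.chamber_diameter_mm:
            raise ValueError("chambers overlap: minimum separation must exceed "
                             "the chamber diameter")


@dataclass(frozen=True)
class ErrorModel:
    """Stochastic and systematic error sources of one measurement session."""

    positioning_sd: float = 0.0        # mm per axis, stack placement
    relative_noise_sd: float = 0.0     # fraction, per chamber
    background_offset: float = 0.0     # Gy, additive per session
    calibration_bias: float = 0.0      # fraction, multiplicative
    human_error_mode: str = "none"     # none | wrong_calibration | wrong_position | wrong_air_gap
    wrong_calibration_bias: float = 0.05
    wrong_position_shift_mm: tuple[float, float, float] = (0.0, 5.0, 5.0)
    wrong_air_gap_shift_mm: float = 3.0

    def __post_init__(self):
        if self.positioning_sd < 0 or self.relative_noise_sd < 0:
            raise ValueError("error standard deviations must be >= 0")
        allowed = {"none", "wrong_calibration", "wrong_position", "wrong_air_gap"}
        if self.human_error_mode not in allowed:
            raise ValueError(f"human_error_mode must be one of {sorted(allowed)}")


@dataclass(frozen=True)
class MeasurementSession:
    """Placement of the stack reference point in the phantom, plus errors."""

    placement: tuple[float, float, float]   # (A, B, C) mm
    seed: int = 0
    error_model: ErrorModel = field(default_factory=ErrorModel)


@dataclass(frozen=True)
class MeasuredSet:
    doses: np.ndarray                    # (24,) Gy
    human_error_suspected: bool = False

    def __post_init__(self):
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if self.doses.shape != (N_CHAMBERS,):
            raise ValueError(f"measured set must contain {N_CHAMBERS} doses")
        if not np.all(np.isfinite(self.doses)):
            raise ValueError("measured doses must be finite")


def default_stack_layout() -> ICStackLayout:
    """Fixed 6x4 layout on three heights.

    Rows run along A (depth) at 12 mm pitch, the four chambers of a row along
    C at 12 mm pitch; row ``i`` sits at height B = (-10, 0, +10) mm cycling
    with ``i % 3``.  Offsets are centered on the stack reference point.
    """
    rows_a = (np.arange(6) - 2.5) * 12.0
    cols_c = (np.arange(4) - 1.5) * 12.0
    heights = np.array([-10.0, 0.0, 10.0])
    offsets = np.array([
        (a, heights[i % 3], c)
        for i, a in enumerate(rows_a) for c in cols_c
    ])
    return ICStackLayout(offsets=offsets)


def _chamber_positions(layout: ICStackLayout, session: MeasurementSession,
                       spec: ChamberSpec) -> np.ndarray:
    pos = np.asarray(session.placement, dtype=float) + layout.offsets
    pos[:, 0] += spec.effective_point_offset_mm
    return pos


def _interpolator(grid: DoseGrid) -> RegularGridInterpolator:
    axes = [grid.axis_centers(i) for i in range(3)]
    return RegularGridInterpolator(axes, grid.values, method="linear",
                                   bounds_error=True)


def planned_doses_at_chambers(grid: DoseGrid, layout: ICStackLayout,
                              session: MeasurementSession,
                              spec: ChamberSpec = ChamberSpec()) -> np.ndarray:
    """Trilinear interpolation of the planned grid at each effective point."""
    interp = _interpolator(grid)
    pos = _chamber_positions(layout, session, spec)
    doses = np.empty(N_CHAMBERS)
    for i, p in enumerate(pos):
        try:
            doses[i] = interp(p)[0]
        except ValueError as exc:
            raise ValueError(
                f"chamber {i} effective point {tuple(p)} lies outside the "
                "dose grid") from exc
    return doses


# 3-point Gauss-Legendre nodes/weights on [-1, 1] per axis.
_GL_NODES = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GL_WEIGHTS = np.array([5.0, 8.0, 5.0]) / 18.0


def _volume_average(interp: RegularGridInterpolator, center: np.ndarray,
                    half_widths: tuple[float, float, float]) -> float:
    """Mean dose over the sensitive volume (box-approximated cylinder),
    by 3x3x3 Gauss-Legendre quadrature."""
    if max(half_widths) == 0.0:
        return float(interp(center)[0])
    pts = np.array([
        center + np.array([hx * _GL_NODES[i], hy * _GL_NODES[j],
                           hz * _GL_NODES[k]])
        for i in range(3) for j in range(3) for k in range(3)
        for hx, hy, hz in [half_widths]
    ])
    w = np.array([
        _GL_WEIGHTS[i] * _GL_WEIGHTS[j] * _GL_WEIGHTS[k]
        for i in range(3) for j in range(3) for k in range(3)
    ])
    return float(w @ interp(pts))


def simulate_measurement(grid: DoseGrid, layout: ICStackLayout,
                         session: MeasurementSession,
                         spec: ChamberSpec = ChamberSpec()) -> MeasuredSet:
    """Synthesize the 24 chamber readings for one field.

    measured_i = volume_avg(grid at displaced position_i)
                 * (1 + calibration_bias) * (1 + noise_i) + background_offset

    The stack displacement is one shared draw per session (the stack is
    positioned once); noise is independent per chamber.  Gross human-error
    modes override calibration or positioning.  Fully reproducible from the
    session seed.
    """
    em = session.error_model
    rng = np.random.default_rng(session.seed)
    shift = rng.normal(0.0, em.positioning_sd, size=3) if em.positioning_sd > 0 \
        else np.zeros(3)
    noise = rng.normal(0.0, em.relative_noise_sd, size=N_CHAMBERS) \
        if em.relative_noise_sd > 0 else np.zeros(N_CHAMBERS)

    bias = em.calibration_bias
    if em.human_error_mode == "wrong_calibration":
        bias += em.wrong_calibration_bias
    elif em.human_error_mode == "wrong_position":
        shift = shift + np.asarray(em.wrong_position_shift_mm)
    elif em.human_error_mode == "wrong_air_gap":
        shift = shift + np.array([em.wrong_air_gap_shift_mm, 0.0, 0.0])

    interp = _interpolator(grid)
    pos = _chamber_positions(layout, session, spec) + shift
    doses = np.empty(N_CHAMBERS)
    for i, p in enumerate(pos):
        try:
            doses[i] = _volume_average(interp, p, spec.half_widths_mm)
        except ValueError as exc:
            raise ValueError(
                f"chamber {i} displaced to {tuple(p)} falls outside the dose "
                "grid") from exc
    doses = doses * (1.0 + bias) * (1.0 + noise) + em.background_offset
    return MeasuredSet(doses=doses,
                       human_error_suspected=em.human_error_mode != "none")
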