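"""Field verification: gradient-based chamber deactivation, normalized
deviation statistics, and tolerance classification.

Per chamber the deviation is 100 * (measured - planned) / D_max, where D_max
is the maximum planned dose of the entire field grid — a single normalization
for all 24 positions.  Chambers sitting in steep dose gradients (local
gradient in mGy/mm above a fraction, default 5%, of D_max expressed in mGy)
are deactivated and excluded from the statistics.  A field passes when
|mean| <= 5%, minimum >= -7% and maximum <= +7% of D_max (boundaries
inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chambers import (ChamberSpec, ICStackLayout, MeasuredSet,
                       MeasurementSession, N_CHAMBERS,
                       planned_doses_at_chambers)
from .dose import DoseGrid

__all__ = [
    "ToleranceConfig",
    "VerificationRecord",
    "DeviationSummary",
    "VerificationResult",
    "NoEvaluableChambersError",
    "estimate_gradient",
    "select_active_chambers",
    "compute_deviation_summary",
    "classify",
    "verify_field",
    "repeat_policy",
    "RepeatPolicyConfig",
]


class NoEvaluableChambersError(RuntimeError):
    """Raised when every chamber of a field is deactivated."""


@dataclass(frozen=True)
class ToleranceConfig:
    """Institutional tolerances, in percent of D_max."""

    mean_tol: float = 5.0
    min_tol: float = -7.0
    max_tol: float = 7.0
    gradient_threshold_fraction: float = 0.05   # of D_max, per mm
    gradient_scalar: str = "norm"               # "norm" | "max_component"

    def __post_init__(self):
        if self.mean_tol <= 0:
            raise ValueError("mean_tol must be positive")
        if not (self.min_tol < 0 < self.max_tol):
            raise ValueError("need min_tol < 0 < max_tol")
        if self.gradient_threshold_fraction <= 0:
            raise ValueError("gradient_threshold_fraction must be positive")


@dataclass
class VerificationRecord:
    """Per-chamber planned/measured doses and gradients for one field."""

    planned: np.ndarray       # (24,) Gy
    measured: np.ndarray      # (24,) Gy
    gradients: np.ndarray     # (24,) mGy/mm
    d_max: float              # Gy, whole-field maximum
    active: np.ndarray | None = None   # (24,) bool, set by activation step

    def __post_init__(self):
        self.planned = np.asarray(self.planned, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        for arr in (self.planned, self.measured, self.gradients):
            if arr.shape != (N_CHAMBERS,):
                raise ValueError(f"expected {N_CHAMBERS} chamber entries")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


@dataclass(frozen=True)
class DeviationSummary:
    """Deviation statistics over the activated chambers, in % of D_max."""

    deviations: np.ndarray    # (24,) % of D_max, all chambers
    active: np.ndarray        # (24,) bool
    mean: float
    sd: float
    min: float
    max: float
    n_active: int


@dataclass(frozen=True)
class VerificationResult:
    summary: DeviationSummary
    passed: bool
    violated_criteria: tuple[str, ...]
    chamber_classes: tuple[str, ...]   # per chamber


def estimate_gradient(grid: DoseGrid, position) -> float:
    """Local dose gradient (mGy/mm) from the six neighboring voxels.

    Central differences along each axis using the +/-1 voxel neighbors of the
    voxel enclosing ``position``; the scalar is the Euclidean norm of the
    three components (or the maximum component, via ToleranceConfig).
    """
    return _gradient(grid, position, scalar="norm")


def _gradient(grid: DoseGrid, position, scalar: str = "norm") -> float:
    position = np.asarray(position, dtype=float)
    idx = np.floor((position - np.asarray(grid.origin)) / grid.spacing).astype(int)
    shape = grid.values.shape
    for ax in range(3):
        if idx[ax] - 1 < 0 or idx[ax] + 1 >= shape[ax]:
            raise ValueError(
                f"position {tuple(position)} has no +/-1 voxel neighbor along "
                f"axis {ax}; deactivate the chamber or pad the grid")
    i, j, k = idx
    v = grid.values
    comps = np.array([
        v[i + 1, j, k] - v[i - 1, j, k],
        v[i, j + 1, k] - v[i, j - 1, k],
        v[i, j, k + 1] - v[i, j, k - 1],
    ]) / (2.0 * grid.spacing)            # Gy/mm
    comps *= 1000.0                      # mGy/mm
    if scalar == "max_component":
        return float(np.abs(comps).max())
    return float(np.sqrt((comps ** 2).sum()))


def select_active_chambers(record: VerificationRecord,
                           tol: ToleranceConfig) -> np.ndarray:
    """Deactivate chambers whose gradient exceeds the threshold.

    Threshold = gradient_threshold_fraction * D_max, with D_max expressed in
    mGy so the comparison is mGy/mm against mGy per mm.  Exact equality keeps
    the chamber active.
    """
    if record.d_max <= 0:
        raise ValueError("d_max must be positive")
    threshold = tol.gradient_threshold_fraction * record.d_max * 1000.0
    active = record.gradients <= threshold
    record.active = active
    return active


def compute_deviation_summary(record: VerificationRecord) -> DeviationSummary:
    """Normalized deviations and their statistics over active chambers.

    deviation_i = 100 * (measured_i - planned_i) / D_max.  The SD is the
    sample standard deviation (n-1), reported as 0 for a single active
    chamber.
    """
    if record.active is None:
        raise ValueError("activation flags not set; run select_active_chambers")
    deviations = 100.0 * (record.measured - record.planned) / record.d_max
    act = deviations[record.active]
    n = int(record.active.sum())
    if n == 0:
        raise NoEvaluableChambersError(
            "no evaluable chambers: every chamber was deactivated")
    sd = float(np.std(act, ddof=1)) if n > 1 else 0.0
    return DeviationSummary(
        deviations=deviations, active=record.active.copy(),
        mean=float(act.mean()), sd=sd,
        min=float(act.min()), max=float(act.max()), n_active=n)


def classify(summary: DeviationSummary,
             tol: ToleranceConfig = ToleranceConfig()) -> VerificationResult:
    """Pass/fail against the institutional tolerances (boundaries inclusive).

    Per-chamber classes: within +/-5%, between 5 and 7%, beyond 7%, or
    deactivated.
    """
    violated = []
    if abs(summary.mean) > tol.mean_tol:
        violated.append("mean")
    if summary.min < tol.min_tol:
        violated.append("minimum")
    if summary.max > tol.max_tol:
        violated.append("maximum")
    classes = []
    for dev, act in zip(summary.deviations, summary.active):
        if not act:
            classes.append("deactivated")
        elif abs(dev) <= 5.0:
            classes.append("active_within_5")
        elif abs(dev) <= 7.0:
            classes.append("active_5_to_7")
        else:
            classes.append("active_beyond_7")
    return VerificationResult(summary=summary, passed=not violated,
                              violated_criteria=tuple(violated),
                              chamber_classes=tuple(classes))


def verify_field(grid: DoseGrid, layout: ICStackLayout,
                 session: MeasurementSession, measured: MeasuredSet,
                 tol: ToleranceConfig = ToleranceConfig(),
                 spec: ChamberSpec = ChamberSpec()) -> tuple[VerificationResult,
                                                             VerificationRecord]:
    """Full verification pipeline for one field.

    planned doses -> gradients -> activation -> deviations -> classification.
    Chambers whose gradient stencil leaves the grid are deactivated (their
    gradient is recorded as +inf).
    """
    planned = planned_doses_at_chambers(grid, layout, session, spec)
    pos = np.asarray(session.placement) + layout.offsets
    pos[:, 0] += spec.effective_point_offset_mm
    gradients = np.empty(N_CHAMBERS)
    for i, p in enumerate(pos):
        try:
            gradients[i] = _gradient(grid, p, scalar=tol.gradient_scalar)
        except ValueError:
            gradients[i] = np.inf
    record = VerificationRecord(planned=planned, measured=measured.doses,
                                gradients=gradients, d_max=grid.d_max)
    select_active_chambers(record, tol)
    summary = compute_deviation_summary(record)
    return classify(summary, tol), record


@dataclass(frozen=True)
class RepeatPolicyConfig:
    """Institutional follow-up rules after a failed verification."""

    max_justifiable_chambers: int = 2
    justification_gradient_quantile: float = 0.75


def repeat_policy(result: VerificationResult,
                  history: tuple[VerificationResult, ...] = (),
                  policy: RepeatPolicyConfig = RepeatPolicyConfig(),
                  record: VerificationRecord | None = None) -> str:
    """Decide the follow-up action for a verification result.

    pass -> accept; first failure -> repeat the measurement; failure after a
    repeat -> accept with justification when at most ``k`` chambers lie
    beyond +/-7% and all of them sit in the upper-gradient region of the
    field, otherwise adapt the plan.
    """
    if result.passed:
        return "accept"
    if len(history) == 0:
        return "repeat_measurement"
    beyond = [i for i, c in enumerate(result.chamber_classes)
              if c == "active_beyond_7"]
    if len(beyond) <= policy.max_justifiable_chambers and record is not None \
            and len(beyond) > 0:
        finite = record.gradients[np.isfinite(record.gradients)]
        q = float(np.quantile(finite, policy.justification_gradient_quantile))
        if all(record.gradients[i] >= q for i in beyond):
            return "accept_with_justification"
    return "adapt_plan"
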