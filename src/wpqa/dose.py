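"""Synthetic pencil-beam dose engine for a water phantom.

Plays the role of the treatment planning system when no clinical TPS is
available: it turns a scanned-ion-beam plan (energy layers + spots) into a 3D
dose grid in water.  The depth-dose model is an analytic Bragg-curve
parametrization chosen for physical plausibility (entrance plateau, single
peak near the nominal range, sharp distal fall-off), not for fidelity to any
particular beamline.

Coordinate convention (used consistently across the package): phantom frame
with origin at the center of the entrance window at isocenter; axis A =
longitudinal (depth in water), B = vertical, C = lateral.  All lengths in mm,
doses in Gy.  Voxel centers sit at ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls
from scipy.special import erfc

__all__ = [
    "DepthDoseCurve",
    "PencilBeamSpot",
    "TreatmentField",
    "DoseGrid",
    "WaterPhantomGeometry",
    "TargetRegion",
    "make_depth_dose",
    "compute_dose_grid",
    "optimize_sobp",
    "apply_range_shifter",
    "ION_DEFAULTS",
    "MIN_FWHM_MM",
]

# 80%-to-20% distance of a Gaussian fall-off, in units of sigma.
_FALLOFF_80_20 = np.sqrt(2.0 * np.log(5.0)) - np.sqrt(2.0 * np.log(1.25))
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

MIN_RANGE_MM = 2.0
MAX_RANGE_MM = 300.0

# Minimum pencil-beam FWHM per ion species (mm).
MIN_FWHM_MM = {"proton": 8.0, "helium": 6.0, "carbon": 6.0}

# Per-ion Bragg-curve defaults.  peak_width is the proximal half-width of the
# peak (mm), distal_falloff the 80%-20% distance (mm), idd_peak the integral
# depth dose at the peak in Gy*mm^2 per particle (order-of-magnitude values
# from stopping-power ratios; absolute scale is absorbed by plan weights).
ION_DEFAULTS = {
    "proton": dict(entrance_to_peak_ratio=0.30, peak_width=8.0,
                   distal_falloff=4.0, idd_peak=1.6e-6),
    "helium": dict(entrance_to_peak_ratio=0.28, peak_width=6.0,
                   distal_falloff=2.5, idd_peak=6.0e-6),
    "carbon": dict(entrance_to_peak_ratio=0.25, peak_width=5.0,
                   distal_falloff=1.8, idd_peak=2.5e-5),
}


@dataclass(frozen=True)
class DepthDoseCurve:
    """Tabulated dose-per-particle versus depth for one beam energy."""

    ion_species: str
    nominal_range: float          # mm water-equivalent (distal 80% level region)
    entrance_to_peak_ratio: float
    peak_width: float             # mm, proximal half-width of the peak
    distal_falloff: float         # mm, 80%-20% distal distance
    depths: np.ndarray            # mm, ascending
    dose: np.ndarray              # Gy*mm^2 per particle

    def dose_at(self, depth) -> np.ndarray:
        """Linear interpolation; zero beyond the tabulated support."""
        return np.interp(depth, self.depths, self.dose, left=0.0, right=0.0)

    @property
    def peak_dose(self) -> float:
        return float(self.dose.max())

    @property
    def peak_depth(self) -> float:
        return float(self.depths[int(np.argmax(self.dose))])


@dataclass(frozen=True)
class PencilBeamSpot:
    """One raster-scan spot: which energy layer, where, how many particles."""

    energy_index: int
    lateral_position: tuple[float, float]  # (B, C) mm at isocenter
    particle_number: float
    fwhm: float                            # mm

    def __post_init__(self):
        if self.particle_number <= 0:
            raise ValueError("particle_number must be > 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")


@dataclass(frozen=True)
class TreatmentField:
    ion_species: str
    energy_layers: tuple[float, ...]       # nominal ranges, mm
    spots: tuple[PencilBeamSpot, ...]
    range_shifter: bool = False
    range_shifter_wet_mm: float = 0.0
    room: str = "Hx"
    fraction_dose: float = 2.0             # Gy

    def __post_init__(self):
        if len(self.energy_layers) < 1 or len(self.spots) < 1:
            raise ValueError("field needs at least one layer and one spot")
        n = len(self.energy_layers)
        for s in self.spots:
            if not (0 <= s.energy_index < n):
                raise ValueError(
                    f"spot addresses nonexistent energy layer {s.energy_index}")

    @property
    def total_particles(self) -> float:
        return float(sum(s.particle_number for s in self.spots))

    @property
    def effective_ranges(self) -> tuple[float, ...]:
        """Layer ranges after the range-shifter shift (mm water-equivalent)."""
        shift = self.range_shifter_wet_mm if self.range_shifter else 0.0
        return tuple(r - shift for r in self.energy_layers)


@dataclass(frozen=True)
class WaterPhantomGeometry:
    """Water phantom; origin at the entrance-window center at isocenter."""

    extent_a: float = 300.0   # mm, depth
    extent_b: float = 150.0   # mm, vertical (centered on origin)
    extent_c: float = 150.0   # mm, lateral (centered on origin)

    def __post_init__(self):
        if min(self.extent_a, self.extent_b, self.extent_c) <= 0:
            raise ValueError("phantom extents must be positive")


@dataclass
class DoseGrid:
    """3D dose distribution on an isotropic grid in the phantom frame."""

    origin: tuple[float, float, float]  # mm, corner of the grid volume
    spacing: float                      # mm
    values: np.ndarray                  # (na, nb, nc), Gy

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3D")
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")

    @property
    def d_max(self) -> float:
        """Maximum dose over the entire field grid (Gy)."""
        return float(self.values.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


@dataclass(frozen=True)
class TargetRegion:
    """Cylindrical target: a depth interval times a lateral circle."""

    depth_min: float                 # mm along A
    depth_max: float
    center: tuple[float, float] = (0.0, 0.0)   # (B, C) mm
    diameter: float = 50.0           # mm

    def __post_init__(self):
        if not (0 < self.depth_min < self.depth_max):
            raise ValueError("need 0 < depth_min < depth_max")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


def make_depth_dose(ion_species: str, nominal_range: float,
                    model_params: dict | None = None,
                    depth_step: float = 0.2) -> DepthDoseCurve:
    """Build an analytic Bragg curve for one beam energy.

    The curve is the sum of an asymmetric Gaussian peak (proximal width from
    ``peak_width``, distal width from ``distal_falloff``) and a gently rising
    entrance plateau cut off at the peak by a complementary error function.
    The peak sits ``distal_falloff`` proximal to the nominal range so the
    distal 80% level falls near the nominal range.
    """
    if ion_species not in ION_DEFAULTS:
        raise ValueError(f"unknown ion species {ion_species!r}")
    if not (MIN_RANGE_MM <= nominal_range <= MAX_RANGE_MM):
        raise ValueError(
            f"nominal_range {nominal_range} mm outside supported "
            f"[{MIN_RANGE_MM}, {MAX_RANGE_MM}] mm")

    p = dict(ION_DEFAULTS[ion_species])
    if model_params:
        p.update(model_params)

    ratio = p["entrance_to_peak_ratio"]
    sigma_dist = p["distal_falloff"] / _FALLOFF_80_20
    sigma_prox = p["peak_width"] / 1.1774      # half-width at half max -> sigma
    z_peak = max(nominal_range - p["distal_falloff"], 0.5)

    depths = np.arange(0.0, nominal_range + 5.0 * p["distal_falloff"] + depth_step,
                       depth_step)
    sigma = np.where(depths < z_peak, sigma_prox, sigma_dist)
    peak = np.exp(-0.5 * ((depths - z_peak) / sigma) ** 2)
    # Entrance plateau: slight rise with depth, killed distally with the same
    # fall-off scale as the peak.
    cutoff = 0.5 * erfc((depths - z_peak) / (np.sqrt(2.0) * sigma_dist))
    plateau = ratio * (1.0 + 0.4 * depths / z_peak) * cutoff
    dose = peak + plateau
    dose *= p["idd_peak"] / dose.max()
    return DepthDoseCurve(
        ion_species=ion_species, nominal_range=nominal_range,
        entrance_to_peak_ratio=ratio, peak_width=p["peak_width"],
        distal_falloff=p["distal_falloff"], depths=depths, dose=dose)


def _layer_curves(fld: TreatmentField) -> list[DepthDoseCurve]:
    shift = fld.range_shifter_wet_mm if fld.range_shifter else 0.0
    curves = []
    for rng in fld.energy_layers:
        eff = rng - shift
        if eff <= 0:
            raise ValueError(
                f"range shifter of {shift} mm leaves layer range {rng} mm "
                "non-positive")
        curves.append(make_depth_dose(fld.ion_species, eff))
    return curves


def compute_dose_grid(fld: TreatmentField, phantom: WaterPhantomGeometry,
                      spacing: float = 2.0) -> DoseGrid:
    """Superimpose all spots of a field into a dose grid.

    dose(a, b, c) = sum_s N_s * IDD_layer(s)(a) * G2D(b - b_s, c - c_s; fwhm_s)
    with G2D a normalized 2D Gaussian, so the grid is exactly linear in every
    spot's particle number.  Computation is separable per layer (depth profile
    x lateral fluence map).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    half_b, half_c = phantom.extent_b / 2.0, phantom.extent_c / 2.0
    for i, s in enumerate(fld.spots):
        b, c = s.lateral_position
        if abs(b) > half_b or abs(c) > half_c:
            raise ValueError(
                f"spot {i} at (B={b}, C={c}) mm lies outside the phantom "
                f"extents (±{half_b}, ±{half_c}) mm")

    na = int(round(phantom.extent_a / spacing))
    nb = int(round(phantom.extent_b / spacing))
    nc = int(round(phantom.extent_c / spacing))
    origin = (0.0, -half_b, -half_c)
    a = origin[0] + (np.arange(na) + 0.5) * spacing
    b = origin[1] + (np.arange(nb) + 0.5) * spacing
    c = origin[2] + (np.arange(nc) + 0.5) * spacing

    curves = _layer_curves(fld)
    values = np.zeros((na, nb, nc))
    by_layer: dict[int, list[PencilBeamSpot]] = {}
    for s in fld.spots:
        by_layer.setdefault(s.energy_index, []).append(s)

    for li, spots in by_layer.items():
        depth_profile = curves[li].dose_at(a)
        lateral = np.zeros((nb, nc))
        for s in spots:
            sig = s.fwhm / _FWHM_TO_SIGMA
            norm = 1.0 / (np.sqrt(2.0 * np.pi) * sig)
            gb = norm * np.exp(-0.5 * ((b - s.lateral_position[0]) / sig) ** 2)
            gc = norm * np.exp(-0.5 * ((c - s.lateral_position[1]) / sig) ** 2)
            lateral += s.particle_number * np.outer(gb, gc)
        values += depth_profile[:, None, None] * lateral[None, :, :]

    return DoseGrid(origin=origin, spacing=spacing, values=values)


def _spot_grid(center: tuple[float, float], radius: float,
               spacing: float) -> list[tuple[float, float]]:
    """Square lateral grid of spot positions covering a circle."""
    n = int(np.ceil(radius / spacing))
    offs = np.arange(-n, n + 1) * spacing
    pts = []
    for db in offs:
        for dc in offs:
            if db * db + dc * dc <= radius * radius + 1e-9:
                pts.append((center[0] + db, center[1] + dc))
    return pts


def optimize_sobp(ion_species: str, target: TargetRegion,
                  prescribed_dose: float,
                  fwhm: float | None = None,
                  layer_step: float | None = None,
                  room: str = "Hx") -> TreatmentField:
    """Build a treatment field delivering a flat SOBP to a cylindrical target.

    Bragg peaks are placed across the target depth interval and the per-layer
    weights are solved by non-negative least squares so the central-axis dose
    matches the prescription on a 1 mm sampling of the target interval.
    Deterministic: no random numbers.
    """
    if prescribed_dose < 0:
        raise ValueError("prescribed_dose must be >= 0")
    defaults = ION_DEFAULTS.get(ion_species)
    if defaults is None:
        raise ValueError(f"unknown ion species {ion_species!r}")
    if target.depth_max + defaults["distal_falloff"] > MAX_RANGE_MM:
        raise ValueError(
            f"target depth {target.depth_max} mm exceeds the maximum "
            f"deliverable range of {MAX_RANGE_MM} mm")

    fwhm = fwhm if fwhm is not None else MIN_FWHM_MM[ion_species]
    if layer_step is None:
        layer_step = min(2.5, defaults["peak_width"] / 2.0)

    # Peak positions spanning the target, deepest first; layer range puts the
    # peak at the requested depth.
    peaks = np.arange(target.depth_max, target.depth_min - 1e-9, -layer_step)
    if peaks[-1] > target.depth_min + 1e-9:
        peaks = np.append(peaks, target.depth_min)
    ranges = tuple(float(pz + defaults["distal_falloff"]) for pz in peaks)
    curves = [make_depth_dose(ion_species, r) for r in ranges]

    # Lateral spot layout shared by all layers; margin keeps the plateau flat
    # out to the target radius.
    margin = 1.5 * fwhm
    positions = _spot_grid(target.center, target.diameter / 2.0 + margin,
                           fwhm / 2.0)
    sig = fwhm / _FWHM_TO_SIGMA
    # Central-axis lateral fluence factor of the spot layout (per unit weight).
    lf = sum(
        np.exp(-0.5 * (((target.center[0] - pb) ** 2 +
                        (target.center[1] - pc) ** 2) / sig ** 2))
        for pb, pc in positions) / (2.0 * np.pi * sig ** 2)

    nl = len(curves)
    weights = np.zeros(nl)
    if prescribed_dose > 0.0:
        # Flat-plateau weights by non-negative least squares: match the
        # prescription on a dense depth sampling of the target interval.
        sample = np.arange(target.depth_min, target.depth_max + 0.5, 1.0)
        a_mat = lf * np.array([[c.dose_at(z) for c in curves]
                               for z in sample])
        weights, _ = nnls(a_mat, np.full(len(sample), prescribed_dose))
    # particle_number must stay positive; a zero prescription degenerates to
    # numerically-zero weights.
    spots = tuple(
        PencilBeamSpot(energy_index=li, lateral_position=(pb, pc),
                       particle_number=max(float(weights[li]), 1e-30),
                       fwhm=fwhm)
        for li in range(nl) for pb, pc in positions)

    return TreatmentField(ion_species=ion_species, energy_layers=ranges,
                          spots=spots, room=room,
                          fraction_dose=prescribed_dose)


def apply_range_shifter(fld: TreatmentField, thickness_mm: float,
                        fwhm_broadening_per_mm: float = 0.0) -> TreatmentField:
    """Insert a range shifter of given water-equivalent thickness.

    Every layer's effective range is reduced by the thickness; optionally the
    spot FWHM is inflated linearly with thickness (off by default — lateral
    scattering is out of scope).
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be >= 0")
    if thickness_mm == 0:
        return fld
    for rng in fld.energy_layers:
        if rng - thickness_mm <= 0:
            raise ValueError(
                f"thickness {thickness_mm} mm reduces layer range {rng} mm "
                "to <= 0")
    spots = fld.spots
    if fwhm_broadening_per_mm > 0:
        factor = 1.0 + fwhm_broadening_per_mm * thickness_mm
        spots = tuple(replace(s, fwhm=s.fwhm * factor) for s in fld.spots)
    return replace(fld, range_shifter=True,
                   range_shifter_wet_mm=fld.range_shifter_wet_mm + thickness_mm,
                   spots=spots)
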