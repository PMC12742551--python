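"""Rule engines around the verification measurement itself.

Two institutional checks are modeled: (a) whether re-measurement of an
*adapted* treatment plan (ATP) may be omitted because the adapted plan is
sufficiently similar to the already-verified original, and (b) the
data-integrity comparison of the plan as transferred to the machine against
the approved plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PlanSummary",
    "ATPDecision",
    "PlanRecord",
    "ATPRulesConfig",
    "check_atp",
    "integrity_check",
]


@dataclass(frozen=True)
class PlanSummary:
    """The plan-level quantities entering the ATP similarity rules."""

    ion_species: str
    fraction_dose_gy: float
    n_fields: int
    field_angles: tuple[tuple[float, float], ...]   # (couch, gantry) deg per field
    modifiers: dict = field(default_factory=dict)   # name -> position mm
    energy_levels: frozenset = frozenset()
    total_particles: float = 1.0
    optimization_meta: dict = field(default_factory=dict)  # layer/spot spacing, grid size

    def __post_init__(self):
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.total_particles <= 0:
            raise ValueError("total_particles must be positive")


@dataclass(frozen=True)
class ATPDecision:
    omit_measurement: bool
    violated_rules: tuple[str, ...]

    def __post_init__(self):
        if self.omit_measurement != (len(self.violated_rules) == 0):
            raise ValueError("omit_measurement must mirror empty violations")


@dataclass(frozen=True)
class ATPRulesConfig:
    angle_tol_deg: float = 10.0
    modifier_position_tol_mm: float = 100.0
    max_new_energy_levels: int = 20
    particle_number_rel_tol: float = 0.20
    fraction_dose_tol_gy: float = 1e-6
    optimization_meta_rel_tol: float = 0.10


def _circular_diff(a: float, b: float) -> float:
    """Shortest arc between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def check_atp(original: PlanSummary, adapted: PlanSummary,
              rules: ATPRulesConfig = ATPRulesConfig()) -> ATPDecision:
    """Decide whether re-measurement of an adapted plan may be omitted.

    Omission requires ALL of: same ion species; same fraction dose; same
    number of fields; couch and gantry angles within ~10 deg; same modifier
    set at positions within ~100 mm; the adapted energy set contained in the
    original expanded by at most ~20 new levels; total particle number within
    ~20%; comparable optimization settings.  A differing ion species
    short-circuits the check.
    """
    if original.ion_species != adapted.ion_species:
        return ATPDecision(False, ("ion_species",))

    violated: list[str] = []
    if abs(original.fraction_dose_gy - adapted.fraction_dose_gy) \
            > rules.fraction_dose_tol_gy:
        violated.append("fraction_dose")
    if original.n_fields != adapted.n_fields:
        violated.append("n_fields")
    if any(   # compare angles field-by-field over the common prefix
        _circular_diff(c0, c1) > rules.angle_tol_deg
        or _circular_diff(g0, g1) > rules.angle_tol_deg
        for (c0, g0), (c1, g1) in zip(original.field_angles,
                                      adapted.field_angles)
    ):
        violated.append("angles")

    if set(original.modifiers) != set(adapted.modifiers) or any(
        abs(original.modifiers[m] - adapted.modifiers[m])
        > rules.modifier_position_tol_mm for m in original.modifiers
    ):
        violated.append("modifiers")

    new_levels = set(adapted.energy_levels) - set(original.energy_levels)
    if len(new_levels) > rules.max_new_energy_levels:
        violated.append("energy_levels")

    # symmetric relative difference, so the rule reads the same from either side
    rel = abs(adapted.total_particles - original.total_particles) \
        / (0.5 * (adapted.total_particles + original.total_particles))
    if rel > rules.particle_number_rel_tol:
        violated.append("particle_number")

    keys = set(original.optimization_meta) | set(adapted.optimization_meta)
    for key in sorted(keys):
        a = original.optimization_meta.get(key)
        b = adapted.optimization_meta.get(key)
        if a is None or b is None:
            violated.append("field_contributions")
            break
        scale = max(abs(a), abs(b), 1e-12)
        if abs(a - b) / scale > rules.optimization_meta_rel_tol:
            violated.append("field_contributions")
            break

    return ATPDecision(len(violated) == 0, tuple(violated))


# Tags compared by the data-integrity check, in reporting order.
INTEGRITY_TAGS = (
    "approval_status",
    "plan_label",
    "review_timestamp",
    "patient_name",
    "patient_id",
    "field_names",
    "number_of_scan_spots",
    "particle_number_tuples",
    "beam_modifiers",
    "modifier_positions",
    "isocenter_positions",
)


@dataclass(frozen=True)
class PlanRecord:
    """Integrity view of a plan: the transfer-checked tags."""

    approval_status: str = "approved"
    plan_label: str = ""
    review_timestamp: str = ""
    patient_name: str = ""
    patient_id: str = ""
    field_names: tuple[str, ...] = ()
    number_of_scan_spots: int = 0
    particle_number_tuples: tuple = ()   # (position, focus, energy) triples
    beam_modifiers: tuple[str, ...] = ()
    modifier_positions: tuple = ()
    isocenter_positions: tuple = ()

    def __post_init__(self):
        if self.number_of_scan_spots != len(self.particle_number_tuples) \
                and self.particle_number_tuples:
            raise ValueError("spot count must equal the length of the "
                             "particle-number list")


def integrity_check(planned: PlanRecord, transferred: PlanRecord) -> list[str]:
    """Field-by-field comparison of the transfer-checked tags.

    Returns the list of mismatching tag names (empty iff the transfer is
    intact).  Numeric tuples are compared exactly; a missing (None) value is
    reported as ``tag (absent)``.
    """
    mismatches: list[str] = []
    for tag in INTEGRITY_TAGS:
        a = getattr(planned, tag, None)
        b = getattr(transferred, tag, None)
        if a is None or b is None:
            mismatches.append(f"{tag} (absent)")
        elif a != b:
            mismatches.append(tag)
    return mismatches
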