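"""Seeded generators of synthetic verification cohorts.

Two modes:

* **parametric** — fast: draws per-field mean deviations and per-chamber
  residuals from a documented statistical model and assembles FieldRecords.
  This is the stand-in for the institutional database (which is not public);
  its defaults are calibrated to the published cohort summaries: total field
  mean deviation -0.5 +/- 0.9 % of D_max, 21 +/- 2 activated chambers,
  irradiation time 03:24 +/- 01:57 mm:ss, and a residual tail tuned so
  roughly 0.7% of active-chamber deviations exceed +/-7%.

* **mechanistic** — slow, desk-scale: for each field builds an SOBP plan,
  computes its dose grid, places the 24-chamber stack, simulates the
  measurement with a sampled error model and runs the full verification
  pipeline.

Pass/fail flags are always recomputed from the tolerance rules, never
sampled, so tolerance changes propagate consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chambers as ch
from . import dose as de
from .cohort import FieldRecord
from .verify import (DeviationSummary, ToleranceConfig, VerificationRecord,
                     classify, verify_field)

__all__ = [
    "CohortGeneratorConfig",
    "MechanisticConfig",
    "generate_parametric_cohort",
    "generate_mechanistic_cohort",
    "calibrate_from_summary",
]


def _default_proportions() -> dict:
    # Cohort composition of a large scanned-ion-beam QA program: mostly
    # protons and carbon ions, helium a late addition; two horizontal rooms
    # vs one gantry; one legacy and one current TPS; head dominates.
    return {
        "room": {"Hx": 0.59, "Ga": 0.41},
        "ion": {"p": 0.517, "C": 0.472, "He": 0.011},
        "tps": {"Syngo": 0.77, "RayStation": 0.23},
        "rashi": {False: 0.75, True: 0.25},
        "indication": {"head": 0.68, "abdomen": 0.12, "spine": 0.06,
                       "thorax": 0.05, "prostate": 0.03, "extremities": 0.02,
                       "neck": 0.02, "pancreas": 0.02},
        "year": {2016: 2285, 2017: 2098, 2018: 2488, 2019: 2024, 2020: 2504,
                 2021: 2368, 2022: 2677, 2023: 2379, 2024: 2477, 2025: 1538},
    }


@dataclass
class CohortGeneratorConfig:
    """Parameters of the parametric cohort generator.

    ``mean_loc``/``mean_scale`` (percent of D_max) describe the distribution
    of field-mean deviations; alternatively ``mean_by`` selects one category
    axis whose per-level ``mean_params`` {level: (loc, scale)} drive the
    field mean.  Per-chamber residuals are a two-component normal mixture
    (narrow core + rare wide tail) centered within each field, so the
    recorded field mean equals the drawn field-level mean.
    """

    n_fields: int = 23014
    proportions: dict = field(default_factory=_default_proportions)
    mean_loc: float = -0.5          # % of D_max
    mean_scale: float = 0.9
    mean_by: str | None = None
    mean_params: dict = field(default_factory=dict)
    residual_core_sd: float = 1.6   # % of D_max, per chamber
    tail_weight: float = 0.028
    tail_sd: float = 6.0
    n_active_mean: float = 21.0
    n_active_sd: float = 2.0
    time_mean_s: float = 204.0
    time_sd_s: float = 117.0
    time_by: str | None = None
    time_params: dict = field(default_factory=dict)
    human_error_rate: float = 0.005
    repeat_rate: float = 0.03
    repeat_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        for scale in (self.mean_scale, self.residual_core_sd, self.tail_sd,
                      self.n_active_sd, self.time_sd_s):
            if scale < 0:
                raise ValueError("scales must be >= 0")
        if not (0 <= self.tail_weight <= 1):
            raise ValueError("tail_weight must lie in [0, 1]")
        for axis, props in self.proportions.items():
            total = sum(props.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6) and axis != "year":
                raise ValueError(
                    f"proportions for {axis!r} sum to {total}, not 1")


def _choose(rng, props: dict, size: int):
    keys = list(props)
    p = np.array([props[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    var = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - var / 2.0, math.sqrt(var)


def _passes(devs: np.ndarray, tol: ToleranceConfig) -> bool:
    """Recompute the pass flag from the tolerance rules (never sampled)."""
    k = len(devs)
    devs24 = np.zeros(ch.N_CHAMBERS)
    devs24[:k] = devs
    active = np.zeros(ch.N_CHAMBERS, dtype=bool)
    active[:k] = True
    sd = float(np.std(devs, ddof=1)) if k > 1 else 0.0
    summary = DeviationSummary(deviations=devs24, active=active,
                               mean=float(devs.mean()), sd=sd,
                               min=float(devs.min()), max=float(devs.max()),
                               n_active=k)
    return classify(summary, tol).passed


def _residuals(rng, k: int, cfg: CohortGeneratorConfig) -> np.ndarray:
    wide = rng.random(k) < cfg.tail_weight
    r = rng.normal(0.0, cfg.residual_core_sd, size=k)
    if wide.any():
        r[wide] = rng.normal(0.0, cfg.tail_sd, size=int(wide.sum()))
    return r - r.mean()   # spatial residuals within the field, mean-free

def generate_parametric_cohort(cfg: CohortGeneratorConfig,
                               seed: int | None = None,
                               tol: ToleranceConfig = ToleranceConfig()
                               ) -> list[FieldRecord]:
    """Draw a cohort of FieldRecords from the parametric model."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_fields
    cats = {axis: _choose(rng, props, n)
            for axis, props in cfg.proportions.items()}

    if cfg.mean_by is not None:
        missing = set(cats[cfg.mean_by]) - set(cfg.mean_params)
        if missing:
            raise ValueError(f"mean_params missing levels: {sorted(missing)}")
        locs = np.array([cfg.mean_params[v][0] for v in cats[cfg.mean_by]])
        scales = np.array([cfg.mean_params[v][1] for v in cats[cfg.mean_by]])
    else:
        locs = np.full(n, cfg.mean_loc)
        scales = np.full(n, cfg.mean_scale)
    field_means = locs + scales * rng.standard_normal(n) \
        if np.any(scales > 0) else locs.copy()

    n_active = np.clip(np.rint(rng.normal(cfg.n_active_mean, cfg.n_active_sd,
                                          size=n)), 1, 24).astype(int) \
        if cfg.n_active_sd > 0 else \
        np.full(n, int(np.clip(round(cfg.n_active_mean), 1, 24)))

    if cfg.time_by is not None:
        missing = set(cats[cfg.time_by]) - set(cfg.time_params)
        if missing:
            raise ValueError(f"time_params missing levels: {sorted(missing)}")
        tp = [cfg.time_params[v] for v in cats[cfg.time_by]]
        times = np.array([
            rng.lognormal(*_lognormal_params(m, s)) if s > 0 else m
            for m, s in tp])
    elif cfg.time_sd_s > 0:
        mu, sig = _lognormal_params(cfg.time_mean_s, cfg.time_sd_s)
        times = rng.lognormal(mu, sig, size=n)
    else:
        times = np.full(n, cfg.time_mean_s)

    pos_a = rng.uniform(20.0, 250.0, size=n)
    pos_bc = np.clip(rng.normal(0.0, 30.0, size=(n, 2)), -60.0, 60.0)
    volumes = np.clip(rng.lognormal(math.log(150.0), 1.2, size=n),
                      10.0, 10000.0)
    human_err = rng.random(n) < cfg.human_error_rate
    repeats = rng.random(n) < cfg.repeat_rate

    records: list[FieldRecord] = []
    for i in range(n):
        k = n_active[i]
        r = _residuals(rng, k, cfg)
        devs = field_means[i] + r
        rec = FieldRecord(
            field_id=f"F{i:05d}",
            room=cats["room"][i], ion=cats["ion"][i], tps=cats["tps"][i],
            rashi=bool(cats["rashi"][i]), indication=cats["indication"][i],
            year=int(cats["year"][i]),
            pos_a=float(pos_a[i]), pos_b=float(pos_bc[i, 0]),
            pos_c=float(pos_bc[i, 1]), volume_cm3=float(volumes[i]),
            mean_dev=float(devs.mean()),
            sd_dev=float(np.std(devs, ddof=1)) if k > 1 else 0.0,
            min_dev=float(devs.min()), max_dev=float(devs.max()),
            n_active=int(k), time_s=float(times[i]),
            passed=_passes(devs, tol),
            human_error=bool(human_err[i]))
        records.append(rec)
        if repeats[i]:
            # re-measurement of the same field: residuals correlated with the
            # original draw, reflecting largely reproducible conditions
            rho = cfg.repeat_correlation
            r2 = rho * r + math.sqrt(max(1.0 - rho * rho, 0.0)) \
                * _residuals(rng, k, cfg)
            r2 = r2 - r2.mean()
            devs2 = field_means[i] + r2
            records.append(replace(
                rec, mean_dev=float(devs2.mean()),
                sd_dev=float(np.std(devs2, ddof=1)) if k > 1 else 0.0,
                min_dev=float(devs2.min()), max_dev=float(devs2.max()),
                time_s=float(times[i]), passed=_passes(devs2, tol),
                repeat_index=1, human_error=False))
    return records


@dataclass
class MechanisticConfig:
    """Parameters of the mechanistic (physics-pipeline) cohort generator."""

    n_fields: int = 20
    spacing_mm: float = 2.0
    ions: dict = field(default_factory=lambda: {"p": 0.5, "C": 0.45, "He": 0.05})
    depth_center_range: tuple[float, float] = (70.0, 120.0)
    half_length_range: tuple[float, float] = (15.0, 25.0)
    diameter_range: tuple[float, float] = (40.0, 60.0)
    prescribed_dose_gy: float = 2.0
    zero_error: bool = False
    positioning_sd: float = 0.3       # mm
    relative_noise_sd: float = 0.006
    background_offset_gy: float = -0.0005
    calibration_bias_loc: float = -0.004
    calibration_bias_sd: float = 0.006
    human_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")


_ION_NAMES = {"p": "proton", "He": "helium", "C": "carbon"}


def generate_mechanistic_cohort(cfg: MechanisticConfig,
                                seed: int | None = None,
                                tol: ToleranceConfig = ToleranceConfig()
                                ) -> tuple[list[FieldRecord],
                                           list[VerificationRecord]]:
    """Run the full plan -> dose -> measurement -> verification pipeline.

    Returns the FieldRecords plus the per-field chamber tables (planned,
    measured, gradients, D_max) needed to replay activation decisions, e.g.
    for gradient-threshold sensitivity studies.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    phantom = de.WaterPhantomGeometry(extent_a=200.0, extent_b=120.0,
                                      extent_c=120.0)
    layout = ch.default_stack_layout()
    spec = ch.POINT_CHAMBER if cfg.zero_error else ch.ChamberSpec()

    records: list[FieldRecord] = []
    tables: list[VerificationRecord] = []
    for i in range(cfg.n_fields):
        ion = _choose(rng, cfg.ions, 1)[0]
        center = rng.uniform(*cfg.depth_center_range)
        half = rng.uniform(*cfg.half_length_range)
        diameter = rng.uniform(*cfg.diameter_range)
        target = de.TargetRegion(depth_min=center - half,
                                 depth_max=center + half,
                                 diameter=diameter)
        fld = de.optimize_sobp(_ION_NAMES[ion], target,
                               cfg.prescribed_dose_gy)
        grid = de.compute_dose_grid(fld, phantom, spacing=cfg.spacing_mm)

        if cfg.zero_error:
            em = ch.ErrorModel()
        else:
            mode = "wrong_calibration" \
                if rng.random() < cfg.human_error_rate else "none"
            em = ch.ErrorModel(
                positioning_sd=cfg.positioning_sd,
                relative_noise_sd=cfg.relative_noise_sd,
                background_offset=cfg.background_offset_gy,
                calibration_bias=float(rng.normal(cfg.calibration_bias_loc,
                                                  cfg.calibration_bias_sd)),
                human_error_mode=mode)
        session = ch.MeasurementSession(
            placement=(center, 0.0, 0.0),
            seed=int(rng.integers(0, 2 ** 31)), error_model=em)
        measured = ch.simulate_measurement(grid, layout, session, spec)
        result, table = verify_field(grid, layout, session, measured, tol,
                                     spec)
        s = result.summary
        volume_cm3 = math.pi * (diameter / 2.0) ** 2 * (2 * half) / 1000.0
        records.append(FieldRecord(
            field_id=f"M{i:03d}", room="Hx", ion=ion,
            tps="RayStation", rashi=False, indication="head",
            year=2025, pos_a=float(center), pos_b=0.0, pos_c=0.0,
            volume_cm3=volume_cm3, mean_dev=s.mean, sd_dev=s.sd,
            min_dev=s.min, max_dev=s.max, n_active=s.n_active,
            time_s=float(rng.lognormal(*_lognormal_params(204.0, 117.0))),
            passed=result.passed,
            human_error=measured.human_error_suspected))
        tables.append(table)
    return records, tables


def calibrate_from_summary(summary: pd.DataFrame, axis: str,
                           base: CohortGeneratorConfig | None = None
                           ) -> CohortGeneratorConfig:
    """Build a generator config from a per-category summary table.

    ``summary`` must be indexed by category level with columns ``n``,
    ``mean`` and ``sd`` (percent of D_max); optional ``time_mean_s`` and
    ``time_sd_s``.  The returned config draws the category from the observed
    proportions and the field mean from the per-level location/scale, so at
    large n the aggregate reproduces the input table within Monte-Carlo
    error.
    """
    required = {"n", "mean", "sd"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary table lacks columns: {sorted(missing)}")
    if len(summary) == 0:
        raise ValueError("summary table is empty")
    if (summary["sd"] < 0).any():
        raise ValueError("negative SD in summary table")
    if (summary["n"] <= 0).any():
        raise ValueError("non-positive group size in summary table")

    cfg = base if base is not None else CohortGeneratorConfig()
    total = float(summary["n"].sum())
    props = dict(cfg.proportions)
    props[axis] = {lvl: float(row["n"]) / total
                   for lvl, row in summary.iterrows()}
    mean_params = {lvl: (float(row["mean"]), float(row["sd"]))
                   for lvl, row in summary.iterrows()}
    kwargs = dict(
        n_fields=int(total), proportions=props, mean_by=axis,
        mean_params=mean_params, seed=cfg.seed,
        residual_core_sd=cfg.residual_core_sd, tail_weight=cfg.tail_weight,
        tail_sd=cfg.tail_sd, n_active_mean=cfg.n_active_mean,
        n_active_sd=cfg.n_active_sd, human_error_rate=cfg.human_error_rate,
        repeat_rate=cfg.repeat_rate, repeat_correlation=cfg.repeat_correlation)
    if {"time_mean_s", "time_sd_s"} <= set(summary.columns):
        kwargs["time_by"] = axis
        kwargs["time_params"] = {
            lvl: (float(row["time_mean_s"]), float(row["time_sd_s"]))
            for lvl, row in summary.iterrows()}
    return CohortGeneratorConfig(**kwargs)
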