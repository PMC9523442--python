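"""CSV interchange, run configuration and the end-to-end pipeline.

One plain-text interchange format is used throughout: CSV with explicit
unit-bearing column names.

* mechanical test (one per file): ``time_s, displacement_mm, force_N``;
  mode, velocity and sample geometry come from the run configuration;
* Ussing trace: ``time_s, v_te_mV, r_te_ohm_cm2`` (current clamp) or
  ``time_s, i_sc_uA_cm2, r_te_ohm_cm2`` (voltage clamp) plus an events file
  ``time_s, label``;
* per-test modulus report: one row per curve with both Young's-modulus
  estimates, the fitted constitutive parameters and peak diagnostics.

``run_pipeline`` ties the stages together: generate (or load) force-distance
tests, convert to stress-strain, fit linear and van der Waals moduli, group
by velocity and run the statistical decision tree, then write the report
with the exact configuration hash and seed for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import mech, stats, synthetic, ussing
from .vdw import VdWParameters

__all__ = [
    "SchemaError",
    "RunConfig",
    "PipelineReport",
    "read_mech_csv",
    "write_mech_csv",
    "read_ussing_csv",
    "write_ussing_csv",
    "modulus_report_row",
    "run_pipeline",
]

log = logging.getLogger("lungmech")

MECH_COLUMNS = ("time_s", "displacement_mm", "force_N")


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _read_numeric_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        if coerced.isna().any():
            raise SchemaError(
                f"{path}: empty cell in column {col!r} at row "
                f"{df.index[coerced.isna()][0] + 2}"
            )
        df[col] = coerced
    return df


def read_mech_csv(
    path: str | Path,
    mode: str,
    velocity_mm_per_min: float,
    geometry: mech.SampleGeometry,
) -> mech.DeformationTest:
    """Read one force-distance test; validates schema, types and time order."""
    df = _read_numeric_csv(path, MECH_COLUMNS)
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise SchemaError(f"{path}: time not strictly increasing at row {i + 3}")
    return mech.DeformationTest(
        mode=mode,
        velocity_mm_per_min=velocity_mm_per_min,
        geometry=geometry,
        time_s=t,
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
    )


def write_mech_csv(test: mech.DeformationTest, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": test.time_s,
            "displacement_mm": test.displacement_mm,
            "force_N": test.force_N,
        }
    ).to_csv(path, index=False)


def read_ussing_csv(
    path: str | Path,
    events_path: str | Path | None = None,
    clamp_mode: str = "current_clamp",
    pressure_cmH2O: float = 0.0,
    pressure_side: str = "none",
    label: str = "",
) -> ussing.UssingTrace:
    """Read one Ussing trace plus its optional events file."""
    signal_col = "v_te_mV" if clamp_mode == "current_clamp" else "i_sc_uA_cm2"
    df = _read_numeric_csv(path, ("time_s", signal_col, "r_te_ohm_cm2"))
    events: tuple = ()
    if events_path is not None:
        ev = pd.read_csv(events_path)
        if not {"time_s", "label"} <= set(ev.columns):
            raise SchemaError(f"{events_path}: events file needs columns time_s, label")
        events = tuple((float(r.time_s), str(r.label)) for r in ev.itertuples())
    kwargs = {signal_col: df[signal_col].to_numpy()}
    return ussing.UssingTrace(
        time_s=df["time_s"].to_numpy(),
        r_te_ohm_cm2=df["r_te_ohm_cm2"].to_numpy(),
        events=events,
        pressure_cmH2O=pressure_cmH2O,
        pressure_side=pressure_side,
        clamp_mode=clamp_mode,
        label=label or Path(path).stem,
        **kwargs,
    )


def write_ussing_csv(
    trace: ussing.UssingTrace, path: str | Path, events_path: str | Path | None = None
) -> None:
    signal_col = "v_te_mV" if trace.clamp_mode == "current_clamp" else "i_sc_uA_cm2"
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            signal_col: trace.signal(),
            "r_te_ohm_cm2": trace.r_te_ohm_cm2,
        }
    ).to_csv(path, index=False)
    if events_path is not None:
        pd.DataFrame(trace.events, columns=["time_s", "label"]).to_csv(
            events_path, index=False
        )


def modulus_report_row(
    curve: mech.StressStrainCurve,
    estimate: mech.ModulusEstimate,
    prominence_Pa: float = 50.0,
    label: str = "",
) -> dict:
    """One report row per processed curve (schema of the per-test report CSV)."""
    maxima = mech.detect_maxima(curve, prominence_Pa)
    p = estimate.fit_params
    return {
        "label": label,
        "mode": curve.mode,
        "velocity_mm_per_min": curve.velocity_mm_per_min,
        "young_linear_Pa": estimate.young_linear_Pa,
        "young_vdw_Pa": estimate.young_vdw_Pa,
        "G_Pa": p.shear_modulus_Pa,
        "a": p.interaction,
        "lambda_m": p.limit_stretch,
        "global_max_stress_Pa": maxima.global_max[1],
        "global_max_strain": maxima.global_max[0],
        "n_local_maxima": len(maxima.local_maxima),
        "fit_rss": estimate.goodness.get("rss", float("nan")),
    }


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration (see ``RunConfig.from_yaml``).

    When ``input_dir`` is set, every ``*.csv`` in it is loaded as a
    mechanical test with the configured mode/velocity metadata; otherwise a
    synthetic cohort is generated (``velocities`` × ``n_per_velocity``
    curves).  Thresholds default to the protocol values and are logged when
    used.
    """

    out_dir: str = "lungmech_out"
    seed: int = 0
    input_dir: str | None = None
    mode: str = "compression"
    velocities: tuple = (1.0, 7.0, 70.0)
    n_per_velocity: int = 10
    noise_sd_rel: float = 0.05
    punch_diameter_mm: float = 4.0
    initial_height_mm: float = 2.0
    base_young_Pa: float = 2646.0
    interaction: float = 1.9
    limit_stretch: float = 2.1
    linear_bound: float | None = None
    prominence_Pa: float = 50.0
    contact_force_N: float | None = None
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("prominence_Pa", "alpha", "punch_diameter_mm", "initial_height_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "velocities" in raw:
            raw["velocities"] = tuple(raw["velocities"])
        return cls(**raw)

    def geometry(self) -> mech.SampleGeometry:
        return mech.SampleGeometry(self.punch_diameter_mm, self.initial_height_mm)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineReport(NamedTuple):
    per_test: pd.DataFrame
    comparison: stats.GroupComparison | None
    config_hash: str
    seed: int
    out_dir: Path


def _load_or_generate(config: RunConfig) -> list[mech.DeformationTest]:
    if config.input_dir is not None:
        files = sorted(Path(config.input_dir).glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no CSV test files found in {config.input_dir}")
        geom = config.geometry()
        return [
            read_mech_csv(f, config.mode, config.velocities[0], geom) for f in files
        ]
    base = VdWParameters(
        shear_modulus_Pa=config.base_young_Pa / 3.0,
        interaction=config.interaction,
        limit_stretch=config.limit_stretch,
    )
    cfg = synthetic.MechGenConfig(
        base_params=base,
        mode=config.mode,
        geometry=config.geometry(),
        noise_sd_rel=config.noise_sd_rel,
        seed=config.seed,
    )
    return synthetic.gen_mech_cohort(
        cfg, list(config.velocities), config.n_per_velocity, seed=config.seed
    )


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Generate-or-load → process → fit → group statistics → report files.

    Writes ``report.csv`` (per-test moduli), ``comparison.csv`` (pairwise
    statistics, when ≥ 2 velocity groups exist) and ``manifest.json``
    (config, hash, seed) into ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    log.info(
        "thresholds: linear_bound=%s prominence_Pa=%s contact_force_N=%s alpha=%s",
        config.linear_bound, config.prominence_Pa, config.contact_force_N, config.alpha,
    )
    tests = _load_or_generate(config)
    rows = []
    for i, test in enumerate(tests):
        curve = mech.to_stress_strain(test, contact_force_N=config.contact_force_N)
        try:
            est = mech.fit_vdw(
                curve, linear_bound=config.linear_bound, seed=config.seed
            )
        except mech.FitError as err:
            log.warning("curve %d: fit failed: %s", i, err)
            continue
        rows.append(
            modulus_report_row(curve, est, config.prominence_Pa, label=f"test_{i:03d}")
        )
    if not rows:
        raise RuntimeError("no curve could be fitted; nothing to report")
    per_test = pd.DataFrame(rows)

    comparison = None
    groups = [
        stats.GroupData(label=f"{v:g} mm/min", values=g["young_vdw_Pa"].to_numpy(), unit="Pa")
        for v, g in per_test.groupby("velocity_mm_per_min")
    ]
    if len(groups) >= 2:
        comparison = stats.decide_and_compare(groups, alpha=config.alpha)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_test.to_csv(out / "report.csv", index=False)
    if comparison is not None and comparison.pairwise_p:
        comparison.to_frame().to_csv(out / "comparison.csv", index=False)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_tests": len(tests),
        "n_fitted": len(rows),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineReport(
        per_test=per_test,
        comparison=comparison,
        config_hash=config.config_hash(),
        seed=config.seed,
        out_dir=out,
    )
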