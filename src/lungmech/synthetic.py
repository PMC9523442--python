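"""Synthetic uniaxial-test and Ussing-chamber data with the statistical
structure the analysis pipeline assumes.

No raw instrument data are distributed with this package, so every pipeline
stage is exercised on generated datasets:

* mechanical tests — force-distance records whose noiseless stress trace is
  exactly the van der Waals network stress at the configured parameters,
  sampled at the machine cadence (2 ms) for a constant crosshead velocity up
  to 50 % strain.  Compression stiffness scales with deformation velocity
  through configurable shear-modulus multipliers (defaults derived from the
  measured fetal-compression modulus ratios at 1, 7 and 70 mm·min⁻¹);
  tension is velocity-independent.  Noise is multiplicative Gaussian on
  stress (spread grows with stress, as in the experimental curves) and
  occasional local rupture events appear as 100–200 Pa step drops.
* electrophysiology traces — piecewise plateaus (baseline rise, inhibitor
  decay) approached exponentially and held exactly once settled, with
  additive Gaussian noise and configurable transepithelial resistance.

All randomness flows from explicit seeds; the same seed reproduces the same
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mech import DeformationTest, SampleGeometry
from .ussing import UssingTrace
from .vdw import BeyondExtensibilityError, VdWParameters, conformation_phi, nominal_stress

__all__ = [
    "FETAL_COMPRESSION_STIFFENING",
    "FETAL_GEOMETRY",
    "ADULT_GEOMETRY",
    "MechGenConfig",
    "UssingGenConfig",
    "gen_mech_test",
    "gen_mech_cohort",
    "gen_ussing_trace",
    "gen_ussing_cohort",
]

#: Fetal (4 mm punch, 2.0 mm height) and adult (8 mm punch, 4.2 mm height) geometry.
FETAL_GEOMETRY = SampleGeometry(punch_diameter_mm=4.0, initial_height_mm=2.0)
ADULT_GEOMETRY = SampleGeometry(punch_diameter_mm=8.0, initial_height_mm=4.2)

#: Compression shear-modulus multipliers per velocity (mm/min), normalized to
#: the 1 mm/min group; ratios follow the measured fetal-compression Young's
#: moduli 2646 : 4441 : 7617 Pa.
FETAL_COMPRESSION_STIFFENING = {1.0: 1.0, 7.0: 4441.0 / 2646.0, 70.0: 7617.0 / 2646.0}

#: Representative fetal constitutive parameters (7 mm/min compression group):
#: E = 4441 Pa -> G = E/3, a = 3.0, lambda_m = 2.10.
FETAL_COMPRESSION_PARAMS = VdWParameters(
    shear_modulus_Pa=4441.0 / 3.0, interaction=3.0, limit_stretch=2.10
)


@dataclass(frozen=True)
class MechGenConfig:
    """Configuration of one synthetic uniaxial test.

    ``velocity_stiffening`` maps velocity (mm/min) to a shear-modulus
    multiplier; it applies in compression only (the viscoelastic
    rate-dependence is a compression feature) and must be ≥ 1 and monotone
    in velocity.  ``rupture_rate`` is the expected number of Poisson step
    drops per curve, each of amplitude drawn from ``rupture_amplitude_Pa``;
    ``n_ruptures`` forces an exact count instead.
    """

    base_params: VdWParameters = FETAL_COMPRESSION_PARAMS
    mode: str = "compression"
    velocity_mm_per_min: float = 7.0
    geometry: SampleGeometry = FETAL_GEOMETRY
    velocity_stiffening: dict = field(
        default_factory=lambda: dict(FETAL_COMPRESSION_STIFFENING)
    )
    noise_sd_rel: float = 0.05
    noise_mode: str = "multiplicative"
    noise_sd_abs_Pa: float = 0.0
    rupture_rate: float = 0.0
    n_ruptures: int | None = None
    rupture_amplitude_Pa: tuple[float, float] = (100.0, 200.0)
    sampling_interval_s: float = 0.002
    max_strain: float = 0.5
    approach_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tension", "compression"):
            raise ValueError(f"mode must be 'tension' or 'compression', got {self.mode!r}")
        if self.mode == "compression" and self.velocity_stiffening:
            items = sorted(self.velocity_stiffening.items())
            mults = [m for _, m in items]
            if any(m < 1 for m in mults) or any(
                m2 < m1 for m1, m2 in zip(mults, mults[1:])
            ):
                raise ValueError(
                    "compression stiffening multipliers must be >= 1 and monotone in velocity"
                )
        if not 0 < self.max_strain <= 0.5:
            raise ValueError("max_strain must lie in (0, 0.5]")
        if self.noise_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")

    def effective_params(self) -> VdWParameters:
        """Generating parameters with the velocity multiplier applied (compression only)."""
        if self.mode != "compression" or not self.velocity_stiffening:
            return self.base_params
        mult = self.velocity_stiffening.get(float(self.velocity_mm_per_min), 1.0)
        return replace(
            self.base_params, shear_modulus_Pa=self.base_params.shear_modulus_Pa * mult
        )


def gen_mech_test(cfg: MechGenConfig) -> DeformationTest:
    """Generate one force-distance test record.

    The noiseless stress trace equals the van der Waals nominal stress at
    the effective parameters, so processing it with
    :func:`lungmech.mech.to_stress_strain` reproduces the model curve
    exactly.  Compression force is emitted with the machine's negative sign.
    """
    params = cfg.effective_params()
    geom = cfg.geometry
    lam_end = 1.0 + cfg.max_strain if cfg.mode == "tension" else 1.0 - cfg.max_strain
    if conformation_phi(lam_end) >= conformation_phi(params.limit_stretch):
        raise BeyondExtensibilityError(
            f"max_strain {cfg.max_strain} exceeds the network limit of the generating "
            f"parameters (λ_m = {params.limit_stretch})"
        )
    rng = np.random.default_rng(cfg.seed)

    rate_mm_s = cfg.velocity_mm_per_min / 60.0
    total_disp = cfg.max_strain * geom.initial_height_mm
    n = int(np.floor(total_disp / (rate_mm_s * cfg.sampling_interval_s))) + 1
    t = np.arange(n) * cfg.sampling_interval_s
    disp = rate_mm_s * t
    strain = disp / geom.initial_height_mm
    lam = 1.0 + strain if cfg.mode == "tension" else 1.0 - strain
    stress = np.abs(nominal_stress(lam, params))

    # local rupture events: step drops persisting to the end of the record
    n_rupt = (
        cfg.n_ruptures
        if cfg.n_ruptures is not None
        else int(rng.poisson(cfg.rupture_rate))
    )
    for _ in range(n_rupt):
        k = int(rng.integers(int(0.3 * n), int(0.9 * n)))
        amp = rng.uniform(*cfg.rupture_amplitude_Pa)
        stress[k:] -= amp

    if cfg.noise_sd_rel > 0 and cfg.noise_mode == "multiplicative":
        stress = stress * (1.0 + cfg.noise_sd_rel * rng.standard_normal(n))
    elif cfg.noise_mode == "additive" and cfg.noise_sd_abs_Pa > 0:
        stress = stress + cfg.noise_sd_abs_Pa * rng.standard_normal(n)

    force = stress * geom.area_m2
    if cfg.mode == "compression":
        force = -force

    if cfg.approach_samples > 0:
        # crosshead approach before contact: zero force, displacement still advancing
        pre_disp = rate_mm_s * np.arange(cfg.approach_samples) * cfg.sampling_interval_s
        disp = np.concatenate([pre_disp, pre_disp[-1] + rate_mm_s * cfg.sampling_interval_s + disp])
        force = np.concatenate([np.zeros(cfg.approach_samples), force])
        t = np.arange(disp.size) * cfg.sampling_interval_s

    return DeformationTest(
        mode=cfg.mode,
        velocity_mm_per_min=cfg.velocity_mm_per_min,
        geometry=geom,
        time_s=t,
        displacement_mm=disp,
        force_N=force,
    )


def gen_mech_cohort(
    cfg: MechGenConfig, velocities: list[float], n_per_velocity: int, seed: int = 0
) -> list[DeformationTest]:
    """A family of tests across velocities, with independent per-curve seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(len(velocities) * n_per_velocity)
    tests = []
    i = 0
    for v in velocities:
        for _ in range(n_per_velocity):
            tests.append(
                gen_mech_test(
                    replace(cfg, velocity_mm_per_min=v, seed=int(seeds[i] % 2**31))
                )
            )
            i += 1
    return tests


@dataclass(frozen=True)
class UssingGenConfig:
    """Configuration of one synthetic Ussing-chamber trace.

    The signal approaches ``plateau_targets[0]`` from ``initial_value``,
    then after each event in ``event_times`` decays toward the next target.
    Approaches are exponential with time constant ``tau_s`` and are held at
    the target exactly once ``settle_s`` has elapsed, so noiseless plateau
    means equal the configured targets to machine precision.
    """

    clamp_mode: str = "current_clamp"
    initial_value: float = 0.0
    plateau_targets: tuple = (3.6, 1.3)
    event_labels: tuple = ("amiloride_apical",)
    event_times_s: tuple = (1200.0,)
    duration_s: float = 2400.0
    r_te_ohm_cm2: float = 1283.0
    tau_s: float = 60.0
    settle_s: float = 600.0
    noise_sd: float = 0.0
    pressure_cmH2O: float = 0.0
    pressure_side: str = "none"
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.plateau_targets) != len(self.event_times_s) + 1:
            raise ValueError("need one plateau target per segment (events + 1)")
        if any(not 0 < et < self.duration_s for et in self.event_times_s):
            raise ValueError("event times must fall inside the trace duration")
        if list(self.event_times_s) != sorted(self.event_times_s):
            raise ValueError("event times must be increasing")
        if self.r_te_ohm_cm2 <= 0:
            raise ValueError("R_te must be positive")


def gen_ussing_trace(cfg: UssingGenConfig) -> UssingTrace:
    """Generate one trace at the clamp mode's sampling cadence (20 s / 5 s)."""
    dt = 20.0 if cfg.clamp_mode == "current_clamp" else 5.0
    t = np.arange(0.0, cfg.duration_s + dt / 2, dt)
    y = np.empty_like(t)
    boundaries = [0.0, *cfg.event_times_s, cfg.duration_s + dt]
    level_from = cfg.initial_value
    for seg, target in enumerate(cfg.plateau_targets):
        t0, t1 = boundaries[seg], boundaries[seg + 1]
        mask = (t >= t0) & (t < t1)
        dt_seg = t[mask] - t0
        approach = target + (level_from - target) * np.exp(-dt_seg / cfg.tau_s)
        y[mask] = np.where(dt_seg >= cfg.settle_s, target, approach)
        level_from = target
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        y = y + cfg.noise_sd * rng.standard_normal(t.size)
    r = np.full(t.size, cfg.r_te_ohm_cm2)
    events = tuple((et, lbl) for et, lbl in zip(cfg.event_times_s, cfg.event_labels))
    kwargs = dict(
        time_s=t,
        r_te_ohm_cm2=r,
        events=events,
        pressure_cmH2O=cfg.pressure_cmH2O,
        pressure_side=cfg.pressure_side,
        clamp_mode=cfg.clamp_mode,
        label=cfg.label,
    )
    if cfg.clamp_mode == "current_clamp":
        kwargs["v_te_mV"] = y
    else:
        kwargs["i_sc_uA_cm2"] = y
    return UssingTrace(**kwargs)


def gen_ussing_cohort(
    cfg: UssingGenConfig,
    n_traces: int,
    target_sds: tuple | None = None,
    seed: int = 0,
) -> list[UssingTrace]:
    """A cohort of traces with between-trace variability in plateau levels.

    ``target_sds`` gives one between-trace standard deviation per plateau
    target; the within-trace sampling noise stays at ``cfg.noise_sd``.
    """
    rng = np.random.default_rng(seed)
    if target_sds is None:
        target_sds = tuple(0.0 for _ in cfg.plateau_targets)
    if len(target_sds) != len(cfg.plateau_targets):
        raise ValueError("need one SD per plateau target")
    seeds = np.random.SeedSequence(seed).generate_state(n_traces)
    traces = []
    for i in range(n_traces):
        targets = tuple(
            m + sd * rng.standard_normal() for m, sd in zip(cfg.plateau_targets, target_sds)
        )
        traces.append(
            gen_ussing_trace(
                replace(
                    cfg,
                    plateau_targets=targets,
                    seed=int(seeds[i] % 2**31),
                    label=cfg.label or f"trace_{i}",
                )
            )
        )
    return traces
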