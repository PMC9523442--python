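"""Uniaxial-test processing and Young's-modulus estimation for lung tissue.

Raw machine output (force vs. crosshead displacement on a cylindrically
punched sample of known geometry) is converted to engineering strain
(displacement / initial height) and nominal stress (force / undeformed
cross-section).  Two stiffness estimates are produced per curve:

* ``linear_modulus`` — ordinary least-squares slope of stress vs. strain
  restricted to the linear regime (default below 15 % strain in
  compression, 10 % in tension), the classical small-strain Young's modulus;
* ``VanDerWaalsModel.fit`` — nonlinear least-squares fit of the van der
  Waals network stress over the full strain range, whose shear modulus is
  converted to a Young's modulus via E = 2G(1+ν).

Local stress maxima (rupture events of order 100–200 Pa seen in some
compression tests) are located by prominence-based peak detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .vdw import (
    BeyondExtensibilityError,
    VdWParameters,
    conformation_phi,
    nominal_stress,
    young_from_shear,
)

__all__ = [
    "SampleGeometry",
    "DeformationTest",
    "StressStrainCurve",
    "LinearFit",
    "MaximaResult",
    "ModulusEstimate",
    "FitError",
    "VanDerWaalsModel",
    "VanDerWaalsResults",
    "to_stress_strain",
    "linear_modulus",
    "detect_maxima",
    "fit_vdw",
    "DEFAULT_LINEAR_BOUND",
]

#: Default linear-regime strain bound per test mode.
DEFAULT_LINEAR_BOUND = {"compression": 0.15, "tension": 0.10}

#: Contact force threshold of the test machine (N).
CONTACT_FORCE_N = 1e-3


class FitError(RuntimeError):
    """Raised when a model fit cannot be performed or does not converge."""


@dataclass(frozen=True)
class SampleGeometry:
    """Cylindrical punch geometry: 4 mm biopsy punch for fetal, 8 mm for adult lungs."""

    punch_diameter_mm: float
    initial_height_mm: float

    def __post_init__(self) -> None:
        if self.punch_diameter_mm <= 0 or self.initial_height_mm <= 0:
            raise ValueError("punch diameter and initial height must be positive")

    @property
    def area_m2(self) -> float:
        """Undeformed cross-sectional area π(d/2)² in m²."""
        return np.pi * (self.punch_diameter_mm * 1e-3 / 2.0) ** 2


@dataclass(frozen=True)
class DeformationTest:
    """One raw uniaxial test: force-distance samples plus metadata.

    ``samples`` columns are (time_s, displacement_mm, force_N); time must be
    strictly increasing and displacement magnitude nondecreasing (constant
    crosshead velocity, position controlled).
    """

    mode: str
    velocity_mm_per_min: float
    geometry: SampleGeometry
    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_N: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in ("tension", "compression"):
            raise ValueError(f"mode must be 'tension' or 'compression', got {self.mode!r}")
        if self.velocity_mm_per_min <= 0:
            raise ValueError("velocity must be positive")
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.displacement_mm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if not (t.size and t.size == d.size == f.size):
            raise ValueError("time, displacement and force must be equal-length and nonempty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(np.abs(d)) < -1e-9):
            raise ValueError("displacement magnitude must be nondecreasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "displacement_mm", d)
        object.__setattr__(self, "force_N", f)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering strain vs. nominal stress for one test.

    Strain is nonnegative and starts at 0 regardless of loading direction;
    stress is sign-normalized so the loading direction reads positive.
    """

    strain: np.ndarray
    stress_Pa: np.ndarray
    mode: str
    velocity_mm_per_min: float
    geometry: SampleGeometry | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.strain, dtype=float)
        p = np.asarray(self.stress_Pa, dtype=float)
        if s.size == 0 or s.size != p.size:
            raise ValueError("strain and stress must be equal-length and nonempty")
        if np.any(s < -1e-12):
            raise ValueError("engineering strain must be nonnegative")
        if self.mode not in ("tension", "compression"):
            raise ValueError(f"mode must be 'tension' or 'compression', got {self.mode!r}")
        if s.max() > 0.5 + 1e-9:
            warnings.warn(
                f"maximum strain {s.max():.3f} exceeds the 50% protocol limit", stacklevel=2
            )
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "stress_Pa", p)

    def __len__(self) -> int:
        return self.strain.size

    def stretch(self) -> np.ndarray:
        """Uniaxial stretch λ: 1 + strain in tension, 1 − strain in compression."""
        if self.mode == "tension":
            return 1.0 + self.strain
        return 1.0 - self.strain

    def signed_stress(self) -> np.ndarray:
        """Stress with the physical sign convention (negative in compression)."""
        return self.stress_Pa if self.mode == "tension" else -self.stress_Pa

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain": self.strain, "stress_Pa": self.stress_Pa})


class LinearFit(NamedTuple):
    slope_Pa: float
    intercept_Pa: float
    r_squared: float
    n_points: int


class MaximaResult(NamedTuple):
    global_max: tuple[float, float]  # (strain, stress_Pa)
    local_maxima: list[tuple[float, float]]


def to_stress_strain(
    test: DeformationTest, contact_force_N: float | None = None
) -> StressStrainCurve:
    """Convert a raw force-distance test into a stress-strain curve.

    strain_i = |displacement_i − displacement_contact| / initial height,
    stress_i = force_i / (π (d/2)²), with stress sign-normalized positive in
    the loading direction.

    Parameters
    ----------
    contact_force_N : float, optional
        If given, the record is assumed to include an approach phase: the
        curve is trimmed to the first sample whose |force| exceeds this
        threshold (the machine's ~1 mN contact criterion) and displacement
        is re-zeroed there.  By default the record is taken to start at
        contact, which is how the machine logs a test (contact is
        established during setup, when the sample height is measured).
    """
    d = test.displacement_mm.copy()
    f = test.force_N.copy()
    if contact_force_N is not None:
        above = np.flatnonzero(np.abs(f) > contact_force_N)
        if above.size == 0:
            raise ValueError(
                f"no contact point found: |force| never exceeds {contact_force_N} N"
            )
        i0 = above[0]
        d = d[i0:] - d[i0]
        f = f[i0:]
    strain = np.abs(d - d[0]) / test.geometry.initial_height_mm
    stress = f / test.geometry.area_m2
    # normalize sign so the loading direction is positive (compression rigs
    # report negative force); rupture drops keep their shape
    if stress.sum() < 0:
        stress = -stress
    return StressStrainCurve(
        strain=strain,
        stress_Pa=stress,
        mode=test.mode,
        velocity_mm_per_min=test.velocity_mm_per_min,
        geometry=test.geometry,
    )


def linear_modulus(
    curve: StressStrainCurve, bound: float | None = None, min_points: int = 5
) -> LinearFit:
    """OLS slope of stress vs. strain within the linear regime (strain ≤ bound).

    The slope is the small-strain Young's modulus in Pa.  The intercept is
    free (not forced through the origin).  Default bounds are 0.15 in
    compression and 0.10 in tension.
    """
    if bound is None:
        bound = DEFAULT_LINEAR_BOUND[curve.mode]
    if not 0 < bound <= 0.5:
        raise ValueError(f"linear-regime bound must lie in (0, 0.5], got {bound}")
    mask = curve.strain <= bound
    n = int(mask.sum())
    if n < min_points:
        raise ValueError(
            f"only {n} points at strain ≤ {bound}; need at least {min_points} for regression"
        )
    res = stats.linregress(curve.strain[mask], curve.stress_Pa[mask])
    return LinearFit(
        slope_Pa=float(res.slope),
        intercept_Pa=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=n,
    )


def detect_maxima(curve: StressStrainCurve, prominence_Pa: float = 50.0) -> MaximaResult:
    """Global stress maximum plus interior local maxima above a prominence.

    Local maxima flag rupture-like events: interior peaks whose stress drop
    on both sides exceeds ``prominence_Pa`` (default 50 Pa, below the
    100–200 Pa amplitude of observed local failure events so those are
    caught).
    """
    stress = curve.stress_Pa
    i_max = int(np.argmax(stress))
    peaks, _ = signal.find_peaks(stress, prominence=prominence_Pa)
    local = [(float(curve.strain[i]), float(stress[i])) for i in peaks]
    return MaximaResult(
        global_max=(float(curve.strain[i_max]), float(stress[i_max])),
        local_maxima=local,
    )


# ---------------------------------------------------------------------------
# van der Waals model fitting
# ---------------------------------------------------------------------------


def _equivalent_tension_stretch(phi_value: float) -> float:
    """Tension-side stretch λ > 1 with the same conformation measure Φ.

    A compression excursion λ < 1 constrains λ_m through Φ(λ), not λ itself;
    this maps it onto the equivalent λ > 1 so λ_m bounds can be stated on
    one axis.
    """
    if phi_value <= 0:
        return 1.0
    fun = lambda x: conformation_phi(x) - phi_value
    return float(optimize.brentq(fun, 1.0 + 1e-12, 1e3))


class VanDerWaalsModel:
    """Nonlinear least-squares fit of the van der Waals network stress.

    Parameters
    ----------
    curve : StressStrainCurve
        Processed stress-strain data; the test mode maps strain to stretch
        (λ = 1 ± strain).
    poisson_ratio : float
        ν used for the E = 2G(1+ν) conversion; 0.5 (incompressible) by default.
    linear_bound : float, optional
        Strain bound of the linear regime used for the companion OLS modulus
        and for the shear-modulus starting value; mode default if omitted.

    The free parameters are (G, a, λ_m) with bounds G ∈ (0, 10⁶ Pa],
    a ∈ [0, 20] and λ_m constrained above 1.01× the largest observed stretch
    excursion so that η < 1 holds on every data point throughout the search.
    The loss is unweighted least squares on nominal stress.
    """

    def __init__(
        self,
        curve: StressStrainCurve,
        poisson_ratio: float = 0.5,
        linear_bound: float | None = None,
    ) -> None:
        self.curve = curve
        self.poisson_ratio = float(poisson_ratio)
        self.linear_bound = (
            DEFAULT_LINEAR_BOUND[curve.mode] if linear_bound is None else float(linear_bound)
        )
        self.endog = curve.signed_stress()
        self.exog = curve.stretch()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        mode: str,
        velocity_mm_per_min: float = np.nan,
        strain_col: str = "strain",
        stress_col: str = "stress_Pa",
        **kwargs,
    ) -> "VanDerWaalsModel":
        """Build the model from a tidy DataFrame with strain and stress columns."""
        curve = StressStrainCurve(
            strain=data[strain_col].to_numpy(dtype=float),
            stress_Pa=data[stress_col].to_numpy(dtype=float),
            mode=mode,
            velocity_mm_per_min=velocity_mm_per_min,
        )
        return cls(curve, **kwargs)

    # -- internal -----------------------------------------------------------

    def _bounds_and_start(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam = self.exog
        phi_max = float(np.max(conformation_phi(lam)))
        lam_eq = _equivalent_tension_stretch(phi_max)
        lam_m_lo = max(1.01 * lam_eq, 1.0 + 1e-6)
        lo = np.array([1e-9, 0.0, lam_m_lo])
        hi = np.array([1e6, 20.0, 10.0])
        try:
            g0 = abs(linear_modulus(self.curve, self.linear_bound).slope_Pa) / 3.0
        except ValueError:
            g0 = abs(np.ptp(self.endog)) / max(np.ptp(np.abs(lam - 1.0)), 1e-6) / 3.0
        g0 = float(np.clip(g0, lo[0] * 10, hi[0] / 10))
        x0 = np.array([g0, 2.0, np.clip(1.05 * lam_eq, lam_m_lo * 1.001, hi[2])])
        return lo, hi, x0

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        g, a, lam_m = theta
        try:
            pred = nominal_stress(
                self.exog, VdWParameters(g, a, lam_m, self.poisson_ratio)
            )
        except (BeyondExtensibilityError, ValueError):
            # bounds keep η < 1; this is a numerical-safety penalty only
            return np.full_like(self.endog, 1e9)
        return pred - self.endog

    # -- public -------------------------------------------------------------

    def fit(
        self, n_restarts: int = 5, seed: int = 0, ftol: float = 1e-12, xtol: float = 1e-12
    ) -> "VanDerWaalsResults":
        """Fit (G, a, λ_m) by trust-region-reflective least squares.

        On a poor first solution the optimizer is restarted up to
        ``n_restarts`` times from seeded random points inside the bounds.

        Raises
        ------
        FitError
            For degenerate input (constant stress) or if no restart converges.
        """
        if np.ptp(self.endog) == 0:
            raise FitError("degenerate curve: stress is constant, nothing to fit")
        lo, hi, x0 = self._bounds_and_start()
        rng = np.random.default_rng(seed)
        best = None
        starts = [x0]
        for _ in range(n_restarts):
            g = 10 ** rng.uniform(np.log10(max(x0[0] / 30, lo[0])), np.log10(min(x0[0] * 30, hi[0])))
            a = rng.uniform(0.0, 8.0)
            lm = rng.uniform(lo[2] * 1.001, min(4.0, hi[2]))
            starts.append(np.array([g, a, lm]))
        scale = max(float(np.max(np.abs(self.endog))), 1.0)
        for k, start in enumerate(starts):
            sol = optimize.least_squares(
                self._residuals,
                start,
                bounds=(lo, hi),
                x_scale=[scale / 3.0, 1.0, 0.1],
                ftol=ftol,
                xtol=xtol,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            # stop early once the fit explains the data essentially perfectly
            if best.cost <= 1e-16 * scale**2 * self.endog.size:
                break
        if best is None or not best.success:
            raise FitError("van der Waals fit did not converge after restarts")
        return VanDerWaalsResults(self, best)


class VanDerWaalsResults:
    """Fit results: parameter estimates, uncertainties and diagnostics.

    Attributes
    ----------
    params : VdWParameters
        Point estimates (G in Pa, a, λ_m; ν carried through unfitted).
    bse : ndarray
        Asymptotic standard errors of (G, a, λ_m) from the Gauss–Newton
        covariance s²(JᵀJ)⁻¹.
    young_vdw_Pa : float
        E = 2G(1+ν) from the fitted shear modulus.
    young_linear_Pa : float
        Companion OLS small-strain modulus on the same curve (NaN if the
        linear regime holds too few points).
    """

    _names = ("G_Pa", "a", "lambda_m")

    def __init__(self, model: VanDerWaalsModel, solution) -> None:
        self.model = model
        self._sol = solution
        g, a, lam_m = solution.x
        self.params = VdWParameters(g, a, lam_m, model.poisson_ratio)
        self.rss = float(2.0 * solution.cost)
        self.nobs = int(model.endog.size)
        self.df_resid = self.nobs - 3
        self.converged = bool(solution.success)
        tss = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.r_squared = 1.0 - self.rss / tss if tss > 0 else np.nan
        self.bse = self._standard_errors()
        try:
            self._linfit = linear_modulus(model.curve, model.linear_bound)
            self.young_linear_Pa = abs(self._linfit.slope_Pa)
        except ValueError:
            self._linfit = None
            self.young_linear_Pa = float("nan")

    def _standard_errors(self) -> np.ndarray:
        if self.df_resid <= 0:
            return np.full(3, np.nan)
        j = self._sol.jac
        s2 = self.rss / self.df_resid
        try:
            cov = s2 * np.linalg.inv(j.T @ j)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)

    @property
    def young_vdw_Pa(self) -> float:
        return young_from_shear(self.params)

    @property
    def linear_regime_bound(self) -> float:
        return self.model.linear_bound

    def predict(self, strain=None) -> np.ndarray:
        """Model stress (loading direction positive) at the given strains."""
        if strain is None:
            lam = self.model.exog
        else:
            strain = np.asarray(strain, dtype=float)
            lam = 1.0 + strain if self.model.curve.mode == "tension" else 1.0 - strain
        pred = nominal_stress(lam, self.params)
        return np.abs(pred)

    def to_estimate(self) -> "ModulusEstimate":
        return ModulusEstimate(
            young_linear_Pa=self.young_linear_Pa,
            fit_params=self.params,
            young_vdw_Pa=self.young_vdw_Pa,
            linear_regime_bound=self.linear_regime_bound,
            goodness={
                "rss": self.rss,
                "r_squared": self.r_squared,
                "nobs": self.nobs,
                "converged": self.converged,
            },
        )

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            "van der Waals network fit (uniaxial, nominal stress)",
            "=" * 56,
            f"mode: {self.model.curve.mode:<12} n obs: {self.nobs}",
            f"RSS: {self.rss:.6g} Pa^2    R^2: {self.r_squared:.6f}",
            "-" * 56,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        vals = (self.params.shear_modulus_Pa, self.params.interaction, self.params.limit_stretch)
        for name, v, se in zip(self._names, vals, self.bse):
            lines.append(f"{name:<10}{v:>14.5g}{se:>14.3g}")
        lines += [
            "-" * 56,
            f"E (vdW)    = {self.young_vdw_Pa:.5g} Pa   [E = 2G(1+nu), nu = {self.params.poisson_ratio}]",
            f"E (linear) = {self.young_linear_Pa:.5g} Pa   [strain <= {self.linear_regime_bound}]",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data, the fitted curve and the linear-regime slope."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.strain, c.stress_Pa, ".", ms=2, label="data")
        grid = np.linspace(c.strain.min(), c.strain.max(), 400)
        ax.plot(grid, self.predict(grid), "-", label="van der Waals fit")
        if self._linfit is not None:
            lin = grid[grid <= self.linear_regime_bound]
            ax.plot(
                lin,
                self._linfit.intercept_Pa + self._linfit.slope_Pa * lin,
                "--",
                label=f"linear regime (E = {self.young_linear_Pa:.0f} Pa)",
            )
        ax.set_xlabel("engineering strain")
        ax.set_ylabel("nominal stress [Pa]")
        ax.set_title(f"{c.mode}, {c.velocity_mm_per_min:g} mm/min")
        ax.legend()
        return ax


@dataclass(frozen=True)
class ModulusEstimate:
    """Per-curve modulus report: linear-regime and full-range estimates."""

    young_linear_Pa: float
    fit_params: VdWParameters
    young_vdw_Pa: float
    linear_regime_bound: float
    goodness: dict = field(default_factory=dict)


def fit_vdw(
    curve: StressStrainCurve,
    poisson_ratio: float = 0.5,
    linear_bound: float | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> ModulusEstimate:
    """Fit the van der Waals model to one curve and report both moduli.

    Functional wrapper over :class:`VanDerWaalsModel`; see its docstring for
    bounds, initialization and restart policy.
    """
    model = VanDerWaalsModel(curve, poisson_ratio=poisson_ratio, linear_bound=linear_bound)
    return model.fit(n_restarts=n_restarts, seed=seed).to_estimate()
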