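import numpy as np
import pytest

from lungmech.mech import StressStrainCurve, to_stress_strain
from lungmech.synthetic import MechGenConfig, gen_mech_test
from lungmech.vdw import VdWParameters

# Fetal 7 mm/min compression group: E = 4441 Pa -> G = E/3, a = 3.0, lambda_m = 2.10
FETAL_C7 = VdWParameters(shear_modulus_Pa=4441.0 / 3.0, interaction=3.0, limit_stretch=2.10)


@pytest.fixture(scope="session")
def fetal_c7_params() -> VdWParameters:
    return FETAL_C7


@pytest.fixture(scope="session")
def noiseless_compression_curve(fetal_c7_params) -> StressStrainCurve:
    """Noiseless synthetic compression curve at the fetal 7 mm/min parameters."""
    cfg = MechGenConfig(
        base_params=fetal_c7_params,
        mode="compression",
        velocity_mm_per_min=7.0,
        velocity_stiffening={},
        noise_sd_rel=0.0,
        seed=11,
    )
    return to_stress_strain(gen_mech_test(cfg))


@pytest.fixture(scope="session")
def noiseless_tension_curve(fetal_c7_params) -> StressStrainCurve:
    cfg = MechGenConfig(
        base_params=fetal_c7_params,
        mode="tension",
        velocity_mm_per_min=7.0,
        noise_sd_rel=0.0,
        max_strain=0.5,
        seed=12,
    )
    return to_stress_strain(gen_mech_test(cfg))
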