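import numpy as np
import pytest

from erythrosim import (
    ModelParams,
    PatientParams,
    calibrate_kappa,
    default_specs,
)


@pytest.fixture(scope="session")
def model():
    """Default mechanistic model, kappa calibrated to the healthy anchor."""
    return calibrate_kappa(ModelParams())


@pytest.fixture(scope="session")
def specs():
    """Default cohort generator specs (fitted once per session)."""
    return default_specs()


def make_patient(
    patient_id=1,
    rbc_life_span=76.0,
    endogenous_epo=15.0,
    esa_half_life=20.0,
    apoptosis_sensitivity=30.0,
    maturation_factor=0.5,
) -> PatientParams:
    return PatientParams(
        patient_id=patient_id,
        rbc_life_span=rbc_life_span,
        endogenous_epo=endogenous_epo,
        esa_half_life=esa_half_life,
        apoptosis_sensitivity=apoptosis_sensitivity,
        maturation_factor=maturation_factor,
    )


def random_patients(n: int, seed: int) -> list[PatientParams]:
    """Heterogeneous patients drawn uniformly over plausible ranges."""
    rng = np.random.default_rng(seed)
    return [
        make_patient(
            patient_id=i + 1,
            rbc_life_span=float(rng.uniform(33, 137)),
            endogenous_epo=float(rng.uniform(5, 40)),
            esa_half_life=float(rng.uniform(10, 40)),
            apoptosis_sensitivity=float(rng.uniform(10, 60)),
            maturation_factor=float(rng.uniform(0.0, 1.5)),
        )
        for i in range(n)
    ]
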