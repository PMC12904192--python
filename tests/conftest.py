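import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from efalss.pkmodel import IndividualPK, PopPKParams, Regimen

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> PopPKParams:
    return PopPKParams()


@pytest.fixture(scope="session")
def typical_adult(default_params) -> IndividualPK:
    """Typical non-Asian adult at the 72 kg reference bodyweight."""
    return IndividualPK(cl=default_params.tvcl, v=default_params.tvv)


@pytest.fixture(scope="session")
def bolus_regimen() -> Regimen:
    """Nominal 3600 IU weekly dose in the bolus limit."""
    return Regimen(dose=3600.0, tau=168.0, infusion_duration=1e-6)


@pytest.fixture(scope="session")
def infusion_regimen() -> Regimen:
    return Regimen(dose=3600.0, tau=168.0, infusion_duration=6.0 / 60.0)


def superposition_conc(pk: IndividualPK, reg: Regimen, t: float,
                       n_doses: int = 80) -> float:
    """Independent oracle: explicit sum of single-dose infusion responses
    over ``n_doses`` past administrations."""
    k, cl, d = pk.k, pk.cl, reg.infusion_duration
    r0 = reg.dose / d
    total = 0.0
    for m in range(n_doses):
        tt = t + m * reg.tau
        if tt < d:
            total += (r0 / cl) * (1.0 - math.exp(-k * tt))
        else:
            total += (r0 / cl) * (1.0 - math.exp(-k * d)) * math.exp(-k * (tt - d))
    return total


def bolus_conc(pk: IndividualPK, dose: float, tau: float, t: float) -> float:
    """Steady-state bolus equation, written out independently."""
    k = pk.k
    return dose / pk.v * math.exp(-k * t) / (1.0 - math.exp(-k * tau))


@pytest.fixture(scope="session")
def superposition_oracle():
    return superposition_conc


@pytest.fixture(scope="session")
def bolus_oracle():
    return bolus_conc


def make_subject(params: PopPKParams, weight=72.0, asian=False,
                 eta=(0.0, 0.0), dose=None, infusion_duration=0.1,
                 subject_id=0):
    """Hand-built virtual subject for unit tests."""
    from efalss.cohort import VirtualSubject
    from efalss.pkmodel import individual_params

    pk = individual_params(params, weight, asian, eta)
    reg = Regimen(dose=dose if dose is not None else 50.0 * weight,
                  tau=168.0, infusion_duration=infusion_duration,
                  weight=weight)
    return VirtualSubject(id=subject_id, weight=weight, asian=asian,
                          age_class="adult" if weight >= 45 else "child",
                          eta=np.asarray(eta, float), pk=pk, regimen=reg)


@pytest.fixture(scope="session")
def subject_factory(default_params):
    def factory(**kwargs):
        return make_subject(default_params, **kwargs)
    return factory
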