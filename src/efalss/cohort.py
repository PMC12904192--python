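"""Virtual haemophilia A population generator.

The study population is 10,000 adults plus 2,500 children.  Paediatric
bodyweights follow a truncated normal (mean 35, SD 15, range 3-60 kg).
Adult bodyweights are drawn from a truncated normal calibrated so that the
combined population reproduces the published demographic summary (median
71.7 kg, 5th-95th percentiles 25.2-93.4 kg); only bodyweight and ethnicity
enter the PK model, so the full multivariate covariate dependence structure
of a survey-based simulator is not needed.  About 10.6% of subjects are of
Asian descent, children inheriting the adult proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pkmodel import IndividualPK, PopPKParams, Regimen, individual_params
from .trial import assign_regimen

# Adult bodyweight distribution (kg): truncated normal calibrated to the
# combined-population median and percentile targets.
ADULT_WT_MEAN = 75.5
ADULT_WT_SD = 11.5
ADULT_WT_RANGE = (45.0, 120.0)

# Paediatric bodyweight distribution (kg).
CHILD_WT_MEAN = 35.0
CHILD_WT_SD = 15.0
CHILD_WT_RANGE = (3.0, 60.0)

P_ASIAN = 0.106

N_ADULTS_DEFAULT = 10_000
N_CHILDREN_DEFAULT = 2_500


@dataclass(frozen=True)
class VirtualSubject:
    id: int
    weight: float
    asian: bool
    age_class: str                 # "adult" | "child"
    eta: np.ndarray                # log-scale (eta_CL, eta_V)
    pk: IndividualPK
    regimen: Regimen


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _truncnorm(mean, sd, lo, hi):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def gen_adults(n: int, rng_seed, p_asian: float = P_ASIAN):
    """Adult (weight, asian) pairs; weights i.i.d. truncated normal."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(rng_seed)
    weights = _truncnorm(ADULT_WT_MEAN, ADULT_WT_SD, *ADULT_WT_RANGE).rvs(
        size=n, random_state=rng)
    asian = rng.random(n) < p_asian
    return weights, asian


def gen_children(n: int, rng_seed, p_asian: float = P_ASIAN):
    """Paediatric (weight, asian) pairs; truncated normal(35, 15, [3, 60]) kg."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(rng_seed)
    weights = _truncnorm(CHILD_WT_MEAN, CHILD_WT_SD, *CHILD_WT_RANGE).rvs(
        size=n, random_state=rng)
    asian = rng.random(n) < p_asian
    return weights, asian


def build_population(
    params: PopPKParams,
    n_adults: int = N_ADULTS_DEFAULT,
    n_children: int = N_CHILDREN_DEFAULT,
    rng_seed=0,
    p_asian: float = P_ASIAN,
) -> list[VirtualSubject]:
    """Assemble the virtual cohort with individual PK and dosing regimens.

    Each subject draws eta ~ MVN(0, omega) for the log-scale deviations of
    CL and V, gets covariate-adjusted individual parameters, and is assigned
    50 IU/kg weekly rounded to vial size with a random 1-10 min infusion.
    """
    if n_adults < 0 or n_children < 0:
        raise ValueError("counts must be non-negative")
    rng = _as_rng(rng_seed)
    weights_a, asian_a = (gen_adults(n_adults, rng, p_asian)
                          if n_adults else (np.empty(0), np.empty(0, bool)))
    weights_c, asian_c = (gen_children(n_children, rng, p_asian)
                          if n_children else (np.empty(0), np.empty(0, bool)))
    weights = np.concatenate([weights_a, weights_c])
    asian = np.concatenate([asian_a, asian_c])
    age_class = ["adult"] * n_adults + ["child"] * n_children
    n = n_adults + n_children
    # svd method: tolerates a semi-definite (even zero) omega
    etas = rng.multivariate_normal(
        np.zeros(2), params.omega, size=n
    ) if n else np.empty((0, 2))
    subjects = []
    for i in range(n):
        pk = individual_params(params, weights[i], bool(asian[i]), etas[i])
        reg = assign_regimen(weights[i], rng)
        subjects.append(VirtualSubject(
            id=i, weight=float(weights[i]), asian=bool(asian[i]),
            age_class=age_class[i], eta=etas[i].copy(), pk=pk, regimen=reg,
        ))
    return subjects


POPULATION_COLUMNS = ["id", "age_class", "weight_kg", "asian",
                      "eta_cl", "eta_v", "cl", "v", "dose_iu", "infusion_h"]


def population_to_csv(subjects, path) -> None:
    rows = [[s.id, s.age_class, s.weight, int(s.asian),
             s.eta[0], s.eta[1], s.pk.cl, s.pk.v,
             s.regimen.dose, s.regimen.infusion_duration]
            for s in subjects]
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, index=False)


def population_from_csv(path) -> list[VirtualSubject]:
    df = pd.read_csv(path)
    subjects = []
    for _, r in df.iterrows():
        reg = Regimen(dose=float(r["dose_iu"]), tau=168.0,
                      infusion_duration=float(r["infusion_h"]),
                      weight=float(r["weight_kg"]))
        subjects.append(VirtualSubject(
            id=int(r["id"]), weight=float(r["weight_kg"]),
            asian=bool(r["asian"]), age_class=str(r["age_class"]),
            eta=np.array([r["eta_cl"], r["eta_v"]], dtype=float),
            pk=IndividualPK(cl=float(r["cl"]), v=float(r["v"])),
            regimen=reg,
        ))
    return subjects
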