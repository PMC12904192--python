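"""Monte-Carlo trial simulation: dosing, sampling designs, assay error, censoring.

Every virtual subject receives 50 IU/kg once weekly, rounded to the nearest
vial size (250 IU increments), infused over a random 1-10 minutes.  Samples
are drawn uniformly within the time windows of a sampling strategy, perturbed
by combined proportional + additive assay error, and censored below the
lower limit of quantification (1 IU/dL); negative raw measurements are
likewise treated as censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pkmodel import PopPKParams, Regimen, conc_ss

VIAL_SIZE_IU = 250.0
DOSE_PER_KG = 50.0
TAU_H = 168.0


@dataclass(frozen=True)
class SamplingStrategy:
    """A named set of sampling-time windows (hours post-dose at steady state)."""

    name: str
    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        windows = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", windows)
        prev_end = 0.0
        for start, end in windows:
            if not (0.0 <= start < end <= TAU_H):
                raise ValueError(f"window ({start}, {end}) outside [0, {TAU_H}]")
            if start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return len(self.windows)


def builtin_strategies() -> list[SamplingStrategy]:
    """The reference strategy (RSS, 7 samples) and the ten limited strategies.

    LSS1-2 take a single elimination-phase sample; LSS3-4 two samples;
    LSS5-10 add a peak (15-30 min) and trough (166-168 h) around one mid-
    interval sample that moves later in the week from LSS5 to LSS10.
    """
    peak = (0.25, 0.5)
    trough = (166.0, 168.0)
    mids = [(22.0, 26.0), (46.0, 50.0), (70.0, 74.0),
            (94.0, 98.0), (118.0, 122.0), (142.0, 146.0)]
    out = [
        SamplingStrategy("RSS", (peak, *mids[1:], trough)),
        SamplingStrategy("LSS1", (trough,)),
        SamplingStrategy("LSS2", ((118.0, 122.0),)),
        SamplingStrategy("LSS3", ((118.0, 122.0), trough)),
        SamplingStrategy("LSS4", (peak, trough)),
    ]
    for i, mid in enumerate(mids, start=5):
        out.append(SamplingStrategy(f"LSS{i}", (peak, mid, trough)))
    return out


def get_strategies(names=None) -> list[SamplingStrategy]:
    """Subset the built-in strategies by name (all when ``names`` is None)."""
    all_s = builtin_strategies()
    if names is None:
        return all_s
    by_name = {s.name: s for s in all_s}
    try:
        return [by_name[n] for n in names]
    except KeyError as e:
        raise ValueError(f"unknown strategy name: {e.args[0]}") from None


def assign_regimen(weight: float, rng: np.random.Generator) -> Regimen:
    """50 IU/kg weekly, rounded half-up to the nearest vial, 1-10 min infusion."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    nominal = DOSE_PER_KG * weight
    dose = max(VIAL_SIZE_IU, math.floor(nominal / VIAL_SIZE_IU + 0.5) * VIAL_SIZE_IU)
    duration = rng.uniform(1.0 / 60.0, 10.0 / 60.0)
    return Regimen(dose=dose, tau=TAU_H, infusion_duration=duration, weight=weight)


@dataclass(frozen=True)
class Observation:
    """One measured FVIII activity sample; ``value`` is None when censored."""

    time: float
    value: float | None
    bloq: bool
    loq: float


@dataclass(frozen=True)
class ObservationSet:
    """A subject's samples for one strategy, with array views for fitting."""

    observations: tuple[Observation, ...]

    times: np.ndarray = field(init=False, repr=False, compare=False)
    values: np.ndarray = field(init=False, repr=False, compare=False)
    bloq: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times",
                           np.array([o.time for o in self.observations]))
        object.__setattr__(self, "values",
                           np.array([np.nan if o.bloq else o.value
                                     for o in self.observations], dtype=float))
        object.__setattr__(self, "bloq",
                           np.array([o.bloq for o in self.observations], dtype=bool))

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_bloq(self) -> int:
        return int(self.bloq.sum())


def simulate_observations(
    subject,
    strategy: SamplingStrategy,
    params: PopPKParams,
    rng: np.random.Generator,
    noise: bool = True,
) -> ObservationSet:
    """Draw one sample per window, add residual error, censor below the LOQ.

    ``noise=False`` suppresses the residual error (sample times stay
    random), giving noise-free observations for oracle and recovery tests.
    """
    obs = []
    for start, end in strategy.windows:
        t = rng.uniform(start, end)
        f = conc_ss(subject.pk, subject.regimen, t)
        if noise:
            raw = f * (1.0 + rng.normal(0.0, params.sigma_prop)) \
                + rng.normal(0.0, params.sigma_add)
        else:
            raw = f
        if raw < params.loq:
            obs.append(Observation(time=t, value=None, bloq=True, loq=params.loq))
        else:
            obs.append(Observation(time=t, value=float(raw), bloq=False,
                                   loq=params.loq))
    return ObservationSet(observations=tuple(obs))


# -- NONMEM-style dataset interchange ------------------------------------

NONMEM_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "MDV", "EVID",
                  "BLQ", "LOQ", "WT", "ASN"]


def to_nonmem(subjects, obsets) -> pd.DataFrame:
    """Export subjects + observations as a NONMEM-style event dataset.

    One dose record (EVID=1) at time 0 followed by the observation records
    (EVID=0) per subject.  Censored records carry DV=LOQ with MDV=1 and
    BLQ=1.  Bodyweight and Asian flag ride along so that the dataset is
    self-contained for re-estimation.
    """
    rows = []
    for subject, obset in zip(subjects, obsets, strict=True):
        reg = subject.regimen
        wt, asn = subject.weight, int(subject.asian)
        rows.append([subject.id, 0.0, reg.dose, reg.dose / reg.infusion_duration,
                     0.0, 1, 1, 0, 0.0, wt, asn])
        for o in obset.observations:
            dv = o.loq if o.bloq else o.value
            rows.append([subject.id, o.time, 0.0, 0.0, dv,
                         int(o.bloq), 0, int(o.bloq), o.loq, wt, asn])
    return pd.DataFrame(rows, columns=NONMEM_COLUMNS)


def from_nonmem(source) -> list[dict]:
    """Parse a NONMEM-style dataset (path or DataFrame) back into fit inputs.

    Returns one dict per subject with keys ``id``, ``weight``, ``asian``,
    ``regimen`` and ``observations`` (an :class:`ObservationSet`).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(Path(source))
    out = []
    for sid, grp in df.groupby("ID", sort=True):
        dose_rows = grp[grp["EVID"] == 1]
        if len(dose_rows) != 1:
            raise ValueError(f"subject {sid}: expected exactly one dose record")
        d = dose_rows.iloc[0]
        reg = Regimen(dose=float(d["AMT"]), tau=TAU_H,
                      infusion_duration=float(d["AMT"]) / float(d["RATE"]),
                      weight=float(d["WT"]))
        obs = []
        for _, r in grp[grp["EVID"] == 0].iterrows():
            bloq = bool(r["BLQ"])
            obs.append(Observation(
                time=float(r["TIME"]),
                value=None if bloq else float(r["DV"]),
                bloq=bloq,
                loq=float(r["LOQ"]) if r["LOQ"] > 0 else 1.0,
            ))
        out.append(dict(id=int(sid), weight=float(d["WT"]), asian=bool(d["ASN"]),
                        regimen=reg, observations=ObservationSet(tuple(obs))))
    return out
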