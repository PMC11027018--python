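"""Clinical study protocols and dose-unit handling.

Three acute infusion studies in healthy volunteers drive the calibration
pipeline:

* ``rabelink`` — a stepped ET-1 ramp (0.2, 0.4, 0.8 pmol/kg/min in consecutive
  60-min blocks) after 5 days of a 200 mmol/day sodium diet and an oral water
  load, with renal clearance and urine measurements.
* ``bohm`` — a three-arm crossover (saline, the ET_A antagonist BQ123, the
  ET_B antagonist BQ788) followed by a 4 pmol/kg/min ET-1 challenge for
  20 min, with systemic/renal hemodynamics only.
* ``vml588`` — an ET_A-antagonist dose-response (0, 0.05, 0.2, 0.4 mg/kg/hr)
  with a 1 pmol/kg/min ET-1 challenge at 90 min, urine collected in 30-min
  bins; used for validation and for the refined calibration.

Doses are stored in their native per-kg units and converted with
:func:`convert_dose`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: molar mass of endothelin-1 used for ng <-> pmol conversion (g/mol)
ET1_MOLAR_MASS = 2491.9

_MASS_TO_NG = {"ng": 1.0, "ug": 1e3, "mg": 1e6}
_AMOUNT_TO_PMOL = {"pmol": 1.0, "nmol": 1e3, "umol": 1e6}
_TIME_TO_MIN = {"min": 1.0, "hr": 60.0, "h": 60.0}


def _parse_rate_units(units: str) -> tuple[str, str]:
    """Split e.g. ``'ng/kg/min'`` into its quantity and time parts."""
    parts = units.strip().lower().split("/")
    if len(parts) != 3 or parts[1] != "kg":
        raise ValueError(f"unsupported rate units {units!r}; expected '<q>/kg/<t>'")
    q, _, t = parts
    if q not in _MASS_TO_NG and q not in _AMOUNT_TO_PMOL:
        raise ValueError(f"unsupported quantity unit {q!r}")
    if t not in _TIME_TO_MIN:
        raise ValueError(f"unsupported time unit {t!r}")
    return q, t


def convert_dose(rate: float, from_units: str, to_units: str,
                 molar_mass: float = ET1_MOLAR_MASS) -> float:
    """Convert an infusion rate between per-kg dosing units.

    Mass (ng, ug, mg) and molar (pmol, nmol, umol) quantities interconvert
    through ``molar_mass`` (g/mol); the conversion is exact and linear, so a
    round trip returns the input bit-for-bit up to float rounding.

    >>> round(convert_dose(0.5, "ng/kg/min", "pmol/kg/min"), 1)
    0.2
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    q_from, t_from = _parse_rate_units(from_units)
    q_to, t_to = _parse_rate_units(to_units)

    # normalize to pmol/kg/min (ng/molar_mass = nmol -> *1e3 pmol ... careful:
    # ng / (g/mol) = ng/(1e9 ng/ 1e12 pmol mol) => pmol = ng/molar_mass*1e3)
    if q_from in _AMOUNT_TO_PMOL:
        pmol = rate * _AMOUNT_TO_PMOL[q_from]
    else:
        pmol = rate * _MASS_TO_NG[q_from] / molar_mass * 1e3
    per_min = pmol / _TIME_TO_MIN[t_from]

    if q_to in _AMOUNT_TO_PMOL:
        out = per_min / _AMOUNT_TO_PMOL[q_to]
    else:
        out = per_min * molar_mass / 1e3 / _MASS_TO_NG[q_to]
    return out * _TIME_TO_MIN[t_to]


@dataclass
class DoseEvent:
    """A timed constant-rate infusion of one agent."""

    agent: str
    rate: float          # in `units`, per kg
    units: str           # e.g. "pmol/kg/min", "mg/kg/hr"
    t_start: float       # min
    t_end: float         # min

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        _parse_rate_units(self.units)

    def rate_pmol_per_kg_min(self, molar_mass: float = ET1_MOLAR_MASS) -> float:
        return convert_dose(self.rate, self.units, "pmol/kg/min", molar_mass)


@dataclass
class Protocol:
    """Dosing and measurement schedule for one study arm."""

    study: str
    arm: str = "main"
    events: list[DoseEvent] = field(default_factory=list)
    na_intake_mmol_day: float = 150.0
    water_load_ml_per_kg: float = 0.0
    match_urine_output: bool = False
    extra_water_ml_min: float = 0.0   # e.g. maintenance glucose/saline drip
    t_pre: float = -60.0              # simulation start (min), dosing at t>=0
    t_end: float = 240.0
    #: instantaneous sampling times per output variable (min)
    measurements: dict[str, list[float]] = field(default_factory=dict)
    #: (start, end) collection intervals for urine variables
    urine_bins: list[tuple[float, float]] = field(default_factory=list)
    #: variables reported as bin averages rather than point samples
    urine_variables: list[str] = field(default_factory=list)
    n_subjects: int = 6

    def __post_init__(self):
        for ev in self.events:
            if ev.t_start < self.t_pre or ev.t_end > self.t_end:
                raise ValueError(
                    f"dose event [{ev.t_start}, {ev.t_end}] outside protocol span")
        for var, times in self.measurements.items():
            for t in times:
                if t < self.t_pre or t > self.t_end:
                    raise ValueError(f"measurement time {t} for {var} outside span")
        for (a, b) in self.urine_bins:
            if b <= a or a < self.t_pre or b > self.t_end:
                raise ValueError(f"bad urine bin ({a}, {b})")

    @property
    def label(self) -> str:
        return f"{self.study}:{self.arm}"

    def agents(self) -> set[str]:
        return {ev.agent for ev in self.events}

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["urine_bins"] = [list(b) for b in self.urine_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        d["events"] = [DoseEvent(**e) for e in d.get("events", [])]
        d["urine_bins"] = [tuple(b) for b in d.get("urine_bins", [])]
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Protocol":
        return cls.from_dict(yaml.safe_load(text))


_HEMO_VARS = ["MAP", "RBF", "GFR", "RVR"]


def build_rabelink_protocol() -> Protocol:
    """Stepped ET-1 ramp with water loading and full renal panel.

    The 5-day 200 mmol/day sodium equilibration is represented by
    initializing the model at the steady state for that intake; the 25 mL/kg
    oral water load is absorbed over the 20 min preceding the first
    measurement.
    """
    hemo_times = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 225.0]
    meas = {v: list(hemo_times) for v in _HEMO_VARS}
    meas["plasma_ET1"] = [0.0, 75.0, 125.0, 225.0]
    bins = [(float(a), float(min(a + 30.0, 225.0))) for a in range(0, 225, 30)]
    return Protocol(
        study="rabelink",
        events=[
            DoseEvent("ET1", 0.2, "pmol/kg/min", 0.0, 60.0),
            DoseEvent("ET1", 0.4, "pmol/kg/min", 60.0, 120.0),
            DoseEvent("ET1", 0.8, "pmol/kg/min", 120.0, 180.0),
        ],
        na_intake_mmol_day=200.0,
        water_load_ml_per_kg=25.0,
        match_urine_output=True,
        t_pre=-60.0,
        t_end=225.0,
        measurements=meas,
        urine_bins=bins,
        urine_variables=["urine_flow", "UNaV", "FENa", "FELi"],
        n_subjects=6,
    )


BOHM_ARMS = ("saline", "BQ123", "BQ788")
#: BQ123 was infused at 2.5-5 nmol/kg/min; the upper end is the default.
BQ123_RATE_NMOL_KG_MIN = 5.0


def build_bohm_protocol(arm: str = "saline",
                        bq123_rate: float = BQ123_RATE_NMOL_KG_MIN) -> Protocol:
    """Antagonist pre-treatment followed by a 4 pmol/kg/min ET-1 challenge."""
    if arm not in BOHM_ARMS:
        raise ValueError(f"arm must be one of {BOHM_ARMS}")
    events = [DoseEvent("ET1", 4.0, "pmol/kg/min", 30.0, 50.0)]
    if arm == "BQ123":
        events.insert(0, DoseEvent("BQ123", bq123_rate, "nmol/kg/min", 0.0, 50.0))
    elif arm == "BQ788":
        events.insert(0, DoseEvent("BQ788", 4.0, "nmol/kg/min", 0.0, 15.0))
    # the antagonist-challenge study measured PAH-derived RBF, MAP and RVR
    # (no inulin GFR) alongside plasma ET-1
    times = [0.0, 15.0, 30.0, 40.0, 50.0]
    meas = {v: list(times) for v in ["MAP", "RBF", "RVR", "plasma_ET1"]}
    return Protocol(
        study="bohm",
        arm=arm,
        events=events,
        na_intake_mmol_day=150.0,
        t_pre=-30.0,
        t_end=60.0,
        measurements=meas,
        n_subjects=6,
    )


VML588_DOSES = (0.0, 0.05, 0.2, 0.4)


def build_vml588_protocol(dose_mg_kg_hr: float = 0.0) -> Protocol:
    """ET_A antagonist dose-response with an ET-1 challenge at 90 min.

    Diuresis is maintained (glucose drip plus drink-to-match-output), urine
    is collected in 30-min bins; sodium excretion and lithium clearance
    (fractional lithium excretion) are reported per bin.
    """
    if dose_mg_kg_hr not in VML588_DOSES:
        raise ValueError(f"dose must be one of {VML588_DOSES}")
    events = [DoseEvent("ET1", 1.0, "pmol/kg/min", 90.0, 110.0)]
    if dose_mg_kg_hr > 0:
        events.insert(0, DoseEvent("VML588", dose_mg_kg_hr, "mg/kg/hr", 0.0, 240.0))
    times = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0]
    meas = {v: list(times) for v in _HEMO_VARS}
    bins = [(float(a), float(a + 30.0)) for a in range(0, 240, 30)]
    return Protocol(
        study="vml588",
        arm=f"d{dose_mg_kg_hr:g}",
        events=events,
        na_intake_mmol_day=150.0,
        match_urine_output=True,
        extra_water_ml_min=2.0,
        t_pre=-60.0,
        t_end=240.0,
        measurements=meas,
        urine_bins=bins,
        urine_variables=["UNaV", "FELi"],
        n_subjects=9,
    )


def study_protocols(study: str) -> list[Protocol]:
    """All arms of one study, as simulated for calibration."""
    if study == "rabelink":
        return [build_rabelink_protocol()]
    if study == "bohm":
        return [build_bohm_protocol(a) for a in BOHM_ARMS]
    if study == "vml588":
        return [build_vml588_protocol(d) for d in VML588_DOSES]
    raise ValueError(f"unknown study {study!r}")


ALL_STUDIES = ("rabelink", "bohm", "vml588")
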