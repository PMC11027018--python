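"""Receptor-occupancy -> physiological-effect link functions.

Each candidate mechanism maps the concentration of ET-1 bound to one receptor
(ET_A or ET_B) onto a dimensionless multiplier E applied to one cardiorenal
parameter.  Two functional forms are supported:

linear
    ``E = max(1 + m * (occ - occ0), 0)`` — slope ``m`` per pM of occupancy
    change, clamped at zero so a strong negative effect cannot produce a
    negative parameter.

sigmoidal
    ``E = 1 + m / (1 + exp((occ - occ0) / b)) - m / 2`` — a bounded band of
    total width ``|m|`` centred on 1, with steepness ``b`` (pM).  As written,
    a positive ``m`` makes E *decrease* with occupancy; the sign of ``m``
    carries the direction of the effect (negative slopes are legitimate and
    are reported as such).

Both forms return exactly 1 at the baseline occupancy ``occ0``, so a model
with all mechanisms at baseline is bit-identical to a model with none.

Renal vascular and tubular targets read the *tissue*-compartment occupancy
(renal receptors are tissue-resident); systemic vascular and venous targets
read the *plasma*-compartment occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

RECEPTORS = ("ET_A", "ET_B")

#: parameter targets a mechanism may act on, in kernel order
TARGETS = (
    "preafferent_R",
    "afferent_R",
    "efferent_R",
    "systemic_R",
    "PT_Na_reabsorption",
    "CD_Na_reabsorption",
    "venous_capacitance",
    "venous_compliance",
)

#: targets whose occupancy signal is the plasma (systemic vascular) compartment
PLASMA_TARGETS = frozenset({"systemic_R", "venous_capacitance", "venous_compliance"})

FORMS = ("linear", "sigmoidal")


@dataclass(frozen=True)
class MechanismSpec:
    """One candidate effect arm: receptor -> target with a fitted slope."""

    receptor: str
    target: str
    form: str = "linear"
    m: float = 0.0
    b: float = 1.0        # steepness (pM), sigmoidal only
    ET1R_i0: float = 0.0  # baseline bound concentration (pM)

    def __post_init__(self):
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "sigmoidal" and self.b <= 0:
            raise ValueError("sigmoidal steepness b must be positive")
        if self.ET1R_i0 < 0:
            raise ValueError("baseline occupancy must be non-negative")

    @property
    def compartment(self) -> str:
        return "plasma" if self.target in PLASMA_TARGETS else "tissue"

    @property
    def key(self) -> tuple[str, str]:
        return (self.receptor, self.target)

    @property
    def n_params(self) -> int:
        return 2 if self.form == "sigmoidal" else 1

    def with_params(self, m: float, b: float | None = None) -> "MechanismSpec":
        if b is None:
            return replace(self, m=m)
        return replace(self, m=m, b=b)

    def to_dict(self) -> dict:
        return asdict(self)


def effect_value(mech: MechanismSpec, occupancy: float) -> float:
    """Evaluate the dimensionless multiplier E at a bound concentration (pM)."""
    if occupancy < 0:
        raise ValueError("occupancy must be non-negative")
    d = occupancy - mech.ET1R_i0
    if mech.form == "linear":
        return max(1.0 + mech.m * d, 0.0)
    # exp can overflow for extreme arguments; the asymptote is exact there
    x = d / mech.b
    if x > 700.0:
        return 1.0 - mech.m / 2.0
    if x < -700.0:
        return 1.0 + mech.m / 2.0
    return 1.0 + mech.m / (1.0 + math.exp(x)) - mech.m / 2.0


def apply_effects(mechanisms: list[MechanismSpec],
                  occupancies: dict[tuple[str, str], float]) -> dict[str, float]:
    """Compose active mechanisms into per-target multipliers.

    ``occupancies`` maps ``(receptor, compartment)`` to the current bound
    concentration (pM).  Targets hit by several mechanisms (e.g. the efferent
    arteriole under both receptors) compose multiplicatively, which preserves
    the baseline identity and positivity and is order-independent; untargeted
    parameters get multiplier 1.
    """
    seen: set[tuple[str, str]] = set()
    mult = {t: 1.0 for t in TARGETS}
    for mech in mechanisms:
        if mech.key in seen:
            raise ValueError(f"duplicate mechanism for {mech.key}")
        seen.add(mech.key)
        occ = occupancies[(mech.receptor, mech.compartment)]
        mult[mech.target] *= effect_value(mech, occ)
    return mult


def candidate_set(baseline_occupancies: dict[tuple[str, str], float] | None = None,
                  forms: tuple[str, ...] = FORMS) -> list[MechanismSpec]:
    """The full candidate pool: both receptors x all eight targets x forms.

    Linear templates precede sigmoidal ones so that, at equal objective, the
    selection tie-break prefers the form with fewer parameters.
    """
    cands = []
    for form in forms:
        for receptor in RECEPTORS:
            for target in TARGETS:
                occ0 = 0.0
                if baseline_occupancies is not None:
                    comp = "plasma" if target in PLASMA_TARGETS else "tissue"
                    occ0 = baseline_occupancies[(receptor, comp)]
                cands.append(MechanismSpec(receptor, target, form=form,
                                           b=1.0, ET1R_i0=occ0))
    return cands


# ---------------------------------------------------------------------------
# Reference mechanism presets: the seven arms retained by the selection
# analysis, with slopes from the initial (two-study) and refined (three-study)
# calibrations.  Baseline occupancies are filled in against a kinetic model
# at load time (see CoupledModel.preset_mechanisms).
# ---------------------------------------------------------------------------

_REFINED = [
    ("ET_A", "preafferent_R", 0.288),
    ("ET_A", "PT_Na_reabsorption", 0.0311),
    ("ET_A", "afferent_R", 1.66),
    ("ET_A", "systemic_R", 0.060),
    ("ET_A", "efferent_R", 0.0635),
    ("ET_B", "efferent_R", -0.0059),
    ("ET_B", "systemic_R", 0.0135),
]

_INITIAL = [
    ("ET_A", "preafferent_R", 0.344),
    ("ET_A", "PT_Na_reabsorption", 0.041),
    ("ET_A", "afferent_R", 1.79),
    ("ET_A", "systemic_R", 0.068),
    ("ET_A", "efferent_R", 0.086),
    ("ET_B", "efferent_R", -0.008),
    ("ET_B", "systemic_R", 0.013),
]

PRESETS = {"refined": _REFINED, "initial": _INITIAL}


def preset_mechanisms(name: str = "refined",
                      baseline_occupancies: dict[tuple[str, str], float] | None = None,
                      ) -> list[MechanismSpec]:
    """The seven-mechanism reference set with calibrated linear slopes."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    mechs = []
    for receptor, target, m in PRESETS[name]:
        occ0 = 0.0
        if baseline_occupancies is not None:
            comp = "plasma" if target in PLASMA_TARGETS else "tissue"
            occ0 = baseline_occupancies[(receptor, comp)]
        mechs.append(MechanismSpec(receptor, target, form="linear",
                                   m=m, ET1R_i0=occ0))
    return mechs
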