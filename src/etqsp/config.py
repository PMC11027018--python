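"""Configuration loading and the packaged reference parameter sets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cardiorenal import CardiorenalParams
from .coupled import CoupledModel
from .kinetics import AntagonistSpec, ET1KineticParams


def _read_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        ref = resources.files("etqsp.data") / default_name
        return yaml.safe_load(ref.read_text())
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return yaml.safe_load(p.read_text())


def load_kinetics(path: str | Path | None = None) -> ET1KineticParams:
    return ET1KineticParams(**_read_yaml(path, "reference_kinetics.yaml"))


def load_cardiorenal(path: str | Path | None = None) -> CardiorenalParams:
    """Build cardiorenal parameters from a config of baseline targets.

    The config carries the physiological operating point (``targets``) and
    explicit parameter ``overrides``; dependent parameters (K_f, eta_CD,
    eta_dw) are derived so the operating point is an exact steady state.
    """
    doc = _read_yaml(path, "reference_cardiorenal.yaml")
    kwargs = dict(doc.get("targets", {}))
    kwargs.update(doc.get("overrides", {}))
    return CardiorenalParams.reference(**kwargs)


def load_antagonists(path: str | Path | None = None) -> dict[str, AntagonistSpec]:
    doc = _read_yaml(path, "antagonists.yaml")
    return {name: AntagonistSpec(name=name, **spec) for name, spec in doc.items()}


def reference_model(kinetics_path=None, cardiorenal_path=None,
                    antagonists_path=None, **model_kwargs) -> CoupledModel:
    """The shipped reference parameterization as a ready-to-run model."""
    return CoupledModel(
        kinetics=load_kinetics(kinetics_path),
        cardiorenal_params=load_cardiorenal(cardiorenal_path),
        antagonists=load_antagonists(antagonists_path),
        **model_kwargs)


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
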