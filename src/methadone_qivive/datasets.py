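"""Loaders for the packaged parameter sets.

All physiological, physicochemical, enzymological and reference constants
ship as versioned YAML files inside the package.  Each loader returns plain
dictionaries; higher-level modules turn them into typed parameter objects.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    ref = resources.files("methadone_qivive.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def compound_data() -> dict:
    """Physicochemical/ADME constants for the methadone enantiomers."""
    return _load("compound.yaml")


def physiology_data() -> dict:
    """Reference physiologies per population."""
    return _load("physiology.yaml")


def cyp_data() -> dict:
    """Recombinant-CYP kinetics, ISEFs, f_m,CYP and abundance distributions."""
    return _load("cyp.yaml")


def hlm_data() -> dict:
    """Descriptive statistics of the individual liver-microsome kinetics."""
    return _load("hlm.yaml")


def reference_data() -> dict:
    """Reference CSAF/BMDL constants and therapeutic dosing stages."""
    return _load("reference.yaml")


def invitro_curve_data() -> dict:
    """Parameters of the synthetic in vitro FPDc concentration-response curve."""
    return _load("invitro_curve.yaml")
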