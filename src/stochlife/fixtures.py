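"""Bundled reference parameter sets.

The two studies shipped with the package: the adaptive-heterogeneity sweep
(single risky resource, ``fig2``) and the two-resource utilization problem
(``fig4``).  Both are stored as TOML files under ``stochlife/data`` and
parsed through the same code path as user configs.
"""

from __future__ import annotations

import tomllib
from importlib import resources

from .config import parse_model
from .params import GBMAllometricParams, TwoResourceParams

__all__ = ["fixture_path_text", "fig2_params", "fig4_params"]


def fixture_path_text(name: str) -> str:
    """Raw TOML text of a bundled fixture (``fig2`` or ``fig4``)."""
    return (resources.files("stochlife.data") / f"{name}.toml").read_text()


def fig2_params() -> GBMAllometricParams:
    """Single-resource study parameters (reference sigma1 = 0.5)."""
    model = tomllib.loads(fixture_path_text("fig2"))["model"]
    params = parse_model(model)
    assert isinstance(params, GBMAllometricParams)
    return params


def fig4_params() -> TwoResourceParams:
    """Two-resource utilization study parameters."""
    model = tomllib.loads(fixture_path_text("fig4"))["model"]
    params = parse_model(model)
    assert isinstance(params, TwoResourceParams)
    return params
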