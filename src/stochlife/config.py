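"""TOML run configuration.

A config file holds a ``[model]`` section whose keys match the parameter
field names exactly (``b1``, ``sigma1``, ``x``, ``mu0``, ``f0``, ``rho``,
and optionally ``b2``, ``sigma2`` for the two-resource model), an optional
``[environment]`` section with ``epsilon``, and an optional ``[simulation]``
section passed through to the simulator configurations.  CLI flags override
file values by key.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import ParameterError
from .params import EnvironmentSpec, GBMAllometricParams, TwoResourceParams

__all__ = ["RunConfig", "parse_model", "load_config"]

_GBM_KEYS = {"b1", "sigma1", "x", "mu0", "f0", "rho"}
_TWO_KEYS = _GBM_KEYS | {"b2", "sigma2"}


def parse_model(section: dict) -> Union[GBMAllometricParams, TwoResourceParams]:
    """Build a validated parameter bundle from a ``[model]`` mapping."""
    keys = set(section)
    if keys == _TWO_KEYS:
        return TwoResourceParams(**section)
    if keys == _GBM_KEYS:
        return GBMAllometricParams(**section)
    missing = (_GBM_KEYS - keys) or (_TWO_KEYS - keys)
    extra = keys - _TWO_KEYS
    raise ParameterError(
        f"[model] section keys {sorted(keys)} do not match a parameter "
        f"bundle (missing {sorted(missing)}; unknown {sorted(extra)})"
    )


@dataclass(frozen=True)
class RunConfig:
    """Parsed and validated run configuration."""

    model: Union[GBMAllometricParams, TwoResourceParams]
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    source: Optional[str] = None

    def as_dict(self) -> dict:
        """Echo of the fully resolved configuration (for logging/JSON)."""
        model = {k: getattr(self.model, k) for k in vars(self.model)}
        return {
            "model": model,
            "environment": {"epsilon": self.environment.epsilon},
            "simulation": self.simulation,
            "seed": self.seed,
            "source": self.source,
        }


def load_config(path, overrides: Optional[dict] = None, seed: int = 0) -> RunConfig:
    """Read a TOML file, apply CLI overrides, and validate."""
    raw = tomllib.loads(Path(path).read_text())
    model_section = dict(raw.get("model", {}))
    if overrides:
        model_section.update({k: v for k, v in overrides.items() if v is not None})
    model = parse_model(model_section)
    env = EnvironmentSpec(**raw.get("environment", {"epsilon": 0.0}))
    return RunConfig(
        model=model,
        environment=env,
        simulation=dict(raw.get("simulation", {})),
        seed=seed,
        source=str(path),
    )
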