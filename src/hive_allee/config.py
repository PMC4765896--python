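"""Configuration files and bundled fixture parameter sets.

Configs are flat YAML ``key: value`` mappings. The five social-model
parameters ``lam, theta, alpha, beta, mu`` (or just ``lam, mu`` for the
asocial baseline) plus a small set of run options; anything else is
rejected by name. Loading and saving round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import AsocialParams, SocialParams

__all__ = ["RunConfig", "load_config", "save_config", "fixtures"]

_SOCIAL_KEYS = ("lam", "theta", "alpha", "beta", "mu")
_ASOCIAL_KEYS = ("lam", "mu")
_OPTION_KEYS = ("n0", "t_max", "dt_out", "mode", "seed", "log_level")
_KNOWN_KEYS = set(_SOCIAL_KEYS) | set(_OPTION_KEYS)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters plus optional run settings."""

    params: SocialParams | AsocialParams
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.params.as_dict())
        d.update(self.options)
        return d


def _build_params(raw: dict) -> SocialParams | AsocialParams:
    param_keys = [k for k in raw if k in _SOCIAL_KEYS]
    errors: list[str] = []
    if set(param_keys) == set(_ASOCIAL_KEYS):
        cls, keys = AsocialParams, _ASOCIAL_KEYS
    elif set(param_keys) == set(_SOCIAL_KEYS):
        cls, keys = SocialParams, _SOCIAL_KEYS
    else:
        missing_social = [k for k in _SOCIAL_KEYS if k not in param_keys]
        raise ValueError(
            "config must define either the social parameters "
            f"{_SOCIAL_KEYS} or the asocial parameters {_ASOCIAL_KEYS}; "
            f"missing: {missing_social}"
        )
    vals = {}
    for k in keys:
        v = raw[k]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            errors.append(f"{k}={v!r} is not a number")
        elif v <= 0:
            errors.append(f"{k}={v} must be strictly positive")
        else:
            vals[k] = float(v)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cls(**vals)


def parse_config(raw: dict) -> RunConfig:
    """Validate an already-parsed flat mapping into a :class:`RunConfig`."""
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    params = _build_params(raw)
    options = {k: raw[k] for k in _OPTION_KEYS if k in raw}
    return RunConfig(params=params, options=options)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def fixtures() -> dict[str, SocialParams]:
    """Bundled parameter sets exercising each dynamical case.

    The model's source describes the cases only qualitatively, so these
    values are this package's own, chosen for biologically plausible
    magnitudes: a queen laying up to ~2000 eggs/day, baseline adult
    mortality ~2%/day, and cooperation scales of a few thousand to a few
    tens of thousands of bees.

    * ``case2_default`` — strong Allee effect; critical size ~1257 bees,
      upper stable size ~47743 bees.
    * ``case1`` — a stronger queen (``lam`` raised to 3000/day): weak
      Allee effect, single stable equilibrium, per-capita growth still
      rising at low density.
    * ``case3`` — tenfold baseline mortality: collapse from any size.
    * ``near_fold`` — ``mu`` raised to 0.036/day, just below the fold at
      ``mu* ~ 0.0372``: a shallow, narrow basin about to vanish.
    """
    base = SocialParams(lam=2000.0, theta=16000.0, alpha=0.12, beta=5000.0, mu=0.02)
    return {
        "case2_default": base,
        "case1": base.replace(lam=3000.0),
        "case3": base.replace(mu=0.2),
        "near_fold": base.replace(mu=0.036),
    }
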