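"""YAML configuration mirroring the package defaults.

A config file holds one section per configurable stage; every key is
optional and falls back to the dataclass default:

.. code-block:: yaml

    simulation:
      interference_rate: 0.3
      gradient_minutes: 30.0
    interference:
      tol_ppm: 10.0
      corr_threshold: 0.8
    digest:
      max_missed_cleavages: 1
      charge_range: [2, 4]
    report:
      q_threshold: 0.01
      site_confidence_threshold: 0.75
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .errors import ConfigurationError
from .interference import InterferenceConfig
from .library_builder import DigestParams
from .synthetic_data import SimConfig

_SECTIONS = {
    "simulation": SimConfig,
    "interference": InterferenceConfig,
    "digest": DigestParams,
    "report": None,  # plain keys, validated below
}
_REPORT_KEYS = {"q_threshold", "site_confidence_threshold", "dialect", "phospho_mode"}


def load_config(path) -> dict:
    """Parse a YAML config into instantiated per-stage configurations.

    Unknown sections or keys raise a configuration error rather than
    being silently ignored.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    out: dict = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ConfigurationError(f"unknown config section {section!r}")
        payload = payload or {}
        if section == "report":
            unknown = set(payload) - _REPORT_KEYS
            if unknown:
                raise ConfigurationError(
                    f"unknown report config key(s): {', '.join(sorted(unknown))}"
                )
            out[section] = dict(payload)
            continue
        cls = _SECTIONS[section]
        valid = {f.name for f in fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown {section} config key(s): {', '.join(sorted(unknown))}"
            )
        def _tuplify(v):
            if isinstance(v, list):
                return tuple(_tuplify(x) for x in v)
            return v

        kwargs = {k: _tuplify(v) for k, v in payload.items()}
        out[section] = cls(**kwargs)
    for section, cls in _SECTIONS.items():
        if section not in out:
            out[section] = cls() if cls is not None else {}
    return out
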