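"""Configuration loading, validation, seed derivation and run manifests.

All knobs live in one nested mapping with documented defaults; YAML files
and command-line overrides (dotted keys, e.g. ``train.p_ratio``) are
merged on top, unknown keys are rejected, and the resolved configuration
is echoed to the log. A single master seed (``seed``) derives the
per-subsystem streams via :func:`gclmi.evaluation.derive_seed`.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("gclmi")

__version__ = "0.1.0"

DEFAULTS: dict = {
    "seed": 0,
    "model": {
        "n_latent": 16,      # latent factors; << min(n_lnc, n_mir) for a low-rank bottleneck
        "lambda": 0.1,       # multiplier on the 1/2||.||^2 weight penalties
    },
    "train": {
        "p_ratio": 3.0,      # negatives sampled per positive, each epoch
        "epochs": 1000,
        "lr": 0.005,
    },
    "conv": {
        "dialect": "renormalized",   # or "plain"
        "row_normalize_features": False,
    },
    "eval": {
        "k": 5,
        "repeats": 20,
    },
    "sim": {
        "n_lnc": 120,
        "n_mir": 80,
        "latent_rank": 6,
        "d_lnc": 22,
        "d_mir": 172,
        "density": 0.04,
        "factor_shape": 0.2,
        "feature_noise": 0.5,
    },
    "baseline": {
        "rank": 16,          # SVD / latent-factor rank
        "beta": 0.01,        # Katz attenuation
        "k_max": "closed_form",
        "lam_reg": 0.1,      # latent-factor L2
    },
}

# (validator, message) per dotted key; keys absent here only need to exist.
_VALIDATORS = {
    "seed": (lambda v: isinstance(v, int) and v >= 0, "must be a nonnegative integer"),
    "model.n_latent": (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    "model.lambda": (lambda v: v >= 0, "must be >= 0"),
    "train.p_ratio": (lambda v: v >= 0, "must be >= 0"),
    "train.epochs": (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    "train.lr": (lambda v: v > 0, "must be > 0"),
    "conv.dialect": (lambda v: v in ("renormalized", "plain"),
                     "must be 'renormalized' or 'plain'"),
    "eval.k": (lambda v: isinstance(v, int) and v >= 2, "must be an integer >= 2"),
    "eval.repeats": (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    "sim.density": (lambda v: 0 < v < 1, "must be in (0, 1)"),
    "sim.feature_noise": (lambda v: v >= 0, "must be >= 0"),
    "baseline.beta": (lambda v: v >= 0, "must be >= 0"),
}


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values."""


@dataclass
class RunConfig:
    """Resolved configuration: defaults, then file, then overrides."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def get(self, dotted: str):
        node = self.values
        for part in dotted.split("."):
            node = node[part]
        return node

    def as_dict(self) -> dict:
        return copy.deepcopy(self.values)


def _flat_keys(d: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_flat_keys(v, key + "."))
        else:
            out.append(key)
    return out


_VALID_KEYS = set(_flat_keys(DEFAULTS))


def _set_dotted(values: dict, dotted: str, value) -> None:
    if dotted not in _VALID_KEYS:
        raise ConfigError(
            f"unknown configuration key {dotted!r}; valid keys: "
            + ", ".join(sorted(_VALID_KEYS))
        )
    parts = dotted.split(".")
    node = values
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


def _validate(values: dict) -> None:
    for dotted, (check, msg) in _VALIDATORS.items():
        node = values
        for part in dotted.split("."):
            node = node[part]
        try:
            ok = check(node)
        except TypeError:
            ok = False
        if not ok:
            raise ConfigError(f"invalid value for {dotted}: {node!r} ({msg})")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Merge defaults <- YAML file <- overrides and validate.

    ``overrides`` maps dotted keys to values and wins over the file. An
    empty or missing file yields all defaults. Unknown keys raise
    :class:`ConfigError` listing the valid ones.
    """
    values = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        for key in _flat_keys(loaded):
            node = loaded
            for part in key.split("."):
                node = node[part]
            _set_dotted(values, key, node)
    for key, value in (overrides or {}).items():
        _set_dotted(values, key, value)
    _validate(values)
    cfg = RunConfig(values=values)
    logger.info("resolved configuration: %s", json.dumps(values, sort_keys=True))
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(config: RunConfig, inputs: dict[str, str], out_dir) -> Path:
    """Write ``manifest.json`` recording config, input checksums and seed.

    ``inputs`` maps a role name (e.g. ``interactions``) to a file path.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "gclmi",
        "version": __version__,
        "seed": config.get("seed"),
        "config": config.as_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
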