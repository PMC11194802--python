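"""Configuration, provenance manifests and shared serialisation helpers."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from .constants import CONSTANTS

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "file_checksum",
    "write_manifest",
    "format_number",
]

#: flat configuration registry: "section.key" -> default
DEFAULT_CONFIG: dict[str, Any] = {
    "constants.T": CONSTANTS.T_default,
    "constants.kappa": CONSTANTS.kappa,
    "constants.freq_scale": CONSTANTS.freq_scale,
    "kinetics.T": CONSTANTS.T_default,
    "kinetics.variant": "slow-eigenvalue-approx",
    "kinetics.solvent_fD": 1.0,
    "kinetics.apo_proS_penalty": 0.0,
    "epr.g_iso": 2.0034,
    "epr.microwave_freq_GHz": 9.4,
    "epr.hyperfine_mT": 1.5,
    "epr.linewidth_mT": 0.5,
    "ms.formula": "C11H11O4",
    "ms.n_offsets": 3,
    "gen.seed": 0,
    "gen.noise_rms": 0.0,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Key-value config file (`section.key = value` lines, `#` comments).

    Defaults are overlaid; unknown keys are rejected by name.  Values are
    coerced to the type of the default.
    """
    config = dict(DEFAULT_CONFIG)
    if path is None:
        return config
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in config:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        default = DEFAULT_CONFIG[key]
        try:
            if isinstance(default, bool):
                config[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int) and not isinstance(default, bool):
                config[key] = int(value)
            elif isinstance(default, float):
                config[key] = float(value)
            else:
                config[key] = value
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: cannot parse {value!r} for {key!r}"
            ) from None
    return config


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    output_path: str | Path,
    command: str,
    inputs: Mapping[str, str | Path] | None = None,
    seeds: Mapping[str, int] | None = None,
    variants: Mapping[str, Any] | None = None,
) -> Path:
    """JSON provenance sidecar ``<output>.manifest.json`` for a CLI run."""
    from . import __version__

    manifest = {
        "tool": "grekin",
        "version": __version__,
        "command": command,
        "constants": {
            "kB_J_per_K": CONSTANTS.kB,
            "h_J_s": CONSTANTS.h,
            "R_J_per_mol_K": CONSTANTS.R,
            "NA_per_mol": CONSTANTS.NA,
            "T_default_K": CONSTANTS.T_default,
            "kappa": CONSTANTS.kappa,
            "freq_scale": CONSTANTS.freq_scale,
        },
        "input_checksums": {
            name: file_checksum(p) for name, p in (inputs or {}).items()
        },
        "seeds": dict(seeds or {}),
        "variants": dict(variants or {}),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(str(output_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def format_number(value: float, full_precision: bool = False) -> str:
    """Serialise with explicit precision (6 significant figures by default)."""
    return repr(float(value)) if full_precision else f"{value:.6g}"
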