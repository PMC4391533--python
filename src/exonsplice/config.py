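"""Flat-key configuration covering every documented default.

Config files are plain text, one ``key = value`` pair per line, ``#``
comments allowed.  Unknown keys are rejected with a nearest-key
suggestion so typos never silently fall back to defaults.
"""

from __future__ import annotations

import difflib
from pathlib import Path
from typing import Any

from .ds_methods import ARH_CUTOFF_DEFAULT, Q_MODES, SI_CUTOFF_DEFAULT
from .permutation import PermutationConfig
from .simulator import SimulationConfig

__all__ = ["DEFAULTS", "load_config", "parse_config", "sim_config_from", "perm_config_from"]

DEFAULTS: dict[str, Any] = {
    # KLAS quantile-weight mode: quotient_linear | iqr_log | fixed_1
    "klas.q_mode": "quotient_linear",
    # published decision cutoffs for score methods
    "si.cutoff": SI_CUTOFF_DEFAULT,
    "arh.cutoff": ARH_CUTOFF_DEFAULT,
    # permutation test
    "perm.n": 1000,
    "perm.seed": 0,
    "perm.exhaustive": True,
    # evaluation
    "eval.alpha": 0.05,
    "eval.fdr": False,  # Benjamini-Hochberg across genes, off by default
    # simulator (log2 units)
    "sim.cmean_high": 10.0,
    "sim.cmean_low": 7.0,
    "sim.sigma_sample": 0.5,
    "sim.sigma_exon": 1.0,
    "sim.sigma_noise": 0.3,
    "sim.ds_delta": 2.0,
    "sim.ds_sign": -1,
    "sim.noise_expr_factor": 2.0,
    "sim.n_tp": 100,
    "sim.n_tn": 100,
    "sim.seed": 0,
}


def _coerce(key: str, raw: str) -> Any:
    default = DEFAULTS[key]
    if isinstance(default, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key!r}: expected a boolean, got {raw!r}")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def parse_config(text: str) -> dict[str, Any]:
    """Parse config text into a full key -> value mapping (defaults filled)."""
    values = dict(DEFAULTS)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"config line {lineno}: unknown key {key!r}{suggestion}")
        values[key] = _coerce(key, raw)
    if values["klas.q_mode"] not in Q_MODES:
        raise ValueError(f"klas.q_mode must be one of {Q_MODES}")
    return values


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a config file; with no path, return all documented defaults."""
    if path is None:
        return dict(DEFAULTS)
    return parse_config(Path(path).read_text(encoding="utf-8"))


def sim_config_from(cfg: dict[str, Any], seed: int | None = None) -> SimulationConfig:
    return SimulationConfig(
        cmean_high=cfg["sim.cmean_high"],
        cmean_low=cfg["sim.cmean_low"],
        sigma_sample=cfg["sim.sigma_sample"],
        sigma_exon=cfg["sim.sigma_exon"],
        sigma_noise=cfg["sim.sigma_noise"],
        ds_delta=cfg["sim.ds_delta"],
        ds_sign=cfg["sim.ds_sign"],
        noise_expr_factor=cfg["sim.noise_expr_factor"],
        n_tp=cfg["sim.n_tp"],
        n_tn=cfg["sim.n_tn"],
        seed=cfg["sim.seed"] if seed is None else seed,
    )


def perm_config_from(cfg: dict[str, Any], seed: int | None = None) -> PermutationConfig:
    return PermutationConfig(
        n_perm=cfg["perm.n"],
        seed=cfg["perm.seed"] if seed is None else seed,
        exhaustive=cfg["perm.exhaustive"],
    )
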