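"""Run configuration: plain-text `key = value` files with CLI overrides.

Precedence is CLI flag > config file > built-in default. Modification
lines use ``name:target:delta`` (repeatable keys ``fixed_mod`` and
``variable_mod``). ``mode`` selects the precursor mass-difference gate:
``full`` [-6000, 4500] Da, ``open`` [-150, 500] Da, ``narrow`` a ppm
tolerance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

from .constants import CARBAMIDOMETHYL, OXIDATION
from .proteome import ModificationSpec
from .search import SearchConfig
from .spectra import BinningScheme

__all__ = ["RunConfiguration", "load_config", "DEFAULT_WINDOWS"]

DEFAULT_WINDOWS = {
    "full": (-6000.0, 4500.0),
    "open": (-150.0, 500.0),
}


def default_modifications() -> tuple[ModificationSpec, ...]:
    return (
        ModificationSpec("carbamidomethyl", "C", CARBAMIDOMETHYL, "fixed"),
        ModificationSpec("oxidation", "M", OXIDATION, "variable"),
    )


@dataclass(frozen=True)
class RunConfiguration:
    spectra: str = ""
    fasta: str = ""
    out_dir: str = "pepsearch_out"
    format: str | None = None          # mgf / mzml, inferred from suffix if None
    enzyme: str = r"[KR](?!P)"
    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    modifications: tuple[ModificationSpec, ...] = field(
        default_factory=default_modifications
    )
    mod_cap: int = 20
    open_k: int = 3
    top_k: int = 150
    bin_width: float = 0.02
    bin_offset: float = 0.0
    mode: str = "full"
    delta_m_window: tuple[float, float] | None = None
    tolerance_ppm: float = 20.0
    min_matched_ions: int = 4
    fragment_charges: tuple[int, ...] = (1, 2)
    fdr: float = 0.01
    seed: int = 42
    decoy_prefix: str = "DECOY_"
    threads: int = 1

    def search_config(self) -> SearchConfig:
        window = self.delta_m_window or DEFAULT_WINDOWS.get(self.mode, (-6000.0, 4500.0))
        return SearchConfig(
            top_k=self.top_k,
            scheme=BinningScheme(bin_width=self.bin_width, offset=self.bin_offset),
            min_matched_ions=self.min_matched_ions,
            fragment_charges=self.fragment_charges,
            mode=self.mode,
            delta_m_window=window,
            tolerance_ppm=self.tolerance_ppm,
            threads=self.threads,
        )

    def digest(self) -> str:
        """Stable hash of the configuration for the run log."""
        d = asdict(self)
        d["modifications"] = [list(m.__dict__.values()) for m in self.modifications]
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_INT_KEYS = {
    "missed_cleavages", "min_length", "max_length", "mod_cap", "open_k",
    "top_k", "min_matched_ions", "seed", "threads",
}
_FLOAT_KEYS = {"bin_width", "bin_offset", "tolerance_ppm", "fdr"}


def _parse_mod(value: str, kind: str) -> ModificationSpec:
    parts = value.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"modification must be name:target:delta, got {value!r}"
        )
    name, target, delta = parts
    return ModificationSpec(name.strip(), target.strip(), float(delta), kind)


def load_config(path=None, **overrides) -> RunConfiguration:
    """Build a RunConfiguration from an optional file plus overrides."""
    values: dict = {}
    mods: list[ModificationSpec] = []
    saw_mod_key = False
    if path is not None:
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if key in ("fixed_mod", "variable_mod"):
                saw_mod_key = True
                if val.lower() not in ("", "none"):
                    mods.append(_parse_mod(val, key.split("_")[0]))
            elif key in _INT_KEYS:
                values[key] = int(val)
            elif key in _FLOAT_KEYS:
                values[key] = float(val)
            elif key == "delta_m_window":
                lo, hi = val.split(",")
                values[key] = (float(lo), float(hi))
            elif key == "fragment_charges":
                values[key] = tuple(int(x) for x in val.split(","))
            else:
                values[key] = val
    if saw_mod_key:
        values["modifications"] = tuple(mods)
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfiguration(**values)
    if cfg.mode not in ("full", "open", "narrow"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    return cfg
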