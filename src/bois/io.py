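"""File I/O shared by the modules: CSV writers/readers, YAML config, metadata.

All tabular outputs are RFC-4180 CSV with a header row and "." decimal;
structured configuration is YAML.  Every writer has a matching reader
that round-trips values exactly (floats via repr-precision formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .information import ComplexionDistribution, SwitchComplexion
from .kinetics import DoseResponseCurve
from .mrep import FluxAllocation, SwitchEnsembleSpec

__all__ = [
    "RunConfig",
    "load_config",
    "ensemble_spec_from_config",
    "write_complexions",
    "read_complexions",
    "write_distribution",
    "read_distribution",
    "write_dose_response",
    "read_dose_response",
    "write_flux_allocation",
    "write_run_metadata",
]


@dataclass
class RunConfig:
    """Parameters of one CLI run; everything stochastic carries a seed."""

    subcommand: str
    seed: int = 0
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"subcommand": self.subcommand, "seed": self.seed, "options": self.options}


def load_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping at top level")
    return cfg


def ensemble_spec_from_config(cfg: dict) -> SwitchEnsembleSpec:
    """Build a switch-ensemble spec from config keys
    (n_pdpc, has_gtpc, return_rates, mu, temperature)."""
    return SwitchEnsembleSpec(
        n_pdpc=int(cfg["n_pdpc"]),
        has_gtpc=bool(cfg.get("has_gtpc", False)),
        return_rates=np.asarray(cfg["return_rates"], dtype=float),
        mu=np.asarray(cfg["mu"], dtype=float),
        temperature=float(cfg.get("temperature", 1.0)),
    )


def write_complexions(complexions: list[SwitchComplexion], path) -> None:
    """One row per complexion, one column per switch location."""
    m = complexions[0].n_switches if complexions else 0
    cols = [f"switch_{i + 1}" for i in range(m)]
    df = pd.DataFrame([c.states for c in complexions], columns=cols)
    df.to_csv(path, index=False)


def read_complexions(path) -> list[SwitchComplexion]:
    df = pd.read_csv(path)
    return [SwitchComplexion(tuple(int(v) for v in row)) for row in df.to_numpy()]


def write_distribution(dist: ComplexionDistribution, path) -> None:
    """Two columns: complexion bit-string, probability."""
    df = pd.DataFrame(
        {
            "complexion": [str(c) for c in dist.complexions],
            "probability": dist.probabilities,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_distribution(path) -> ComplexionDistribution:
    df = pd.read_csv(path, dtype={"complexion": str})
    complexions = [SwitchComplexion(tuple(int(ch) for ch in s)) for s in df["complexion"]]
    return ComplexionDistribution(complexions, df["probability"].to_numpy())


def write_dose_response(curves: list[DoseResponseCurve], path, models: list[str] | None = None) -> None:
    """Tidy CSV: columns L, switch_id, on_concentration, event_flag, direction, model."""
    if models is None:
        models = ["bois"] * len(curves)
    frames = []
    for curve, model in zip(curves, models):
        for i, label in enumerate(curve.switch_labels):
            own_events = {lt for lt, idx in curve.activation_events if idx == i}
            frames.append(
                pd.DataFrame(
                    {
                        "L": curve.ligand_grid,
                        "switch_id": label,
                        "on_concentration": curve.responses[i],
                        "event_flag": [int(ell in own_events) for ell in curve.ligand_grid],
                        "direction": curve.direction,
                        "model": model,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_dose_response(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_flux_allocation(alloc: FluxAllocation, path) -> None:
    df = pd.DataFrame(
        {
            "switch": np.arange(1, alloc.per_switch.size + 1),
            "flux": alloc.per_switch,
        }
    )
    if alloc.on_probabilities is not None:
        df["on_probability"] = alloc.on_probabilities
    df.to_csv(path, index=False, float_format="%.17g")


def write_run_metadata(path, config: RunConfig, version: str) -> None:
    """Provenance JSON written beside every CLI output."""
    meta = {"config": config.to_dict(), "version": version}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
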