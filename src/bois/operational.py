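"""Black–Leff Operational model: the smooth, non-hysteretic comparator.

Receptor occupancy drives the switch output through mass action with an
equilibrium ratio K_S = k+/k-:

    R*(L) = K_S L / (L + K_L + K_S L) * R_T

The response is continuous and monotone in L, linear in R_T, saturates at
K_S R_T / (1 + K_S), has EC50 = K_L / (1 + K_S), and returns to zero when
ligand is removed — in each respect the diagnostic contrast with the
stepwise, hysteretic switch-activation model.  With several identical
switches the receptor pool is equipartitioned, so every switch rises
simultaneously and the per-switch maximum shrinks with the switch count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OperationalParams",
    "operational_response",
    "equipartitioned_response",
    "operational_ec50",
]


@dataclass
class OperationalParams:
    """Equilibrium constants and pool size of the Operational model."""

    k_s: float = 1.0  # switch equilibrium ratio k+ / k-
    k_l: float = 1.0  # ligand dissociation constant
    r_t: float = 2.5  # total receptor concentration (R_ref units)
    n_switches: int = 1

    def __post_init__(self) -> None:
        if self.k_s <= 0 or self.k_l <= 0 or self.r_t <= 0:
            raise ValueError("K_S, K_L and R_T must be positive")
        if self.n_switches < 1:
            raise ValueError("at least one switch is required")


def operational_response(ligand, params: OperationalParams):
    """R*(L) = K_S L / (L + K_L + K_S L) * R_T (vectorized in L)."""
    ell = np.asarray(ligand, dtype=float)
    if np.any(ell < 0):
        raise ValueError("ligand concentration must be non-negative")
    out = params.k_s * ell / (ell + params.k_l + params.k_s * ell) * params.r_t
    return out if out.ndim else float(out)


def equipartitioned_response(ligand, params: OperationalParams):
    """Per-switch response with R_T shared equally over n identical switches."""
    per_switch = OperationalParams(
        params.k_s, params.k_l, params.r_t / params.n_switches, 1
    )
    return operational_response(ligand, per_switch)


def operational_ec50(params: OperationalParams) -> float:
    """Ligand concentration at half-maximal response: K_L / (1 + K_S)."""
    return params.k_l / (1.0 + params.k_s)
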