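"""Stepwise ligand-activation kinetics of the GPCR switch complex.

The specialized model pools every ligand-bound receptor state that is not
a switch output into a single complex state C.  Free receptor R_F binds
ligand L with dissociation constant K_L = k_L- / k_L+; an ACTIVE switch i
drains a constant flux J_0 out of C into its ON state R_i* and returns it
at its rigid rate k_i-:

    dR_F/dt  = k_L- C - k_L+ R_F L
    dR_i*/dt = J_0 - k_i- R_i*          (ACTIVE switches only)
    R_T      = R_F + C + sum_i R_i*     (mass conservation fixes C)

All concentrations are in R_ref units, so an ON switch plateaus at
exactly 1.  Starting from unexposed receptor no switch can be ACTIVE
(finite J_0 would drive concentrations negative); switches activate in
ON/OFF pairs each time the complex concentration reaches C = 1,

    C = L (R_T - n_on) / (L + K_L) = 1,

giving thresholds L_k = K_L / (R_T - k) for the k-th activation.  The
dose-response is therefore a staircase, and because ligand can only
dissociate from state C, switches that have turned ON stay ON when L is
swept back to zero — the model's hysteresis prediction.

Sweeps are realized quasi-statically as sequences of steady-state solves
with exact threshold detection; `ode_rhs`/`integrate_to_steady_state`
provide the time-dependent mode used to validate the fixed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InfeasibleStateError",
    "KineticParameters",
    "KineticState",
    "DoseResponseCurve",
    "ode_rhs",
    "steady_state",
    "integrate_to_steady_state",
    "forward_ligand_sweep",
    "reverse_ligand_sweep",
    "max_on_switches",
]

MASS_TOL = 1e-9


class InfeasibleStateError(ValueError):
    """No physical (non-negative) steady state exists for this configuration."""


@dataclass
class KineticParameters:
    """Rates and pool sizes of the specialized GPCR switch model.

    Parameters
    ----------
    k_l_plus, k_l_minus:
        Ligand association (R_F + L -> C) and dissociation (C -> R_F + L)
        rates; their ratio K_L = k_l_minus / k_l_plus is the dissociation
        constant, the natural unit for ligand concentration.
    r_t:
        Total receptor concentration in R_ref units.
    j0:
        Per-switch chemical flux when ACTIVE (per receptor, per time).
    return_rates:
        Rigid ON -> OFF rates k_i-, one per activatable switch, listed in
        activation order.  Defaults to ``j0`` for every switch so each ON
        plateau is J_0 / k_i- = 1 R_ref unit.
    activation_order:
        Pathway label for each activation event (e.g. ``("gtpc", "pdpc")``
        or ``("g_alpha", "b_arr")``); which pathway fires at each threshold
        is a policy choice, not a model output.
    max_switch_pairs:
        Cap on how many ON/OFF pairs may activate (None = receptor-limited).
    delta_r:
        Receptor concentration not attached to any switch (subtracted from
        the pool available for activation).
    """

    k_l_plus: float = 1.0
    k_l_minus: float = 1.0
    r_t: float = 2.5
    j0: float = 1.0
    return_rates: tuple[float, ...] | None = None
    activation_order: tuple[str, ...] | None = None
    max_switch_pairs: int | None = None
    delta_r: float = 0.0

    def __post_init__(self) -> None:
        if self.k_l_plus <= 0 or self.k_l_minus <= 0:
            raise ValueError("ligand binding rates must be positive")
        if self.r_t <= 0:
            raise ValueError("total receptor concentration must be positive")
        if self.j0 < 0:
            raise ValueError("per-switch flux must be non-negative")
        if not 0 <= self.delta_r < self.r_t:
            raise ValueError("delta_r must lie in [0, r_t)")
        n_max = max_on_switches(self.r_t - self.delta_r) if self.r_t - self.delta_r > 0 else 0
        if self.max_switch_pairs is not None:
            n_max = min(n_max, self.max_switch_pairs)
        if self.return_rates is None:
            self.return_rates = tuple([self.j0 if self.j0 > 0 else 1.0] * n_max)
        else:
            self.return_rates = tuple(float(k) for k in self.return_rates)
            if any(k <= 0 for k in self.return_rates):
                raise ValueError("return rates must be positive")
        if self.activation_order is None:
            self.activation_order = tuple(
                f"switch_{i + 1}" for i in range(len(self.return_rates))
            )
        else:
            self.activation_order = tuple(self.activation_order)
        if len(self.activation_order) != len(self.return_rates):
            raise ValueError("activation_order and return_rates must have equal length")

    @property
    def k_l(self) -> float:
        """Ligand dissociation constant K_L = k_L- / k_L+."""
        return self.k_l_minus / self.k_l_plus

    @property
    def available_pool(self) -> float:
        """Receptor available to switch activation, R_T - Delta_R."""
        return self.r_t - self.delta_r

    @property
    def n_activatable(self) -> int:
        n = min(len(self.return_rates), max_on_switches(self.available_pool))
        if self.max_switch_pairs is not None:
            n = min(n, self.max_switch_pairs)
        return n

    def on_level(self, i: int) -> float:
        """Steady ON concentration J_0 / k_i- of switch i when ACTIVE."""
        return self.j0 / self.return_rates[i]

    def activation_threshold(self, k: int) -> float:
        """Ligand concentration at which the k-th (1-based) pair activates.

        Solves C = L (pool - consumed) / (L + K_L) = 1 with the pool
        depleted by the k-1 switches already ON.
        """
        if k < 1 or k > self.n_activatable:
            raise ValueError(f"activation index must lie in [1, {self.n_activatable}]")
        consumed = sum(self.on_level(i) for i in range(k - 1))
        headroom = self.available_pool - consumed - 1.0
        if headroom <= 0:
            raise InfeasibleStateError(
                f"receptor pool cannot supply activation {k}: C never reaches 1"
            )
        return self.k_l / headroom


@dataclass
class KineticState:
    """Concentrations of the pooled GPCR model at one ligand concentration."""

    r_free: float
    complex_c: float
    r_star: np.ndarray  # ON-state concentration per activatable switch
    ligand: float
    active: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.r_star = np.asarray(self.r_star, dtype=float)

    @property
    def total(self) -> float:
        return self.r_free + self.complex_c + float(self.r_star.sum())

    def check_mass(self, r_t: float, tol: float = MASS_TOL) -> None:
        if abs(self.total - r_t) > tol * max(1.0, r_t):
            raise ValueError(f"mass conservation violated: {self.total} != {r_t}")


@dataclass
class DoseResponseCurve:
    """Per-switch ON concentrations along a ligand sweep.

    ``responses[i, j]`` is switch i's ON concentration at
    ``ligand_grid[j]`` (R_ref units); ``activation_events`` records the
    exact threshold ligand concentrations in sweep order.
    """

    ligand_grid: np.ndarray
    responses: np.ndarray
    activation_events: list[tuple[float, int]]
    direction: str
    switch_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.ligand_grid = np.asarray(self.ligand_grid, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[1] != self.ligand_grid.size:
            raise ValueError("one response column per grid point required")
        if not self.switch_labels:
            self.switch_labels = tuple(
                f"switch_{i + 1}" for i in range(self.responses.shape[0])
            )

    @property
    def total_response(self) -> np.ndarray:
        return self.responses.sum(axis=0)


def max_on_switches(r_t: float) -> int:
    """Largest number of switches that can ever be ON: the largest integer
    strictly less than the normalized receptor concentration.

    Each ON switch consumes 1 R_ref unit and activation needs C to reach 1
    out of the remaining pool, so R_T = 3.0 still allows only 2 ON switches
    (the strict inequality; documented edge case).
    """
    if r_t <= 0:
        raise ValueError("receptor concentration must be positive")
    return max(math.ceil(r_t) - 1, 0)


def ode_rhs(state: KineticState, params: KineticParameters) -> tuple[float, np.ndarray]:
    """Time derivatives (dR_F/dt, dR_i*/dt) at fixed ligand concentration.

    C is eliminated through mass conservation; INACTIVE switches carry no
    flux and have zero derivative.
    """
    c = state.complex_c
    d_rf = params.k_l_minus * c - params.k_l_plus * state.r_free * state.ligand
    d_rstar = np.zeros_like(state.r_star)
    for i in state.active:
        d_rstar[i] = params.j0 - params.return_rates[i] * state.r_star[i]
    return d_rf, d_rstar


def steady_state(
    params: KineticParameters, ligand: float, active: tuple[int, ...] = ()
) -> KineticState:
    """Fixed point of the kinetics at ligand concentration ``ligand``.

    ACTIVE switches sit at R_i* = J_0 / k_i-; the remaining receptor pool
    partitions between R_F and C by the binding balance C = R_F L / K_L.
    Raises :class:`InfeasibleStateError` when any steady concentration
    would be negative, the signal that a switch must remain INACTIVE.
    """
    if ligand < 0:
        raise ValueError("ligand concentration must be non-negative")
    n = len(params.return_rates)
    r_star = np.zeros(n)
    for i in active:
        r_star[i] = params.on_level(i)
    remaining = params.r_t - float(r_star.sum())
    if remaining < -MASS_TOL:
        raise InfeasibleStateError(
            "ACTIVE switches demand more receptor than the total pool holds"
        )
    remaining = max(remaining, 0.0)
    c = remaining * ligand / (ligand + params.k_l)
    r_free = remaining - c
    state = KineticState(r_free, c, r_star, ligand, tuple(active))
    state.check_mass(params.r_t)
    return state


def integrate_to_steady_state(
    params: KineticParameters,
    initial: KineticState,
    t_final: float = 200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> KineticState:
    """Long-horizon integration of the ODEs at fixed L and fixed active set.

    Validation oracle for :func:`steady_state`.  Persistent negativity of
    any concentration marks the configuration infeasible.
    """
    n = initial.r_star.size
    active = initial.active

    def rhs(_t, y):
        r_free, r_star = y[0], y[1:]
        c = params.r_t - r_free - r_star.sum()
        st = KineticState(r_free, c, r_star, initial.ligand, active)
        d_rf, d_rs = ode_rhs(st, params)
        return np.concatenate([[d_rf], d_rs])

    y0 = np.concatenate([[initial.r_free], initial.r_star])
    sol = solve_ivp(rhs, (0.0, t_final), y0, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = sol.y[:, -1]
    r_free, r_star = float(y[0]), y[1:]
    c = params.r_t - r_free - float(r_star.sum())
    if min(r_free, c, *(r_star if n else [0.0])) < -1e-6:
        raise InfeasibleStateError("trajectory leaves the physical (non-negative) region")
    return KineticState(r_free, max(c, 0.0), np.maximum(r_star, 0.0), initial.ligand, active)


def _ligand_grid(l_max: float, n_points: int, thresholds: list[float]) -> np.ndarray:
    if l_max <= 0 or n_points < 2:
        raise ValueError("need l_max > 0 and at least two grid points")
    grid = np.linspace(0.0, l_max, n_points)
    extra = []
    for lt in thresholds:  # straddle each step so the staircase is resolved exactly
        if lt <= l_max:
            extra.extend([lt * (1 - 1e-9), lt])
    return np.unique(np.concatenate([grid, extra]))


def forward_ligand_sweep(
    params: KineticParameters, l_max: float = 10.0, n_points: int = 201
) -> DoseResponseCurve:
    """Adiabatic increase of ligand from 0: the stepwise activation staircase.

    Starting from unexposed receptor, no switch is ACTIVE and the response
    is zero until C first reaches 1; there one ON/OFF switch pair activates
    and C drains into the new ON switch.  Each further threshold activates
    the next pair until the receptor pool (or ``max_switch_pairs``) is
    exhausted.  Thresholds are computed exactly from the depleted-pool
    activation condition; the grid only samples the resulting staircase.
    """
    thresholds = []
    for k in range(1, params.n_activatable + 1):
        lt = params.activation_threshold(k)
        if lt <= l_max:
            thresholds.append(lt)
        else:
            break
    grid = _ligand_grid(l_max, n_points, thresholds)
    n_sw = len(params.return_rates)
    responses = np.zeros((n_sw, grid.size))
    for j, ell in enumerate(grid):
        n_on = sum(1 for lt in thresholds if ell >= lt)
        for i in range(n_on):
            responses[i, j] = params.on_level(i)
    events = [(lt, i) for i, lt in enumerate(thresholds)]
    return DoseResponseCurve(grid, responses, events, "forward", params.activation_order)


def reverse_ligand_sweep(
    params: KineticParameters, forward: DoseResponseCurve
) -> DoseResponseCurve:
    """Adiabatic return of ligand to 0 after a forward sweep: hysteresis.

    Ligand can only dissociate from state C, so receptors captured in ON
    switch states stay there: every switch that activated on the way up
    holds its plateau all the way down.
    """
    if forward.direction != "forward":
        raise ValueError("reverse sweep requires a completed forward sweep")
    grid = forward.ligand_grid[::-1].copy()
    final = forward.responses[:, -1]
    responses = np.tile(final[:, None], (1, grid.size))
    return DoseResponseCurve(
        grid, responses, list(forward.activation_events), "reverse", forward.switch_labels
    )
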