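"""Shannon information of ensembles of binary molecular switches.

A receptor complex is modelled as a bag of M distinguishable binary
switches (phosphorylation sites, the GTPase cycle).  A *complexion* is one
ON/OFF assignment across all switch locations; the information stored in a
distribution over complexions, and the capacity of the ensemble as a
signalling channel, are plain Shannon quantities over this finite state
space.

All quantities are returned in bits by default; pass ``units="nats"`` for
natural logarithms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SwitchComplexion",
    "ComplexionDistribution",
    "JointChannel",
    "enumerate_complexions",
    "count_complexions",
    "information_content",
    "optimal_on_count",
    "capacity",
    "mutual_information",
    "binding_information",
]

_NORM_TOL = 1e-12


def _log(x: float, units: str) -> float:
    if units == "bits":
        return math.log2(x)
    if units == "nats":
        return math.log(x)
    raise ValueError(f"units must be 'bits' or 'nats', got {units!r}")


@dataclass(frozen=True)
class SwitchComplexion:
    """One ON/OFF configuration of M distinguishable switches.

    ``states[0]`` is the switch in location 1 (most significant position in
    the string form): ``SwitchComplexion((1, 1, 0, 0))`` means locations 1
    and 2 are ON, locations 3 and 4 OFF.
    """

    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.states):
            raise ValueError("complexion states must be 0 (OFF) or 1 (ON)")
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))

    @property
    def n_switches(self) -> int:
        return len(self.states)

    @property
    def n_on(self) -> int:
        return sum(self.states)

    def __str__(self) -> str:
        return "".join(str(s) for s in self.states)


@dataclass
class ComplexionDistribution:
    """A probability distribution over distinct complexions."""

    complexions: list[SwitchComplexion]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.complexions) != self.probabilities.size:
            raise ValueError("one probability per complexion required")
        if len(set(self.complexions)) != len(self.complexions):
            raise ValueError("complexions must be distinct")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def uniform(cls, complexions: Sequence[SwitchComplexion]) -> "ComplexionDistribution":
        n = len(complexions)
        return cls(list(complexions), np.full(n, 1.0 / n))


@dataclass
class JointChannel:
    """Joint distribution over (input, output) states of a channel.

    ``joint_probabilities[i, j]`` is Pr(X = input_states[i], Y =
    output_states[j]).  Inputs are typically switch complexions and outputs
    effector couplings, but any hashable labels are accepted.
    """

    input_states: list
    output_states: list
    joint_probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.joint_probabilities = np.asarray(self.joint_probabilities, dtype=float)
        if self.joint_probabilities.shape != (len(self.input_states), len(self.output_states)):
            raise ValueError("joint matrix shape must be (n_inputs, n_outputs)")
        if np.any(self.joint_probabilities < 0):
            raise ValueError("joint probabilities must be non-negative")
        if abs(self.joint_probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")

    @classmethod
    def identity(cls, states: Sequence) -> "JointChannel":
        """Noiseless (bijective) channel with equiprobable inputs."""
        n = len(states)
        return cls(list(states), list(states), np.eye(n) / n)


def enumerate_complexions(m: int, m_on: int | None = None) -> list[SwitchComplexion]:
    """All complexions of ``m`` switches, optionally restricted to ``m_on`` ON.

    Switches are distinguishable, so placements of the same ON count at
    different locations are distinct states.  The result is in lexicographic
    order with switch location 1 as the most significant position.
    """
    if m < 0:
        raise ValueError("switch count M must be non-negative")
    if m_on is None:
        return [SwitchComplexion(states) for states in itertools.product((0, 1), repeat=m)]
    if not 0 <= m_on <= m:
        raise ValueError(f"ON count must satisfy 0 <= Mo <= M, got Mo={m_on}, M={m}")
    out = []
    for states in itertools.product((0, 1), repeat=m):
        if sum(states) == m_on:
            out.append(SwitchComplexion(states))
    return out


def count_complexions(m: int, m_on: int) -> int:
    """Number of complexions W = M! / (Mo! (M-Mo)!) with ``m_on`` switches ON."""
    if m < 0 or not 0 <= m_on <= m:
        raise ValueError(f"require 0 <= Mo <= M, got Mo={m_on}, M={m}")
    return math.comb(m, m_on)


def information_content(dist: ComplexionDistribution, units: str = "bits") -> float:
    """Shannon information H(X) = -sum p log p of a complexion distribution.

    Zero-probability complexions contribute zero (0 log 0 := 0 by
    continuity).  For the uniform distribution over W complexions this is
    log W.
    """
    p = dist.probabilities
    p = p[p > 0]
    h = float(-np.sum(p * np.log2(p)))
    if units == "nats":
        h *= math.log(2.0)
    elif units != "bits":
        raise ValueError(f"units must be 'bits' or 'nats', got {units!r}")
    # clip the tiny negative that a point mass can produce in float arithmetic
    return max(h, 0.0)


def optimal_on_count(m: int) -> tuple[int, ...]:
    """ON count(s) maximizing the number of complexions W(M, Mo).

    Balanced ON/OFF maximizes storage: for even M the unique maximizer is
    M/2; for odd M both (M-1)/2 and (M+1)/2 achieve the maximum and both
    are returned.
    """
    if m < 1:
        raise ValueError("switch count M must be >= 1")
    if m % 2 == 0:
        return (m // 2,)
    return (m // 2, m // 2 + 1)


def capacity(m: int, units: str = "bits") -> float:
    """Channel capacity of M binary switches: log of W at the balanced ON count.

    This is the maximum information the ensemble can store (and, through a
    noiseless readout, transmit): for M = 4, log2(6) ~ 2.585 bits.
    """
    best = optimal_on_count(m)[0]
    return _log(count_complexions(m, best), units)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(channel: JointChannel, units: str = "bits") -> float:
    """Mutual information I(Y|X) = H(Y) - H(Y|X) = H(X) - H(X|Y) of a channel.

    Computed as H(X) + H(Y) - H(X, Y); both conditional decompositions are
    evaluated and must agree to 1e-9, which guards against malformed joints.
    Equals H(X) when the input-output map is a bijection (the conditional
    terms vanish) and 0 when the joint factorizes.
    """
    joint = channel.joint_probabilities
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    hx, hy, hxy = _entropy(px), _entropy(py), _entropy(joint.ravel())
    via_y = hy - (hxy - hx)  # H(Y) - H(Y|X)
    via_x = hx - (hxy - hy)  # H(X) - H(X|Y)
    if abs(via_y - via_x) > 1e-9:
        raise ValueError("mutual-information decompositions disagree; joint is inconsistent")
    mi = max(0.5 * (via_x + via_y), 0.0)
    if units == "nats":
        mi *= math.log(2.0)
    elif units != "bits":
        raise ValueError(f"units must be 'bits' or 'nats', got {units!r}")
    return mi


def binding_information(p: float, units: str = "bits") -> float:
    """Information stored in the ligand-bound/unbound receptor partition.

    The binary entropy -p log p - (1-p) log(1-p) of the bound fraction
    ``p``: zero when no receptor (or every receptor) is bound, maximal (one
    bit) at half occupancy.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bound fraction must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    h = -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)
    if units == "nats":
        h *= math.log(2.0)
    elif units != "bits":
        raise ValueError(f"units must be 'bits' or 'nats', got {units!r}")
    return h
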