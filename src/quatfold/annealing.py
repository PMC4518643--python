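"""Data-fit objective and Metropolis simulated-annealing sampler.

The data fit is Phi(C) = sum over (i, j) in L of n_ij * d_ij: each pair in
the fit set pulls its beads together with a strength proportional to the
observed contact count.  No contact-to-distance conversion is involved;
configurations with every listed pair coincident are unconstrained
minimisers, and it is the geometric constraints that keep the solutions
plausible.  The sampler proposes single-coordinate pivot moves, accepts by
the Metropolis rule at a geometrically decreasing temperature, and rejects
outright any proposal that violates the constraints.  It is deliberately
not a global optimiser: independent seeded runs are the ensemble
mechanism, and distinct runs with similar low Phi are all plausible
solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import Chain, ConstraintSet, check_constraints
from .contact_data import FitSet
from .moves import (
    DegenerateGeometryError,
    perturb_bond_length,
    perturb_dihedral_angle,
    perturb_planar_angle,
)

__all__ = [
    "AnnealingSchedule",
    "AnnealTrace",
    "MoveDescriptor",
    "data_fit",
    "metropolis_accept",
    "propose_move",
    "anneal",
]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Cooling schedule and proposal magnitudes.

    t0=None auto-calibrates the starting temperature with a short pilot so
    that roughly `pilot_accept` of the initial uphill moves are accepted;
    t_min=None stops at t0 / 1000.  Cooling is geometric, T <- alpha * T
    per sweep.  The run also stops after `max_sweeps` sweeps or after
    `stall_sweeps` consecutive sweeps without a single acceptance.
    max_bond_delta is in nm; when None, bond proposals use
    `bond_delta_frac` of the current bond length.
    """

    t0: float | None = None
    alpha: float = 0.98
    t_min: float | None = None
    max_sweeps: int = 400
    moves_per_sweep: int | None = None
    max_planar_delta: float = 15.0
    max_dihedral_delta: float = 30.0
    max_bond_delta: float | None = None
    bond_delta_frac: float = 0.05
    stall_sweeps: int = 50
    pilot_accept: float = 0.8
    pilot_moves: int = 60

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.t_min is not None:
            if self.t_min <= 0:
                raise ValueError("t_min must be positive")
            if self.t0 is not None and not self.t_min < self.t0:
                raise ValueError("t_min must be below t0")
        for name in ("max_planar_delta", "max_dihedral_delta", "bond_delta_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_bond_delta is not None and self.max_bond_delta <= 0:
            raise ValueError("max_bond_delta must be positive")


@dataclass(frozen=True)
class MoveDescriptor:
    kind: str  # "planar" | "dihedral" | "bond"
    site: int
    delta: float


@dataclass
class AnnealTrace:
    """Per-sweep sampling record; best Phi is non-increasing by construction."""

    sweeps: list[int] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    phi_current: list[float] = field(default_factory=list)
    phi_best: list[float] = field(default_factory=list)
    acceptance_rate: list[float] = field(default_factory=list)
    seed: int | None = None
    stop_reason: str = ""

    def record(self, sweep, t, phi_c, phi_b, acc):
        self.sweeps.append(int(sweep))
        self.temperature.append(float(t))
        self.phi_current.append(float(phi_c))
        self.phi_best.append(float(phi_b))
        self.acceptance_rate.append(float(acc))

    @property
    def phi_initial(self) -> float:
        return self.phi_current[0] if self.phi_current else float("nan")

    @property
    def phi_final_best(self) -> float:
        return self.phi_best[-1] if self.phi_best else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep": self.sweeps,
                "T": self.temperature,
                "phi_current": self.phi_current,
                "phi_best": self.phi_best,
                "acceptance_rate": self.acceptance_rate,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def data_fit(chain: Chain, fitset: FitSet) -> float:
    """Phi(C) = sum_{(i,j) in L} n_ij * ||x_i - x_j|| over bead centroids (nm)."""
    i, j, n = fitset.arrays()
    if len(i) == 0:
        return 0.0
    cent = chain.centroids
    d = np.linalg.norm(cent[i] - cent[j], axis=1)
    return float(np.dot(n, d))


def metropolis_accept(
    phi_current: float, phi_proposed: float, t: float, rng: np.random.Generator
) -> bool:
    """Accept downhill moves always, uphill with probability exp(-dPhi / T)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if phi_proposed < phi_current:
        return True
    return rng.random() < math.exp((phi_current - phi_proposed) / t)


def _applicable_move_kinds(chain: Chain) -> list[str]:
    kinds = []
    if chain.free_vertices().any():
        kinds.append("planar")
    if chain.n_points >= 4:
        kinds.append("dihedral")
    if chain.free_segments().any():
        kinds.append("bond")
    return kinds


def propose_move(
    chain: Chain,
    schedule: AnnealingSchedule,
    rng: np.random.Generator,
    *,
    max_retries: int = 30,
) -> tuple[Chain, MoveDescriptor]:
    """One random single-coordinate perturbation of the chain.

    The move type is chosen uniformly among the applicable types, the site
    uniformly among that type's sites, and the delta uniformly in its
    +-max range.  Degenerate sites (collinear geometry) are resampled up to
    `max_retries` times before DegenerateGeometryError propagates.
    """
    if chain.n_beads < 2:
        raise ValueError("cannot perturb a chain with fewer than 2 beads")
    kinds = _applicable_move_kinds(chain)
    if not kinds:
        raise ValueError("chain has no perturbable coordinate")
    free_v = np.nonzero(chain.free_vertices())[0] + 1
    free_s = np.nonzero(chain.free_segments())[0]
    last_err: Exception | None = None
    for _ in range(max_retries):
        kind = kinds[rng.integers(len(kinds))]
        try:
            if kind == "planar":
                site = int(free_v[rng.integers(len(free_v))])
                delta = float(rng.uniform(-schedule.max_planar_delta, schedule.max_planar_delta))
                return perturb_planar_angle(chain, site, delta), MoveDescriptor(kind, site, delta)
            if kind == "dihedral":
                site = int(rng.integers(1, chain.n_points - 2))
                delta = float(
                    rng.uniform(-schedule.max_dihedral_delta, schedule.max_dihedral_delta)
                )
                return perturb_dihedral_angle(chain, site, delta), MoveDescriptor(kind, site, delta)
            site = int(free_s[rng.integers(len(free_s))])
            if schedule.max_bond_delta is not None:
                mag = schedule.max_bond_delta
            else:
                mag = schedule.bond_delta_frac * float(chain.bond_lengths()[site])
            delta = float(rng.uniform(-mag, mag))
            return perturb_bond_length(chain, site, delta), MoveDescriptor(kind, site, delta)
        except DegenerateGeometryError as err:
            last_err = err
            continue
    raise DegenerateGeometryError(
        f"no valid move found in {max_retries} attempts"
    ) from last_err


def _calibrate_t0(chain, fitset, schedule, rng) -> float:
    """Pilot run: pick T0 so ~pilot_accept of initial uphill moves are accepted."""
    phi0 = data_fit(chain, fitset)
    uphill = []
    for _ in range(schedule.pilot_moves):
        try:
            proposal, _move = propose_move(chain, schedule, rng)
        except DegenerateGeometryError:
            continue
        dphi = data_fit(proposal, fitset) - phi0
        if dphi > 0:
            uphill.append(dphi)
    if not uphill:
        return 1.0
    return max(float(np.median(uphill)) / math.log(1.0 / schedule.pilot_accept), 1e-12)


def anneal(
    chain: Chain,
    fitset: FitSet,
    constraints: ConstraintSet,
    schedule: AnnealingSchedule,
    rng: np.random.Generator,
    *,
    feasible: "callable | None" = None,
) -> tuple[Chain, AnnealTrace]:
    """Simulated annealing on Phi with hard constraint rejection.

    Proposals that violate the constraints never enter the chain; the
    best-Phi feasible configuration seen is returned together with the
    per-sweep trace.  `feasible` overrides the default feasibility test
    (empty check_constraints report) -- the multiscale driver passes a
    checker that composes the rigid subchains and validates the finest
    level.  The initial chain must be feasible.
    """
    if feasible is None:
        feasible = lambda c: check_constraints(c, constraints).ok  # noqa: E731
    if not feasible(chain):
        raise ValueError("initial chain violates the constraints")
    current = chain
    phi_current = data_fit(current, fitset)
    best = current
    phi_best = phi_current
    if chain.n_beads < 2 or not _applicable_move_kinds(chain):
        trace = AnnealTrace()
        trace.record(0, schedule.t0 or 1.0, phi_current, phi_best, 0.0)
        trace.stop_reason = "no_moves"
        return best, trace
    t = schedule.t0 if schedule.t0 is not None else _calibrate_t0(chain, fitset, schedule, rng)
    t_min = schedule.t_min if schedule.t_min is not None else t / 1000.0
    moves_per_sweep = (
        schedule.moves_per_sweep
        if schedule.moves_per_sweep is not None
        else max(10 * chain.n_points, 20)
    )
    trace = AnnealTrace()
    trace.record(0, t, phi_current, phi_best, 0.0)
    stalled = 0
    for sweep in range(1, schedule.max_sweeps + 1):
        accepted = 0
        for _ in range(moves_per_sweep):
            try:
                proposal, _move = propose_move(current, schedule, rng)
            except DegenerateGeometryError:
                continue
            phi_proposed = data_fit(proposal, fitset)
            if not metropolis_accept(phi_current, phi_proposed, t, rng):
                continue
            if not feasible(proposal):
                continue
            current = proposal
            phi_current = phi_proposed
            accepted += 1
            if phi_current < phi_best:
                best = current
                phi_best = phi_current
        trace.record(sweep, t, phi_current, phi_best, accepted / moves_per_sweep)
        stalled = stalled + 1 if accepted == 0 else 0
        t *= schedule.alpha
        if t < t_min:
            trace.stop_reason = "t_min"
            break
        if stalled >= schedule.stall_sweeps:
            trace.stop_reason = "stall"
            break
    else:
        trace.stop_reason = "max_sweeps"
    return best, trace
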