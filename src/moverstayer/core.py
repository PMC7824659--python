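"""Markov representation of intra-urban residential relocation.

A city is a closed system of ``N`` zones (suburbs).  Residents relocate
between zones; external migration and boundary expansion are ignored, so
the total population ``x̄`` is conserved.  The yearly dynamics are a simple
Markov chain on the zone populations,

    X(t+1) = X(t) · P,

with ``X`` a row vector of zone headcounts and ``P`` a row-stochastic
relocation matrix.  ``P`` is decomposed in mover–stayer form

    P = (1 − ε) I + ε H,

where ``ε`` is the yearly relocation frequency (its inverse ``τ = 1/ε`` is
the characteristic residence time) and ``H`` is the spatial kernel: the
row-stochastic matrix of destination choices conditional on moving.
Population heterogeneity is expressed as a mixture of components
``(α_k, ε_k, H_k)`` evolving independently under their own ``P_k`` while
sharing (or not) a kernel.

This module houses the domain types and the elementary operations on
them: kernel estimation from origin–destination flow tables, trajectory
evolution, net flows, flow extrapolation over multi-year horizons, and
window stayer shares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: construction-time tolerance for row sums of stochastic matrices
ROW_SUM_TOL = 1e-9


class ModelError(ValueError):
    """Raised when an input violates a model contract."""


def _zone_ids(zone_ids: Sequence[str] | None, n: int) -> tuple[str, ...]:
    if zone_ids is None:
        return tuple(f"z{i + 1}" for i in range(n))
    ids = tuple(str(z) for z in zone_ids)
    if len(ids) != n:
        raise ModelError(f"expected {n} zone ids, got {len(ids)}")
    if len(set(ids)) != n:
        raise ModelError("zone ids must be unique")
    return ids


def _check_zone_match(a: Sequence[str], b: Sequence[str]) -> None:
    if tuple(a) != tuple(b):
        raise ModelError("zone ids do not match between paired objects")


@dataclass(frozen=True)
class PopulationVector:
    """Per-zone headcounts ``x_i`` at a single time step.

    Entries are nonnegative reals (headcounts need not be integers once a
    trajectory has been evolved).  ``total`` is the conserved city
    population ``x̄``.
    """

    values: np.ndarray
    zone_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ModelError("population vector must be 1-D with at least 2 zones")
        if np.any(values < 0):
            raise ModelError("population values must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "zone_ids", _zone_ids(self.zone_ids, values.size))

    @property
    def n_zones(self) -> int:
        return self.values.size

    @property
    def total(self) -> float:
        """Total city population ``x̄``."""
        return float(self.values.sum())


@dataclass(frozen=True)
class FlowMatrix:
    """Origin–destination relocation counts ``T_ij`` over a time window.

    ``counts[i, j]`` is the number of residents whose zone changed from
    ``i`` to ``j`` within ``window_years`` years; the diagonal holds the
    immobile population when the source table reports it.
    """

    counts: np.ndarray
    window_years: int = 1
    zone_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ModelError("flow matrix must be square")
        if np.any(counts < 0):
            raise ModelError("flow counts must be nonnegative")
        if int(self.window_years) < 1:
            raise ModelError("window_years must be a positive integer")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "window_years", int(self.window_years))
        object.__setattr__(self, "zone_ids", _zone_ids(self.zone_ids, counts.shape[0]))

    @property
    def n_zones(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class SpatialKernel:
    """Row-stochastic destination-choice matrix ``H``.

    ``h[i, j]`` is the probability that a mover leaving zone ``i`` settles
    in zone ``j``.  Kernels estimated from flow tables have a zero
    diagonal (a mover changes zone by definition); analytic toy-city
    kernels may keep a nonzero diagonal, recorded by ``zero_diagonal``.

    Rows must sum to 1 within ``ROW_SUM_TOL``; they are renormalised
    exactly once, at construction.
    """

    h: np.ndarray
    zone_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    zero_diagonal: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ModelError("kernel must be square")
        if np.any(h < 0):
            raise ModelError("kernel entries must be nonnegative")
        sums = h.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise ModelError(
                f"kernel row {worst} sums to {sums[worst]!r}, not 1 within {ROW_SUM_TOL}"
            )
        h = h / sums[:, None]
        if self.zero_diagonal and np.any(np.diag(h) != 0.0):
            raise ModelError("kernel flagged zero_diagonal has nonzero diagonal entries")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "zone_ids", _zone_ids(self.zone_ids, h.shape[0]))

    @property
    def n_zones(self) -> int:
        return self.h.shape[0]


@dataclass(frozen=True)
class RelocationModel:
    """Single-component mover–stayer model ``P = (1−ε)I + εH``."""

    epsilon: float
    kernel: SpatialKernel

    def __post_init__(self) -> None:
        eps = float(self.epsilon)
        if not 0.0 <= eps <= 1.0:
            raise ModelError(f"relocation frequency must lie in [0, 1], got {eps}")
        object.__setattr__(self, "epsilon", eps)

    @property
    def tau(self) -> float:
        """Characteristic relocation time ``τ = 1/ε`` (``inf`` for ε = 0)."""
        return math.inf if self.epsilon == 0.0 else 1.0 / self.epsilon

    @property
    def matrix(self) -> np.ndarray:
        """The relocation matrix ``P = (1−ε)I + εH``."""
        n = self.kernel.n_zones
        return (1.0 - self.epsilon) * np.eye(n) + self.epsilon * self.kernel.h

    @property
    def zone_ids(self) -> tuple[str, ...]:
        return self.kernel.zone_ids


@dataclass(frozen=True)
class Component:
    """One population group of a mixture: share, frequency, kernel."""

    alpha: float
    epsilon: float
    kernel: SpatialKernel

    def __post_init__(self) -> None:
        if not 0.0 < float(self.alpha) <= 1.0:
            raise ModelError(f"component share must lie in (0, 1], got {self.alpha}")
        if not 0.0 <= float(self.epsilon) <= 1.0:
            raise ModelError(f"relocation frequency must lie in [0, 1], got {self.epsilon}")
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "epsilon", float(self.epsilon))

    @property
    def model(self) -> RelocationModel:
        return RelocationModel(self.epsilon, self.kernel)


@dataclass(frozen=True)
class ComponentMixture:
    """Population split into ``K`` mobility groups ``(α_k, ε_k, H_k)``.

    The shares ``α_k`` must sum to 1.  Components may share one kernel
    (the homogeneous-space assumption) or carry distinct kernels.
    """

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ModelError("mixture needs at least one component")
        total = sum(c.alpha for c in comps)
        if abs(total - 1.0) > 1e-12:
            raise ModelError(f"component shares sum to {total!r}, not 1")
        ids = comps[0].kernel.zone_ids
        for c in comps[1:]:
            _check_zone_match(ids, c.kernel.zone_ids)
        object.__setattr__(self, "components", comps)

    @property
    def n_zones(self) -> int:
        return self.components[0].kernel.n_zones

    @property
    def zone_ids(self) -> tuple[str, ...]:
        return self.components[0].kernel.zone_ids

    @property
    def shares_same_kernel(self) -> bool:
        """True when every component references an identical kernel matrix."""
        h0 = self.components[0].kernel.h
        return all(np.array_equal(h0, c.kernel.h) for c in self.components[1:])


ModelLike = Union[RelocationModel, ComponentMixture]


def as_mixture(model: ModelLike) -> ComponentMixture:
    """View any model as a mixture (a single model becomes one component)."""
    if isinstance(model, ComponentMixture):
        return model
    return ComponentMixture((Component(1.0, model.epsilon, model.kernel),))


@dataclass(frozen=True)
class RelaxationTrace:
    """A simulated trajectory ``X(t)`` with its finite differences.

    ``states[t]`` is the zone population at step ``t``; ``rates[t]`` is
    ``Q(t) = X(t+1) − X(t)``.  ``driving_forces[t] = U(t) = X(t) − X_eq``
    is filled once an equilibrium is attached (see
    :func:`moverstayer.equilibrium.relaxation_diagnostics`).
    ``component_states[k, t]`` carries the per-group trajectories when the
    trace comes from a mixture.
    """

    times: np.ndarray
    states: np.ndarray
    rates: np.ndarray
    zone_ids: tuple[str, ...]
    component_states: np.ndarray | None = None
    driving_forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        totals = states.sum(axis=1)
        xbar = totals[0]
        if np.any(np.abs(totals - xbar) > 1e-6 * max(xbar, 1.0)):
            raise ModelError("trace states do not conserve total population")
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape[0] != states.shape[0] - 1 or not np.allclose(
            rates, np.diff(states, axis=0), atol=0.0, rtol=0.0
        ):
            raise ModelError("rates must equal the first difference of states")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def total(self) -> float:
        return float(self.states[0].sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def kernel_from_flows(flows: FlowMatrix, zero_row_policy: str = "error") -> SpatialKernel:
    """Estimate the spatial kernel from an origin–destination flow table.

    Off-diagonal flows are normalised row-wise, ``h_ij = T_ij / Σ_{k≠i} T_ik``,
    and the diagonal is set to zero: the kernel describes destination choice
    conditional on having moved, so within-zone counts are ignored.

    Parameters
    ----------
    flows
        Square flow table; diagonal entries (immobile residents) are allowed
        and discarded.
    zero_row_policy
        What to do with a zone that recorded no out-flows: ``"error"``
        (default) raises; ``"uniform"`` substitutes an uninformative uniform
        row over the other zones, with a warning logged.
    """
    counts = flows.counts.copy()
    np.fill_diagonal(counts, 0.0)
    out = counts.sum(axis=1)
    dead = np.flatnonzero(out == 0.0)
    if dead.size:
        if zero_row_policy == "uniform":
            n = flows.n_zones
            for i in dead:
                counts[i] = 1.0 / (n - 1)
                counts[i, i] = 0.0
            out = counts.sum(axis=1)
            logger.warning(
                "kernel_from_flows: %d zone(s) with zero out-flow assigned uniform "
                "destination rows: %s",
                dead.size,
                [flows.zone_ids[i] for i in dead],
            )
        else:
            raise ModelError(
                "zones with zero off-diagonal out-flow: "
                f"{[flows.zone_ids[i] for i in dead]}; pass zero_row_policy='uniform' "
                "to impute uniform destination rows"
            )
    h = counts / out[:, None]
    return SpatialKernel(h, zone_ids=flows.zone_ids, zero_diagonal=True)


def mover_stayer_matrix(kernel: SpatialKernel, epsilon: float) -> np.ndarray:
    """Return the relocation matrix ``P = (1−ε)I + εH``."""
    return RelocationModel(epsilon, kernel).matrix


def naive_rates(flows: FlowMatrix, population: PopulationVector) -> np.ndarray:
    """Per-capita relocation rates ``p_ij = T_ij / x_i``.

    This is the direct single-window estimate of the relocation matrix.  It
    is row-stochastic when the flow table includes the immobile diagonal
    ``T_ii``; sub-stochastic rows (flows that do not account for everyone)
    are returned as-is.
    """
    _check_zone_match(flows.zone_ids, population.zone_ids)
    x = population.values
    if np.any(x <= 0):
        raise ModelError("naive rates need strictly positive population in every zone")
    row_sums = flows.counts.sum(axis=1)
    if np.any(row_sums > x * (1.0 + 1e-9)):
        bad = int(np.argmax(row_sums - x))
        raise ModelError(
            f"zone {population.zone_ids[bad]}: out-flow {row_sums[bad]} exceeds "
            f"population {x[bad]}"
        )
    return flows.counts / x[:, None]


def evolve(
    state: PopulationVector,
    model: ModelLike,
    steps: int,
    component_states: Sequence[np.ndarray] | None = None,
) -> RelaxationTrace:
    """Evolve ``X(t+1) = X(t) · P`` for ``steps`` years.

    For a mixture, each component evolves independently under its own
    ``P_k``; the initial per-component states default to ``α_k · X(0)``
    (the mixture's shares applied uniformly across zones) unless supplied
    explicitly.  The trace carries both the per-component and the summed
    trajectories.  Total population is conserved at every step.
    """
    if steps < 0:
        raise ModelError("steps must be nonnegative")
    mixture = as_mixture(model)
    _check_zone_match(state.zone_ids, mixture.zone_ids)
    k = len(mixture.components)
    n = state.n_zones

    if component_states is None:
        comp0 = np.array([c.alpha * state.values for c in mixture.components])
    else:
        comp0 = np.array([np.asarray(cs, dtype=float) for cs in component_states])
        if comp0.shape != (k, n):
            raise ModelError(f"expected {k} component states of length {n}")
        if not np.allclose(comp0.sum(axis=0), state.values, rtol=0, atol=1e-9 * max(state.total, 1.0)):
            raise ModelError("component states must sum to the total state")

    matrices = [c.model.matrix for c in mixture.components]
    comp_traj = np.empty((k, steps + 1, n))
    comp_traj[:, 0] = comp0
    for t in range(steps):
        for j in range(k):
            comp_traj[j, t + 1] = comp_traj[j, t] @ matrices[j]

    states = comp_traj.sum(axis=0)
    return RelaxationTrace(
        times=np.arange(steps + 1),
        states=states,
        rates=np.diff(states, axis=0),
        zone_ids=state.zone_ids,
        component_states=comp_traj if isinstance(model, ComponentMixture) else None,
    )


def net_flow(state: PopulationVector, model: RelocationModel) -> np.ndarray:
    """Net inter-zone flows ``J_ij = x_i p_ij − x_j p_ji``.

    ``J`` is exactly antisymmetric; a nonzero net flow marks the system as
    out of equilibrium, and ``J → 0`` as the chain relaxes.
    """
    _check_zone_match(state.zone_ids, model.zone_ids)
    gross = state.values[:, None] * model.matrix
    return gross - gross.T


def _mixture_power(mixture: ComponentMixture, horizon: int) -> np.ndarray:
    """``Σ_k α_k P_k^horizon`` by repeated multiplication."""
    n = mixture.n_zones
    acc = np.zeros((n, n))
    for c in mixture.components:
        p = c.model.matrix
        power = np.eye(n)
        for _ in range(horizon):
            power = power @ p
        acc += c.alpha * power
    return acc


def extrapolate_flows(
    population: PopulationVector, model: ModelLike, horizon_years: int
) -> FlowMatrix:
    """Extrapolate a flow table over a multi-year horizon.

    Returns ``T̂_ij = x_i · [Σ_k α_k P_k^h]_ij`` — the expected relocation
    counts over ``h = horizon_years`` years if the one-year dynamics stay
    constant.  The diagonal of the result is the predicted immobile count
    (including movers who returned within the window).
    """
    if horizon_years < 1:
        raise ModelError("horizon must be at least one year")
    mixture = as_mixture(model)
    _check_zone_match(population.zone_ids, mixture.zone_ids)
    p_h = _mixture_power(mixture, horizon_years)
    return FlowMatrix(
        population.values[:, None] * p_h,
        window_years=horizon_years,
        zone_ids=population.zone_ids,
    )


def stayer_share(
    model: ModelLike,
    horizon_years: int,
    weights: PopulationVector | None = None,
    weighted: bool = True,
) -> float:
    """Average share of residents found in their starting zone after ``h`` years.

    Computed as the population-weighted mean of ``diag(Σ_k α_k P_k^h)``
    (pass ``weighted=False`` for the unweighted mean over zones).  Note this
    counts movers who returned to their origin within the window as stayers,
    matching how census windows observe residence.
    """
    if horizon_years < 0:
        raise ModelError("horizon must be nonnegative")
    mixture = as_mixture(model)
    if horizon_years == 0:
        return 1.0
    diag = np.diag(_mixture_power(mixture, horizon_years))
    if weighted and weights is not None:
        _check_zone_match(weights.zone_ids, mixture.zone_ids)
        w = weights.values / weights.total
        return float(diag @ w)
    return float(diag.mean())
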