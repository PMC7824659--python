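"""Equilibrium population structure and diffusive-relaxation diagnostics.

The stationary state of the relocation chain, ``X_eq · P = X_eq``, is the
"equilibrium city": the spatial population distribution to which the
observed dynamics relax if the relocation matrix stays constant.  Because
``P = (1−ε)I + εH`` shares left eigenvectors with ``H``, the equilibrium
is independent of the relocation frequency ε — and, for a mixture whose
components share a kernel, independent of the component shares ``α_k`` as
well: each component settles on ``X_k,eq = α_k X_eq``.

Relaxation towards equilibrium is irreversible and formally diffusive.
Writing ``U(t) = X(t) − X_eq`` for the driving force and
``Q(t) = X(t+1) − X(t)`` for the rate of change, the evolution equation
becomes the discrete transport law

    Q(t) = U(t) · L,        L = P − I = −ε(I − H),

with ``L`` the matrix of transport coefficients.  Near equilibrium the
decay of ``‖U(t)‖`` is exponential and governed by the second-largest
eigenvalue modulus of ``P``: ``λ₂(P) = 1 − ε(1 − λ₂(H))`` for real
spectra, and ``‖Q‖/‖U‖ → 1 − λ₂`` in the asymptotic regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    ComponentMixture,
    ModelError,
    ModelLike,
    PopulationVector,
    RelaxationTrace,
    RelocationModel,
    SpatialKernel,
    as_mixture,
)

logger = logging.getLogger(__name__)

#: tolerance on the unit eigenvalue of a row-stochastic matrix
_EIG_TOL = 1e-8


def _stochastic_or_raise(p: np.ndarray) -> None:
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8) or np.any(p < -1e-12):
        raise ModelError("matrix is not row-stochastic")


def is_primitive(p: np.ndarray, max_power: int | None = None) -> bool:
    """Check primitivity by testing strict positivity of ``P^m`` for m ≤ N.

    Entries above 1e−15 count as positive.  Primitivity guarantees a unique
    stationary vector; reducible chains (e.g. kernels with absorbing
    destination sets) fail the check but remain analysable.
    """
    n = p.shape[0]
    limit = n if max_power is None else max_power
    power = p.copy()
    for _ in range(limit):
        if np.all(power > 1e-15):
            return True
        power = power @ p
    return False


def has_unique_stationary(p: np.ndarray) -> bool:
    """Uniqueness flag for the stationary vector: irreducibility of the chain.

    Tested as primitivity of the lazy matrix ``(I + P)/2``, which shares
    the stationary vectors of ``P`` but is aperiodic by construction —
    so periodic but irreducible kernels (e.g. a pure two-zone swap) are
    correctly reported as having a unique equilibrium, while reducible
    ones (absorbing destination blocks) are flagged.
    """
    return is_primitive(0.5 * (np.eye(p.shape[0]) + p))


@dataclass(frozen=True)
class EquilibriumResult:
    """Stationary population structure of a relocation model.

    ``x_eq`` is scaled to the requested total ``x̄``; ``per_component``
    holds the component equilibria ``X_k,eq`` when the input was a
    mixture (they sum to ``x_eq``).  ``second_eigenvalue_modulus`` is
    ``|λ₂|`` of the relevant relocation matrix (the slowest component's,
    for mixtures): the spectral quantity that sets the relaxation time.
    ``is_unique`` reports the primitivity check; a failed check flags —
    never rejects — the result, with the vector drawn from the dominant
    eigenspace.
    """

    x_eq: PopulationVector
    second_eigenvalue_modulus: float
    is_unique: bool
    per_component: tuple[PopulationVector, ...] | None = None


def _left_unit_eigenvector(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Left eigenvector for eigenvalue 1 and |λ₂|, via dense eigendecomposition."""
    eigvals, eigvecs = np.linalg.eig(p.T)
    order = np.argsort(-np.abs(eigvals))
    lead = order[0]
    if abs(eigvals[lead] - 1.0) > _EIG_TOL:
        raise ModelError(
            f"dominant eigenvalue {eigvals[lead]!r} is not 1; matrix is not stochastic"
        )
    v = np.real(eigvecs[:, lead])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    if v.sum() <= 0:
        raise ModelError("degenerate stationary eigenvector")
    second = float(np.abs(eigvals[order[1]])) if len(order) > 1 else 0.0
    return v / v.sum(), second


def stationary_distribution(
    model: ModelLike | SpatialKernel, total: float = 1.0
) -> EquilibriumResult:
    """Stationary population vector ``X_eq`` with ``X_eq · P = X_eq``.

    Accepts a kernel directly — the stationary vector of
    ``P = (1−ε)I + εH`` equals that of ``H`` for every ε in (0, 1], which
    is why the equilibrium city can be predicted from the observable
    kernel alone.  The result is scaled to the total population ``x̄``.
    """
    if isinstance(model, ComponentMixture):
        return mixture_equilibrium(model, total)
    if isinstance(model, RelocationModel):
        if model.epsilon == 0.0:
            raise ModelError("ε = 0 freezes every state; stationary vector is undefined")
        p = model.matrix
        zone_ids = model.zone_ids
    else:
        p = model.h
        zone_ids = model.zone_ids
    _stochastic_or_raise(p)
    pi, second = _left_unit_eigenvector(p)
    unique = has_unique_stationary(p)
    if not unique:
        logger.warning(
            "stationary_distribution: primitivity check failed; vector drawn from "
            "the dominant eigenspace may not be unique"
        )
    return EquilibriumResult(
        x_eq=PopulationVector(total * pi, zone_ids=zone_ids),
        second_eigenvalue_modulus=second,
        is_unique=unique,
    )


def mixture_equilibrium(mixture: ComponentMixture, total: float = 1.0) -> EquilibriumResult:
    """Component-wise equilibrium ``X_k,eq`` and their sum.

    Each component conserves its own mass ``α_k x̄`` and relaxes to
    ``α_k x̄`` times the stationary vector of its kernel.  With a shared
    kernel this reduces to ``X_k,eq = α_k X_eq``; with heterogeneous
    kernels the total is the mass-weighted sum of distinct stationary
    structures and genuinely depends on the ``α_k``.
    """
    per: list[PopulationVector] = []
    second = 0.0
    unique = True
    for c in mixture.components:
        _stochastic_or_raise(c.kernel.h)
        pi, _ = _left_unit_eigenvector(c.kernel.h)
        p_k = c.model.matrix
        _, second_k = _left_unit_eigenvector(p_k)
        second = max(second, second_k)
        unique = unique and has_unique_stationary(p_k)
        per.append(PopulationVector(c.alpha * total * pi, zone_ids=c.kernel.zone_ids))
    x_eq = np.sum([v.values for v in per], axis=0)
    return EquilibriumResult(
        x_eq=PopulationVector(x_eq, zone_ids=mixture.zone_ids),
        second_eigenvalue_modulus=second,
        is_unique=unique,
        per_component=tuple(per),
    )


def aggregate_kernel(mixture: ComponentMixture) -> SpatialKernel:
    """Share-weighted kernel ``Ĥ = Σ_k α_k H_k``.

    This is the only kernel observable when component memberships are
    unknown: aggregate flow data mix the components in proportion α_k.
    A convex combination of row-stochastic matrices, so row-stochastic by
    construction.
    """
    h = np.sum([c.alpha * c.kernel.h for c in mixture.components], axis=0)
    zero_diag = all(c.kernel.zero_diagonal for c in mixture.components)
    return SpatialKernel(h, zone_ids=mixture.zone_ids, zero_diagonal=zero_diag)


def equilibrium_approximation_error(
    mixture: ComponentMixture, total: float = 1.0, norm: str = "l1"
) -> float:
    """Discrepancy between the true mixture equilibrium and the aggregate one.

    Compares ``X_eq = Σ_k X_k,eq`` against ``X̂_eq``, the stationary vector
    of the aggregate kernel ``Ĥ`` — the prediction available when only
    pooled flows are observed.  Returns the relative L1 discrepancy
    ``‖X_eq − X̂_eq‖₁ / x̄`` by default, or relative L2 with ``norm="l2"``.
    Zero (up to eigen tolerance) when the components share a kernel.
    """
    true_eq = mixture_equilibrium(mixture, total).x_eq.values
    approx_eq = stationary_distribution(aggregate_kernel(mixture), total).x_eq.values
    diff = true_eq - approx_eq
    if norm == "l1":
        value = float(np.abs(diff).sum() / total)
    elif norm == "l2":
        value = float(np.linalg.norm(diff) / total)
    else:
        raise ModelError(f"unknown norm {norm!r}")
    logger.info("equilibrium approximation error (%s, relative): %g", norm, value)
    return value


def transport_matrix(model: RelocationModel) -> np.ndarray:
    """Matrix of transport coefficients ``L = P − I = −ε(I − H)``.

    Maps the driving force to the rate of change, ``Q(t) = U(t) · L`` —
    the discrete analogue of a linear transport law.  Rows sum to zero,
    reflecting conservation.  Both algebraic forms are computed and must
    agree entrywise to 1e−12.
    """
    n = model.kernel.n_zones
    eye = np.eye(n)
    l_from_p = model.matrix - eye
    l_factored = -model.epsilon * (eye - model.kernel.h)
    if not np.allclose(l_from_p, l_factored, rtol=0.0, atol=1e-12):
        raise ModelError("transport matrix forms disagree beyond 1e-12")
    return l_from_p


@dataclass(frozen=True)
class DecayEstimate:
    """Spectral diagnosis of an exponential relaxation trace.

    ``fitted_slope`` is the least-squares slope of ``log ‖U(t)‖`` over the
    tail window; ``predicted_slope`` is ``log |λ₂(P)|``, the value the
    spectrum dictates asymptotically.  ``near_equilibrium_ratio`` is the
    terminal ``‖Q‖/‖U‖``, which tends to ``1 − λ₂`` for real positive λ₂.
    Norms are taken per the stated ``norm_kind`` and normalised by the
    trace's (component) mass so traces of different sizes are comparable.
    """

    fitted_slope: float
    predicted_slope: float
    near_equilibrium_ratio: float
    norm_kind: str
    tail_window: tuple[int, int]


def _vec_norm(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "l2":
        return np.linalg.norm(u, axis=-1)
    if kind == "l1":
        return np.abs(u).sum(axis=-1)
    raise ModelError(f"unknown norm {kind!r}")


def relaxation_diagnostics(
    trace: RelaxationTrace,
    equilibrium: EquilibriumResult,
    model: ModelLike,
    component: int | None = None,
    tail_fraction: float = 0.5,
    norm: str = "l2",
) -> DecayEstimate:
    """Fit the exponential decay of the driving force and compare to the spectrum.

    For a mixture, pass ``component=k`` to diagnose group ``k``'s
    trajectory against its own ``P_k`` and equilibrium ``X_k,eq``; the
    default diagnoses the summed trace against the (first) component
    matrix, which is exact for single models and shared-kernel mixtures
    with one frequency.

    The tail window is the last ``tail_fraction`` of the trace (default:
    last half), where the asymptotic single-mode regime holds.
    """
    if trace.n_steps + 1 < 5:
        raise ModelError("trace too short for decay diagnostics (need ≥ 5 states)")
    mixture = as_mixture(model)

    if component is None:
        states = trace.states
        x_eq = equilibrium.x_eq.values
        p = mixture.components[0].model.matrix
        mass = trace.total
    else:
        if trace.component_states is None:
            raise ModelError("trace has no per-component states")
        states = trace.component_states[component]
        comp = mixture.components[component]
        if equilibrium.per_component is not None:
            x_eq = equilibrium.per_component[component].values
        else:
            x_eq = comp.alpha * equilibrium.x_eq.values
        p = comp.model.matrix
        mass = comp.alpha * trace.total

    if not is_primitive(p):
        raise ModelError("decay diagnostics require a primitive relocation matrix")

    u = states - x_eq
    u_norm = _vec_norm(u, norm) / mass
    q_norm = _vec_norm(np.diff(states, axis=0), norm) / mass

    t_hi = len(u_norm) - 1
    t_lo = max(0, int(np.floor(t_hi * (1.0 - tail_fraction))))
    window = np.arange(t_lo, t_hi + 1)
    if np.all(u_norm[window] < 1e-12):
        raise ModelError("already at equilibrium: driving force below 1e-12 of total")
    positive = window[u_norm[window] > 0]
    if positive.size < 2:
        raise ModelError("driving force vanished inside the tail window; cannot fit slope")
    slope = float(np.polyfit(positive, np.log(u_norm[positive]), 1)[0])

    _, lam2 = _left_unit_eigenvector(p)
    predicted = float(np.log(lam2)) if lam2 > 0 else -np.inf

    last = trace.n_steps - 1  # last index where both Q(t) and U(t) exist
    ratio = float(q_norm[last] / u_norm[last]) if u_norm[last] > 0 else np.nan

    return DecayEstimate(
        fitted_slope=slope,
        predicted_slope=predicted,
        near_equilibrium_ratio=ratio,
        norm_kind=norm,
        tail_window=(int(t_lo), int(t_hi)),
    )
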