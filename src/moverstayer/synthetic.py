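"""Synthetic toy cities for exercising the relocation framework.

Real origin–destination tables are census products; everything this
package needs for testing and illustration can instead be generated from
three stylised constructions:

* a **linear city** of zones along a line, with exponential
  distance-decay destination preference towards (or away from) the
  central zone — two components with opposed preferences make the
  canonical heterogeneous-kernel example;
* **random block kernels**, where each component's destinations are
  confined to a fixed zone subset (central vs peripheral blocks), the
  extreme case of destination heterogeneity;
* the **destination-split decomposition**, which factors one observed
  kernel ``H`` into two component kernels ``H₁`` (destinations inside a
  chosen zone set ``A``) and ``H₂`` (outside), exactly satisfying
  ``α H₁ + (1 − α) H₂ = H`` row by row — the construction used to stress
  equilibrium predictions on real kernels without observing components.

Toy kernels keep their (analytic) nonzero diagonals; kernels estimated
from flow tables are zero-diagonal.  The two conventions coexist and are
recorded on the kernel type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Component, ComponentMixture, ModelError, SpatialKernel


@dataclass(frozen=True)
class LinearCitySpec:
    """Zones 1..n on a line; zone ``center`` (1-based) is the CBD.

    Distance of zone *i* to the centre is ``d_i = |i − center|`` in zone
    units.  ``beta`` is the exponential distance-decay rate of the
    destination preference.  Defaults give the 99-zone city with the
    centre at zone 50 and β = 0.1.
    """

    n_zones: int = 99
    beta: float = 0.1
    center: int = 50

    def __post_init__(self) -> None:
        if self.n_zones < 3:
            raise ModelError("linear city needs at least 3 zones")
        if not 1 <= self.center <= self.n_zones:
            raise ModelError("center must be a valid 1-based zone index")
        if self.beta < 0:
            raise ModelError("distance-decay rate beta must be nonnegative")

    @property
    def distances(self) -> np.ndarray:
        return np.abs(np.arange(1, self.n_zones + 1) - self.center).astype(float)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the destination-split decomposition.

    ``alpha`` is the share of component 1; ``destination_set`` is the
    zone subset ``A`` that component 1 targets (zone ids, or 1-based
    integer positions).  In the urban reading, ``A`` collects the zones
    within a distance threshold of the CBD, but membership is supplied
    explicitly — no geography is computed here.
    """

    alpha: float
    destination_set: tuple = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ModelError("split share alpha must lie strictly in (0, 1)")
        if not self.destination_set:
            raise ModelError("destination set must be nonempty")
        object.__setattr__(self, "destination_set", tuple(self.destination_set))


def _resolve_zone_set(members: Sequence, zone_ids: Sequence[str], n: int) -> np.ndarray:
    """Boolean column mask from zone ids or 1-based integer positions."""
    mask = np.zeros(n, dtype=bool)
    for m in members:
        if isinstance(m, (int, np.integer)):
            if not 1 <= int(m) <= n:
                raise ModelError(f"zone position {m} outside 1..{n}")
            mask[int(m) - 1] = True
        else:
            try:
                mask[list(zone_ids).index(str(m))] = True
            except ValueError:
                raise ModelError(f"unknown zone id {m!r}") from None
    if not mask.any() or mask.all():
        raise ModelError("destination set must be a nonempty proper subset of zones")
    return mask


def linear_city_kernels(spec: LinearCitySpec) -> tuple[SpatialKernel, SpatialKernel]:
    """Opposed distance-decay kernels for the linear city.

    The centre-seeking kernel weighs destination *j* by ``e^{−β d_j}``;
    after row normalisation the origin-dependent factors cancel, so all
    rows are identical and equal to the normalised destination weight
    vector — hence that row is also the kernel's stationary distribution.
    The periphery-seeking kernel uses ``e^{+β d_j}`` and concentrates on
    the line's two endpoints.  Both are destination-only kernels with
    nonzero diagonals.
    """
    d = spec.distances
    w1 = np.exp(-spec.beta * d)
    w2 = np.exp(spec.beta * d)
    row1 = w1 / w1.sum()
    row2 = w2 / w2.sum()
    h1 = np.tile(row1, (spec.n_zones, 1))
    h2 = np.tile(row2, (spec.n_zones, 1))
    return (
        SpatialKernel(h1, zero_diagonal=False),
        SpatialKernel(h2, zero_diagonal=False),
    )


def random_block_kernels(
    n_zones: int, set_a: Sequence, seed: int
) -> tuple[SpatialKernel, SpatialKernel]:
    """Random kernels with complementary destination blocks.

    ``H₁`` has positive (uniform-random) entries exactly on the columns in
    ``set_a`` and zeros elsewhere; ``H₂`` is positive exactly on the
    complement.  Rows are normalised to 1.  Deterministic under ``seed``.
    """
    kernel_ids = tuple(f"z{i + 1}" for i in range(n_zones))
    mask = _resolve_zone_set(set_a, kernel_ids, n_zones)
    rng = np.random.default_rng(seed)
    raw1 = rng.random((n_zones, n_zones))
    raw2 = rng.random((n_zones, n_zones))
    h1 = np.where(mask[None, :], raw1, 0.0)
    h2 = np.where(mask[None, :], 0.0, raw2)
    h1 /= h1.sum(axis=1, keepdims=True)
    h2 /= h2.sum(axis=1, keepdims=True)
    return (
        SpatialKernel(h1, zone_ids=kernel_ids, zero_diagonal=False),
        SpatialKernel(h2, zone_ids=kernel_ids, zero_diagonal=False),
    )


def split_kernel(
    kernel: SpatialKernel, spec: SplitSpec
) -> tuple[SpatialKernel, SpatialKernel]:
    """Split one kernel into destination-targeted components.

    Component 1 (share α) relocates into the zone set ``A``, component 2
    into its complement — but the observed share ``a_i = Σ_{j∈A} h_ij`` of
    row *i*'s mass inside ``A`` need not equal α, so the split reassigns
    row mass branch-wise:

    * if ``a_i ≤ α``: all of row *i*'s in-``A`` mass belongs to component
      1, plus the fraction ``(α − a_i)/(1 − a_i)`` of the out-of-``A``
      mass;
    * if ``a_i > α``: component 1 takes the fraction ``α/a_i`` of the
      in-``A`` mass and nothing outside.

    Component 2's row is the remainder, ``h₂ = (h − α h₁)/(1 − α)``.  The
    construction guarantees ``α H₁ + (1 − α) H₂ = H`` entrywise, with both
    factors row-stochastic and nonnegative.
    """
    h = kernel.h
    n = kernel.n_zones
    alpha = spec.alpha
    mask = _resolve_zone_set(spec.destination_set, kernel.zone_ids, n)
    a = h[:, mask].sum(axis=1)

    h1 = np.zeros_like(h)
    for i in range(n):
        ai = a[i]
        if ai <= alpha:
            if ai == 1.0:  # unreachable when alpha < 1, kept as a guard
                raise ModelError(f"row {i}: degenerate split with a_i = alpha = 1")
            h1[i, mask] = h[i, mask] / alpha
            h1[i, ~mask] = (alpha - ai) / (alpha * (1.0 - ai)) * h[i, ~mask]
        else:
            h1[i, mask] = h[i, mask] / ai
    h2 = (h - alpha * h1) / (1.0 - alpha)
    h2 = np.clip(h2, 0.0, None)  # clamp −0.0 / rounding dust at exact branch points
    return (
        SpatialKernel(h1, zone_ids=kernel.zone_ids, zero_diagonal=kernel.zero_diagonal),
        SpatialKernel(h2, zone_ids=kernel.zone_ids, zero_diagonal=kernel.zero_diagonal),
    )


def mixture_fixture(
    kind: str,
    alpha: float = 0.9,
    epsilons: tuple[float, float] = (0.09, 0.8),
    n_zones: int = 99,
    beta: float = 0.1,
    center: int = 50,
    set_a: Sequence | None = None,
    seed: int = 0,
    kernel: SpatialKernel | None = None,
) -> ComponentMixture:
    """Bundle a generated kernel pair into a ready-to-use two-component mixture.

    ``kind`` selects the construction:

    * ``"shared"`` — both components reference the same centre-seeking
      linear-city kernel (the homogeneous-space assumption);
    * ``"opposed"`` — centre-seeking vs periphery-seeking linear-city
      kernels;
    * ``"blocks"`` — random complementary-destination-block kernels
      (``set_a`` defaults to the central zones 26..74, ``seed`` required
      for reproducibility);
    * ``"split"`` — destination-split decomposition of a supplied
      ``kernel`` over ``set_a``.

    Default frequencies (0.09, 0.8) are of the order produced by
    calibrating the two-component model to observed big-city stayer
    shares: a slow majority and a fast minority.
    """
    eps1, eps2 = epsilons
    if kind == "shared":
        h1, _ = linear_city_kernels(LinearCitySpec(n_zones, beta, center))
        k1 = k2 = h1
    elif kind == "opposed":
        k1, k2 = linear_city_kernels(LinearCitySpec(n_zones, beta, center))
    elif kind == "blocks":
        if set_a is None:
            set_a = tuple(range(26, 75))
        k1, k2 = random_block_kernels(n_zones, set_a, seed)
    elif kind == "split":
        if kernel is None or set_a is None:
            raise ModelError("kind='split' requires a kernel and a destination set")
        k1, k2 = split_kernel(kernel, SplitSpec(alpha, tuple(set_a)))
    else:
        raise ModelError(f"unknown mixture kind {kind!r}")
    return ComponentMixture(
        (Component(alpha, eps1, k1), Component(1.0 - alpha, eps2, k2))
    )
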