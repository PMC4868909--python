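"""Reaction-diffusion model of disparity-map formation on a cortical lattice.

Each lattice site carries a real disparity state x.  A multistable
reaction term drives x toward the nearest of the D stable roots
0, 1, ..., D-1 (each root a learned disparity; the separatrices sit at
the half-integers), while a diffusion term couples each site to its
four neighbours — the lattice analogue of the resistive coupling
between disparity cells.  Without diffusion every site settles
independently into the basin its initial bias places it in; with
diffusion, contiguous clusters of common disparity emerge with gradual
variation across cluster boundaries: continuity, diversity and global
order of a cortical feature map.

The update is explicit Euler:

    x  <-  x + alpha * reaction(x, D) + d_u * laplacian(x)

with ``reaction(x, D) = -sin(2 pi x) / (2 pi)`` inside the root range
(zero and attracting at every integer, zero and repelling at every
half-integer) and a linear restoring drift outside it, and the
5-point discrete Laplacian under reflecting (cortical sheet edge) or
wrapping boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RDLattice",
    "MapStats",
    "StabilityError",
    "reaction",
    "init_lattice",
    "laplacian",
    "evolve_no_diffusion",
    "evolve_rd",
    "map_stats",
]


class StabilityError(RuntimeError):
    """The explicit update left the admissible state range (step too large)."""


@dataclass
class RDLattice:
    """State lattice with its reaction/diffusion constants.

    ``alpha`` is the reaction rate per step (stable for alpha < 2,
    monotone convergence for alpha <= 1); ``d_u`` the diffusion constant
    per step (explicit 2-D stability needs d_u <= 1/4); ``n_disparities``
    the number of stable roots; ``boundary`` is ``reflect`` or ``wrap``.
    """

    x: np.ndarray
    alpha: float = 1.5
    d_u: float = 0.1
    n_disparities: int = 4
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.d_u < 0:
            raise ValueError("d_u must be >= 0")
        if self.n_disparities < 2:
            raise ValueError("need at least two disparities")
        if self.boundary not in ("reflect", "wrap"):
            raise ValueError("boundary must be 'reflect' or 'wrap'")

    def copy(self) -> "RDLattice":
        return RDLattice(
            self.x.copy(), self.alpha, self.d_u, self.n_disparities, self.boundary
        )


@dataclass
class MapStats:
    """Map-quality statistics: continuity, diversity, global order.

    ``continuity`` is the mean absolute state difference over all
    4-neighbour pairs (lower = smoother); ``diversity`` the fraction of
    the D disparities represented by at least one site (by nearest
    root); ``cluster_count`` the number of connected components of
    constant nearest-root disparity, with labels in ``cluster_labels``.
    """

    continuity: float
    diversity: float
    cluster_count: int
    cluster_labels: np.ndarray


def reaction(x, n_disparities: int):
    """Multistable drift whose roots are the integer disparities.

    ``-sin(2 pi x) / (2 pi)`` on [0, D-1]: vanishes at every integer and
    half-integer; integers attract (negative slope), half-integers
    repel, and the sign always points to the nearest integer.  Outside
    [0, D-1] a linear drift restores the state toward the range with
    the same slope the boundary roots have.
    """
    if n_disparities < 2:
        raise ValueError("need at least two disparities")
    x = np.asarray(x, dtype=float)
    top = n_disparities - 1
    drift = -np.sin(2.0 * np.pi * x) / (2.0 * np.pi)
    drift = np.where(x < 0, -x, drift)
    drift = np.where(x > top, top - x, drift)
    return drift if drift.ndim else float(drift)


def init_lattice(
    shape: tuple[int, int],
    n_disparities: int = 4,
    seed: int = 0,
    alpha: float = 1.5,
    d_u: float = 0.1,
    boundary: str = "reflect",
) -> RDLattice:
    """Seeded lattice with iid uniform initial biases in [0, D-1]."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, n_disparities - 1.0, shape)
    return RDLattice(x=x, alpha=alpha, d_u=d_u, n_disparities=n_disparities, boundary=boundary)


def laplacian(x: np.ndarray, boundary: str = "reflect") -> np.ndarray:
    """5-point discrete Laplacian with reflecting or wrapping boundaries."""
    mode = {"reflect": "reflect", "wrap": "wrap"}[boundary]
    k = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    return ndimage.convolve(x, k, mode=mode)


def _check_state(lattice: RDLattice) -> None:
    top = lattice.n_disparities
    if np.any(lattice.x < -1.0) or np.any(lattice.x > top):
        raise StabilityError(
            f"state escaped [-1, {top}]: alpha={lattice.alpha}, d_u={lattice.d_u} "
            "exceed the explicit-scheme stability bounds"
        )


def evolve_no_diffusion(lattice: RDLattice, steps: int) -> RDLattice:
    """Pure-reaction evolution: every site settles to its nearest root.

    Sites sitting exactly on a separatrix (half-integer) stay there —
    the repelling fixed point is still a fixed point of the update.
    """
    out = lattice.copy()
    for _ in range(steps):
        out.x = out.x + out.alpha * reaction(out.x, out.n_disparities)
        _check_state(out)
    return out


def evolve_rd(lattice: RDLattice, steps: int) -> RDLattice:
    """Reaction plus neighbour diffusion: cluster-forming regime.

    With ``d_u = 0`` this reduces exactly to ``evolve_no_diffusion``;
    with moderate ``d_u`` the settled map shows contiguous clusters of
    common disparity and gradual variation at cluster borders.
    """
    if lattice.d_u > 0.25:
        raise StabilityError(
            f"d_u={lattice.d_u} violates the explicit diffusion bound 1/4"
        )
    out = lattice.copy()
    for _ in range(steps):
        out.x = (
            out.x
            + out.alpha * reaction(out.x, out.n_disparities)
            + out.d_u * laplacian(out.x, out.boundary)
        )
        _check_state(out)
    return out


def nearest_root(x: np.ndarray, n_disparities: int) -> np.ndarray:
    """Integer disparity each state is committed to (clipped rounding)."""
    return np.clip(np.rint(x).astype(int), 0, n_disparities - 1)


def map_stats(lattice: RDLattice) -> MapStats:
    """Continuity, diversity and cluster structure of a settled lattice."""
    x = lattice.x
    d_h = np.abs(np.diff(x, axis=1))
    d_v = np.abs(np.diff(x, axis=0))
    continuity = float(np.concatenate([d_h.ravel(), d_v.ravel()]).mean())
    disp = nearest_root(x, lattice.n_disparities)
    diversity = len(np.unique(disp)) / lattice.n_disparities
    labels = np.zeros_like(disp)
    count = 0
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for d in np.unique(disp):
        lab, n = ndimage.label(disp == d, structure=structure)
        labels = np.where(disp == d, lab + count, labels)
        count += int(n)
    return MapStats(
        continuity=continuity,
        diversity=float(diversity),
        cluster_count=count,
        cluster_labels=labels,
    )
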