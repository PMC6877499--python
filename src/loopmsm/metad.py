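"""Well-tempered metadynamics on analytic periodic torsion-like potentials.

A Metropolis Monte Carlo walker samples the biased Boltzmann measure of
V + V_bias on the periodic domain [-180, 180)^d (d = 1 or 2).  Every
``stride`` steps a Gaussian of height

    W = W0 * exp(-V_bias(x) / ((gamma - 1) kT))

is deposited at the current position (well-tempered height damping with
bias factor gamma > 1).  The free-energy surface is reconstructed from the
accumulated bias as

    F(x) = -(gamma / (gamma - 1)) V_bias(x),    min-shifted to 0.

The bias potential is accumulated on a fine periodic grid (1 degree in
1-D, 5 degrees in 2-D) with nearest-node lookup, which keeps every MC step
O(1) regardless of how many Gaussians have been deposited; the individual
depositions are still recorded.  Monte Carlo proposal moves are Gaussian
with a 5-degree step, so the dynamics exactly target the biased Boltzmann
distribution without any force integration.

Units are flexible: energies are expressed in multiples of ``kT`` by
default (kT = 1); physical units, e.g. kcal/mol at 300 K with
kT = 0.5961 kcal/mol, are supported by passing ``kT`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KT_KCAL_300K = 0.5961   # kcal/mol at 300 K

_PERIOD = 360.0


def periodic_delta(a, b):
    """Minimum-image angular difference a - b on the 360-degree torus."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % _PERIOD - 180.0


@dataclass
class BiasState:
    """Accumulated well-tempered bias: deposited Gaussians plus the grid."""

    w0: float
    gamma: float
    sigma: np.ndarray                 # per-dimension width, degrees
    stride: int
    kT: float
    dim: int
    grid_axes: list[np.ndarray]
    bias_grid: np.ndarray
    centers: list[np.ndarray] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)
    steps: list[int] = field(default_factory=list)

    @property
    def n_depositions(self) -> int:
        return len(self.heights)

    def bias_at(self, x: np.ndarray) -> float:
        idx = tuple(int(np.argmin(np.abs(periodic_delta(ax, xi))))
                    for ax, xi in zip(self.grid_axes, np.atleast_1d(x)))
        return float(self.bias_grid[idx])

    def deposit(self, x: np.ndarray, step: int) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        h = self.w0 * np.exp(-self.bias_at(x) / ((self.gamma - 1.0) * self.kT))
        if self.dim == 1:
            d = periodic_delta(self.grid_axes[0], x[0])
            self.bias_grid += h * np.exp(-d ** 2 / (2 * self.sigma[0] ** 2))
        else:
            d0 = periodic_delta(self.grid_axes[0], x[0])[:, None]
            d1 = periodic_delta(self.grid_axes[1], x[1])[None, :]
            self.bias_grid += h * np.exp(-(d0 ** 2 / (2 * self.sigma[0] ** 2)
                                           + d1 ** 2 / (2 * self.sigma[1] ** 2)))
        self.centers.append(x.copy())
        self.heights.append(float(h))
        self.steps.append(int(step))
        return float(h)


@dataclass
class FESEstimate:
    grid_axes: list[np.ndarray]
    values: np.ndarray               # min-shifted to 0
    gamma: float


def _check_periodic(potential, dim: int, kT: float) -> None:
    pts = np.linspace(-180.0, 180.0, 5)
    for p in pts[:-1]:
        if dim == 1:
            a, b = potential(np.array([p])), potential(np.array([p - 360.0]))
        else:
            a = potential(np.array([p, -p / 2]))
            b = potential(np.array([p - 360.0, -p / 2 + 360.0]))
        if abs(float(a) - float(b)) > 1e-8 * max(1.0, kT):
            raise ValueError("potential is not 360-degree periodic")


def run_wtmetad(potential, n_steps: int, seed: int, w0: float = 0.5,
                gamma: float = 10.0, sigma=10.0, stride: int = 1000,
                kT: float = 1.0, dim: int = 1, step_size: float = 5.0,
                x0=None, grid_spacing: float | None = None):
    """Run well-tempered metadynamics; returns (cv_trajectory, BiasState).

    ``potential`` maps a length-``dim`` angle vector (degrees) to an energy
    in the same units as ``kT``.  ``w0`` is the initial Gaussian height
    (w0 = 0 recovers plain Metropolis sampling of ``potential``); ``sigma``
    the Gaussian width per dimension in degrees; ``stride`` the deposition
    period in steps.
    """
    if gamma <= 1.0:
        raise ValueError("bias factor gamma must be > 1")
    if w0 < 0:
        raise ValueError("initial height w0 must be >= 0")
    if dim not in (1, 2):
        raise ValueError("dim must be 1 or 2")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (dim,)).copy()
    if (sigma <= 0).any():
        raise ValueError("sigma must be > 0")
    _check_periodic(potential, dim, kT)
    if grid_spacing is None:
        grid_spacing = 1.0 if dim == 1 else 5.0
    axes = [np.arange(-180.0, 180.0, grid_spacing) for _ in range(dim)]
    shape = tuple(len(ax) for ax in axes)
    bias = BiasState(w0=float(w0), gamma=float(gamma), sigma=sigma,
                     stride=int(stride), kT=float(kT), dim=dim,
                     grid_axes=axes, bias_grid=np.zeros(shape))

    rng = np.random.default_rng(seed)
    x = np.zeros(dim) if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float))
    traj = np.empty((n_steps, dim))
    # index of the current position on each grid axis, for O(1) bias lookup
    def grid_index(xv):
        return tuple(int(np.argmin(np.abs(periodic_delta(ax, xi))))
                     for ax, xi in zip(axes, xv))

    u_cur = float(potential(x))
    moves = rng.normal(0.0, step_size, size=(n_steps, dim))
    accept_u = rng.random(n_steps)
    for step in range(1, n_steps + 1):
        xp = (x + moves[step - 1] + 180.0) % _PERIOD - 180.0
        u_prop = float(potential(xp))
        e_cur = u_cur + bias.bias_grid[grid_index(x)]
        e_prop = u_prop + bias.bias_grid[grid_index(xp)]
        if e_prop <= e_cur or accept_u[step - 1] < np.exp(-(e_prop - e_cur) / kT):
            x = xp
            u_cur = u_prop
        traj[step - 1] = x
        if w0 > 0 and step % stride == 0:
            bias.deposit(x, step)
    return traj, bias


def estimate_fes(bias: BiasState, average_last: float = 0.0) -> FESEstimate:
    """Well-tempered free-energy estimate from the accumulated bias.

    F(x) = -(gamma/(gamma-1)) V_bias(x), min-shifted.  With
    ``average_last`` in (0, 1], the min-shifted estimate is additionally
    averaged over the trailing fraction of depositions (the estimator
    fluctuates around the true surface once the bias is converged, so late
    averaging suppresses the residual noise).
    """
    if bias.n_depositions == 0:
        raise ValueError("no depositions: cannot estimate a free energy")
    pref = bias.gamma / (bias.gamma - 1.0)
    if average_last <= 0.0:
        F = -pref * bias.bias_grid
        return FESEstimate(grid_axes=bias.grid_axes, values=F - F.min(),
                           gamma=bias.gamma)
    n = bias.n_depositions
    start = max(1, int(np.ceil(n * (1.0 - average_last))))
    # rebuild the cumulative bias grid deposition by deposition
    grid = np.zeros_like(bias.bias_grid)
    acc = np.zeros_like(bias.bias_grid)
    n_acc = 0
    for i, (c, h) in enumerate(zip(bias.centers, bias.heights), start=1):
        if bias.dim == 1:
            d = periodic_delta(bias.grid_axes[0], c[0])
            grid += h * np.exp(-d ** 2 / (2 * bias.sigma[0] ** 2))
        else:
            d0 = periodic_delta(bias.grid_axes[0], c[0])[:, None]
            d1 = periodic_delta(bias.grid_axes[1], c[1])[None, :]
            grid += h * np.exp(-(d0 ** 2 / (2 * bias.sigma[0] ** 2)
                                 + d1 ** 2 / (2 * bias.sigma[1] ** 2)))
        if i >= start:
            F = -pref * grid
            acc += F - F.min()
            n_acc += 1
    return FESEstimate(grid_axes=bias.grid_axes, values=acc / n_acc,
                       gamma=bias.gamma)


def analytic_fes(potential, dim: int = 1, grid_spacing: float = 1.0) -> FESEstimate:
    """Reference free-energy surface: the potential itself on the grid,
    min-shifted (for analytic test potentials F == V up to a constant)."""
    axes = [np.arange(-180.0, 180.0, grid_spacing) for _ in range(dim)]
    if dim == 1:
        V = np.array([float(potential(np.array([t]))) for t in axes[0]])
    else:
        V = np.array([[float(potential(np.array([a, b]))) for b in axes[1]]
                      for a in axes[0]])
    return FESEstimate(grid_axes=axes, values=V - V.min(), gamma=np.inf)


def basin_free_energy_difference(fes: FESEstimate, kT: float,
                                 split: float = 0.0) -> float:
    """Delta F (units of the FES) between the two halves of a 1-D periodic
    domain separated at ``split`` and ``split - 180``: F_right - F_left by
    Boltzmann integration over each basin."""
    ax = fes.grid_axes[0]
    w = np.exp(-fes.values / kT)
    left = periodic_delta(ax, split) < 0
    z_left = w[left].sum()
    z_right = w[~left].sum()
    return float(-kT * (np.log(z_right) - np.log(z_left)))


def double_well(a: float = 2.0, b: float = 1.0):
    """Asymmetric periodic double well V(theta) = a cos(2 theta) + b sin(theta)
    (minima near +-90 degrees; b > 0 raises the +90 well and breaks the
    symmetry; b = 0 gives the symmetric well)."""
    def V(x):
        t = np.radians(np.atleast_1d(x)[0])
        return a * np.cos(2 * t) + b * np.sin(t)
    return V
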