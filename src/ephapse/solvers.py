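"""IMEX Crank-Nicolson integrators for the discrete and continuum sheet models.

Two models are integrated, both on a (lateral x axial) grid with zero-flux
boundaries and both starting from uniform rest:

* discrete sheet of N axons:
    dv_p/dt = sum_s B[p,s] d2v_s/dz2 - f(v_p, w_p) + I_p
    dw_p/dt = eps (v_p + a - b w_p)
  with ``B = 4(R+1) A^{-1}`` from :mod:`ephapse.coupling`;

* continuum field approximation:
    d2v/dz2 = i + K d2i/dx2,      i = dv/dt + f(v, w) - I
  advanced as dv/dt = M^{-1} d2v/dz2 - f + I, where
  ``M = 1 + K d2/dx2`` is the lateral Helmholtz-type operator, solved
  implicitly (this is equivalent to the integro-differential kernel form
  of the field model; the sin-kernel resonance of that form shows up here
  as a near-singular eigenvalue of M).

Time stepping is an IMEX split: Crank-Nicolson on the linear coupled
diffusion operator, explicit treatment of the reaction, stimulus, and
the recovery equation.  Two explicit splits are available: forward Euler
(``scheme="euler"``, the default and the reference split that defines
the model's operating point at dt = 0.05) and second-order
Adams-Bashforth (``scheme="ab2"``).  The distinction matters: lateral
recruitment near its onset (e.g. the three-impulse front of the discrete
sheet at R = 0.4) is a marginal phenomenon that is present under the
Euler split at the reference dt but absent both under AB2 and in the
dt -> 0 limit; see docs/methods.md.  The linear operator is separable — a lateral matrix
(B, or M^{-1}) tensored with the axial second difference — and both
factors are time invariant, so every CN solve is carried out in the
operator's eigenbasis: a dense (small) eigenvector transform laterally
and a type-I discrete cosine transform axially, which exactly
diagonalizes the mirrored-ghost zero-flux second difference.  A dense
brute-force step (:func:`dense_reference_step`) guards the fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft
import scipy.linalg

from .coupling import build_coupling_matrix
from .fhn import FHNParams, resting_state
from .stimulation import (
    ProtocolError,
    StimulusEvent,
    StimulusProtocol,
    evaluate_stimulus,
)

__all__ = [
    "GridSpec",
    "FieldState",
    "SimulationResult",
    "StabilityError",
    "ResonanceError",
    "PropagationError",
    "simulate_discrete",
    "simulate_continuum",
    "simulate_single_cable",
    "dense_reference_step",
    "estimate_pulse_speed",
    "axial_operator_matrix",
    "lateral_operator_discrete",
    "lateral_operator_continuum",
]


class StabilityError(RuntimeError):
    """Raised when the solution leaves the finite range (NaN/Inf)."""


class ResonanceError(ValueError):
    """Raised when the lateral Helmholtz operator of the continuum model
    is (near-)singular for the requested K and dx."""


class PropagationError(RuntimeError):
    """Raised when no propagating impulse is detected."""


@dataclass(frozen=True)
class GridSpec:
    """Space-time discretization shared by both models.

    Defaults follow the sheet model's reference discretization: 50
    lateral nodes, axial step ``dz = 0.5``, lateral step ``dx = 1``
    (continuum only), time step ``dt = 0.05``, snapshots every 1 time
    unit.  ``z_extent`` is the axial domain length; pass ``None`` to let
    the caller auto-size it from the measured pulse speed.
    """

    z_extent: float
    t_end: float
    n_lateral: int = 50
    dz: float = 0.5
    dx: float = 1.0
    dt: float = 0.05
    snapshot_every: float = 1.0

    def __post_init__(self) -> None:
        for name in ("z_extent", "t_end", "dz", "dx", "dt", "snapshot_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lateral < 1:
            raise ValueError("n_lateral must be >= 1")
        for num, den, what in (
            (self.z_extent, self.dz, "z_extent/dz"),
            (self.t_end, self.dt, "t_end/dt"),
            (self.snapshot_every, self.dt, "snapshot_every/dt"),
        ):
            ratio = num / den
            if abs(ratio - round(ratio)) > 1e-8 * max(1.0, ratio):
                raise ValueError(f"{what} = {ratio} is not integral")

    @property
    def n_z(self) -> int:
        return int(round(self.z_extent / self.dz)) + 1

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def z_coords(self) -> np.ndarray:
        return np.arange(self.n_z) * self.dz

    @property
    def snapshot_stride(self) -> int:
        return int(round(self.snapshot_every / self.dt))


@dataclass
class FieldState:
    """Fields on the grid at one instant.  ``i`` only for the continuum."""

    v: np.ndarray
    w: np.ndarray
    t: float
    i: np.ndarray | None = None

    def require_finite(self, dt: float) -> None:
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.w))):
            raise StabilityError(
                f"non-finite field at t={self.t:.3f}; the explicit reaction "
                f"step is unstable at dt={dt} — reduce the time step"
            )


@dataclass
class SimulationResult:
    """Time-stamped snapshots plus full provenance of a run."""

    times: np.ndarray
    v: np.ndarray  # (n_snapshots, n_lateral, n_z)
    model: str  # "discrete" | "continuum"
    coupling: float  # R (discrete) or K (continuum)
    grid: GridSpec
    fhn: FHNParams
    protocol: StimulusProtocol
    w: np.ndarray | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.v):
            raise ValueError("times and v snapshot counts differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def coupling_name(self) -> str:
        return "R" if self.model == "discrete" else "K"


# ---------------------------------------------------------------------------
# linear operators


def axial_operator_matrix(n_z: int, dz: float) -> np.ndarray:
    """Axial second difference with second-order mirrored-ghost zero-flux rows.

    The ghost values ``v[-1] = v[1]`` and ``v[n] = v[n-2]`` make the
    boundary rows ``(2 v[1] - 2 v[0]) / dz^2`` (and mirrored at the far
    end); the type-I DCT cosines are exact eigenvectors of this matrix.
    """
    T = np.zeros((n_z, n_z))
    for j in range(n_z):
        T[j, j] = -2.0
        if j > 0:
            T[j, j - 1] += 1.0
        if j < n_z - 1:
            T[j, j + 1] += 1.0
    if n_z > 1:
        T[0, 1] = 2.0
        T[-1, -2] = 2.0
    return T / dz**2


def lateral_operator_discrete(n_lateral: int, R: float) -> np.ndarray:
    """Effective diffusion matrix B of the discrete sheet."""
    return build_coupling_matrix(n_lateral, R).B


def lateral_operator_continuum(n_x: int, K: float, dx: float = 1.0) -> np.ndarray:
    """Inverse lateral Helmholtz operator ``(1 + K d2/dx2)^{-1}``."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    M = np.eye(n_x) + K * axial_operator_matrix(n_x, dx)
    eigvals = np.linalg.eigvals(M)
    if np.min(np.abs(eigvals)) < 1e-8:
        raise ResonanceError(
            f"lateral operator 1 + K d2/dx2 is singular for K={K}, dx={dx}; "
            "choose a different K or dx"
        )
    return np.linalg.inv(M)


def _axial_eigenvalues(n_z: int, dz: float) -> np.ndarray:
    k = np.arange(n_z)
    if n_z == 1:
        return np.zeros(1)
    return (2.0 * np.cos(np.pi * k / (n_z - 1)) - 2.0) / dz**2


def _lateral_eigensystem(model: str, grid: GridSpec, coupling: float):
    """Eigenvalues and (V, Vinv) of the lateral factor of the operator."""
    n = grid.n_lateral
    if model == "discrete":
        B = lateral_operator_discrete(n, coupling)
        lam, V = np.linalg.eigh(B)
        return lam, V, V.T
    if n == 1:
        mu_x = np.zeros(1)
        C = np.eye(1)
    else:
        j = np.arange(n)[:, None]
        k = np.arange(n)[None, :]
        C = np.cos(np.pi * j * k / (n - 1))
        mu_x = _axial_eigenvalues(n, grid.dx)
    helm = 1.0 + coupling * mu_x
    if np.min(np.abs(helm)) < 1e-8:
        raise ResonanceError(
            f"lateral operator 1 + K d2/dx2 is singular for K={coupling}, "
            f"dx={grid.dx}; choose a different K or dx"
        )
    lam = 1.0 / helm
    return lam, C, np.linalg.inv(C)


class _SpectralStepper:
    """One IMEX-CN step in the eigenbasis of the separable linear operator."""

    def __init__(self, model: str, grid: GridSpec, coupling: float,
                 fhn: FHNParams, linear_only: bool = False,
                 scheme: str = "euler"):
        if scheme not in ("euler", "ab2"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.grid = grid
        self.fhn = fhn
        self.linear_only = linear_only
        self.scheme = scheme
        lam_lat, V, Vinv = _lateral_eigensystem(model, grid, coupling)
        mu_z = _axial_eigenvalues(grid.n_z, grid.dz)
        lam = np.outer(lam_lat, mu_z)  # (n_lateral, n_z) operator spectrum
        h = 0.5 * grid.dt
        self.V, self.Vinv = V, Vinv
        self.numer = 1.0 + h * lam
        self.denom = 1.0 - h * lam
        self.dt = grid.dt
        self._prev_explicit = None
        self._prev_w_rate = None

    def _dct(self, x: np.ndarray) -> np.ndarray:
        if self.grid.n_z == 1:
            return x
        return scipy.fft.dct(x, type=1, axis=-1)

    def _idct(self, x: np.ndarray) -> np.ndarray:
        if self.grid.n_z == 1:
            return x
        return scipy.fft.idct(x, type=1, axis=-1)

    def step(self, state: FieldState, stim: np.ndarray) -> FieldState:
        """CNAB2 step: CN on the diffusion, AB2 on reaction + stimulus.

        The AB2 history (previous explicit term and w-rate) is kept on
        the stepper; the first call falls back to forward Euler.
        """
        v, w = state.v, state.w
        fhn = self.fhn
        if self.linear_only:
            explicit = stim
            w_rate = None
        else:
            explicit = (v - v * v * v / 3.0 - w) + stim  # -f(v, w) + I
            w_rate = fhn.eps * (v + fhn.a - fhn.b * w)
        if self.scheme == "euler" or self._prev_explicit is None:
            e_eff = explicit
            w_eff = w_rate
        else:
            e_eff = 1.5 * explicit - 0.5 * self._prev_explicit
            if not self.linear_only:
                w_eff = 1.5 * w_rate - 0.5 * self._prev_w_rate
        n = self.grid.n_lateral
        stacked = self._dct(np.concatenate([v, e_eff], axis=0))
        v_hat = self.Vinv @ stacked[:n]
        e_hat = self.Vinv @ stacked[n:]
        new_hat = (self.numer * v_hat + self.dt * e_hat) / self.denom
        v_new = self._idct(self.V @ new_hat)
        if self.linear_only:
            w_new = w
        else:
            w_new = w + self.dt * w_eff
        if self.scheme == "ab2":
            self._prev_explicit = explicit
            self._prev_w_rate = w_rate
        return FieldState(v=v_new, w=w_new, t=state.t + self.dt)


def _validate_protocol(protocol: StimulusProtocol, grid: GridSpec) -> None:
    for e in protocol.events:
        if not (1 <= e.lateral_index <= grid.n_lateral):
            raise ProtocolError(
                f"event lateral index {e.lateral_index} outside "
                f"[1, {grid.n_lateral}]"
            )
        if e.z_window[0] < 0 or e.z_window[1] > grid.z_extent:
            raise ProtocolError(
                f"event z_window {e.z_window} outside [0, {grid.z_extent}]"
            )
        if e.onset >= grid.t_end:
            raise ProtocolError(
                f"event onset {e.onset} beyond t_end={grid.t_end}"
            )


def _run(model: str, grid: GridSpec, coupling: float, fhn: FHNParams,
         protocol: StimulusProtocol, store_w: bool, seed: int | None,
         linear_only: bool = False, scheme: str = "euler",
         initial: FieldState | None = None) -> SimulationResult:
    _validate_protocol(protocol, grid)
    stepper = _SpectralStepper(model, grid, coupling, fhn,
                               linear_only=linear_only, scheme=scheme)
    if initial is None:
        rest = resting_state(fhn)
        shape = (grid.n_lateral, grid.n_z)
        state = FieldState(v=np.full(shape, rest.v_star),
                           w=np.full(shape, rest.w_star), t=0.0)
    else:
        state = initial
    stride = grid.snapshot_stride
    n_steps = grid.n_steps
    n_snap = n_steps // stride + 1
    times = np.empty(n_snap)
    v_snap = np.empty((n_snap, grid.n_lateral, grid.n_z))
    w_snap = np.empty_like(v_snap) if store_w else None
    # pre-scan event boundaries so evaluate_stimulus is only called while
    # some boxcar is active
    active_any = np.zeros(n_steps, dtype=bool)
    for e in protocol.events:
        i0 = int(np.floor(e.onset / grid.dt))
        i1 = min(n_steps, int(np.ceil((e.onset + e.duration) / grid.dt)) + 1)
        active_any[i0:i1] = True
    zeros = np.zeros((grid.n_lateral, grid.n_z))
    k = 0
    for step in range(n_steps + 1):
        if step % stride == 0:
            times[k] = state.t
            v_snap[k] = state.v
            if store_w:
                w_snap[k] = state.w
            state.require_finite(grid.dt)
            k += 1
        if step == n_steps:
            break
        stim = evaluate_stimulus(protocol, state.t, grid) if active_any[step] else zeros
        state = stepper.step(state, stim)
    return SimulationResult(times=times, v=v_snap, w=w_snap, model=model,
                            coupling=float(coupling), grid=grid, fhn=fhn,
                            protocol=protocol, seed=seed)


def simulate_discrete(grid: GridSpec, R: float, fhn: FHNParams,
                      protocol: StimulusProtocol, store_w: bool = False,
                      seed: int | None = None, scheme: str = "euler",
                      _linear_only: bool = False) -> SimulationResult:
    """Integrate the discrete sheet of ``grid.n_lateral`` coupled axons.

    ``_linear_only`` is a test hook that disables the reaction, stimulus
    aside, leaving the pure coupled-diffusion operator (used for
    conservation checks)."""
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    return _run("discrete", grid, R, fhn, protocol, store_w, seed,
                linear_only=_linear_only, scheme=scheme)


def simulate_continuum(grid: GridSpec, K: float, fhn: FHNParams,
                       protocol: StimulusProtocol, store_w: bool = False,
                       seed: int | None = None, scheme: str = "euler",
                       _linear_only: bool = False) -> SimulationResult:
    """Integrate the continuum field model at lateral coupling ``K >= 0``."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    return _run("continuum", grid, K, fhn, protocol, store_w, seed,
                linear_only=_linear_only, scheme=scheme)


def simulate_single_cable(grid: GridSpec, fhn: FHNParams,
                          protocol: StimulusProtocol,
                          store_w: bool = False) -> SimulationResult:
    """Uncoupled FitzHugh-Nagumo cable (continuum model, one column, K=0)."""
    g1 = replace(grid, n_lateral=1)
    return _run("continuum", g1, 0.0, fhn, protocol, store_w, None)


# ---------------------------------------------------------------------------
# dense reference step (test oracle)

_MAX_DENSE = (20, 100)


def dense_reference_step(state: FieldState, lateral: np.ndarray,
                         axial: np.ndarray, fhn: FHNParams, dt: float,
                         stim: np.ndarray | None = None,
                         linear_only: bool = False,
                         history: dict | None = None) -> FieldState:
    """One IMEX CNAB2 step via the fully assembled dense linear system.

    ``lateral`` is the lateral operator matrix (B for the discrete model,
    ``(1 + K d2/dx2)^{-1}`` for the continuum) and ``axial`` the axial
    second-difference matrix; the full operator is their Kronecker
    product.  ``history`` carries the previous explicit term and w-rate
    for the Adams-Bashforth weights (pass the same dict across calls; an
    empty dict bootstraps with forward Euler, like the production
    stepper).  Deliberately brute force and restricted to small grids;
    the production solver is tested against repeated applications of
    this step.
    """
    n_lat, n_z = state.v.shape
    if n_lat > _MAX_DENSE[0] or n_z > _MAX_DENSE[1]:
        raise ValueError(
            f"dense reference step limited to grids <= {_MAX_DENSE}, "
            f"got ({n_lat}, {n_z})"
        )
    L = np.kron(lateral, axial)
    v = state.v.reshape(-1)
    if stim is None:
        stim = np.zeros_like(state.v)
    if linear_only:
        explicit = stim
        w_rate = None
        w_new = state.w
    else:
        v0 = state.v
        explicit = v0 - v0 * v0 * v0 / 3.0 - state.w + stim
        w_rate = fhn.eps * (state.v + fhn.a - fhn.b * state.w)
    e_eff, w_eff = explicit, w_rate
    if history is not None and "explicit" in history:
        e_eff = 1.5 * explicit - 0.5 * history["explicit"]
        if not linear_only:
            w_eff = 1.5 * w_rate - 0.5 * history["w_rate"]
    if history is not None:
        history["explicit"] = explicit
        history["w_rate"] = w_rate
    if not linear_only:
        w_new = state.w + dt * w_eff
    h = 0.5 * dt
    eye = np.eye(len(v))
    rhs = (eye + h * L) @ v + dt * e_eff.reshape(-1)
    v_new = np.linalg.solve(eye - h * L, rhs)
    return FieldState(v=v_new.reshape(n_lat, n_z), w=w_new, t=state.t + dt)


# ---------------------------------------------------------------------------
# pulse speed


def estimate_pulse_speed(grid: GridSpec | None = None, R: float | None = None,
                         K: float | None = None,
                         fhn: FHNParams | None = None,
                         threshold: float = 0.0) -> float:
    """Traveling-pulse speed from a single-impulse run.

    Launches one impulse at the inlet of the middle axon/column of the
    requested model (uncoupled cable if neither ``R`` nor ``K`` is given)
    and regresses the position of the leading threshold crossing against
    time over the latter half of the run, before the front reaches the
    far boundary.  Used to auto-size ``z_extent`` so impulses never hit
    the boundary within ``t_end``.
    """
    fhn = fhn or FHNParams()
    if grid is None:
        grid = GridSpec(z_extent=200.0, t_end=200.0, n_lateral=1)
    protocol = StimulusProtocol(
        events=(StimulusEvent(lateral_index=(grid.n_lateral + 1) // 2, onset=0.0),)
    )
    if R is not None:
        result = simulate_discrete(grid, R, fhn, protocol)
    else:
        result = simulate_continuum(grid, K if K is not None else 0.0, fhn, protocol)
    lat = (grid.n_lateral + 1) // 2 - 1
    z = grid.z_coords
    fronts, times = [], []
    for t, snap in zip(result.times, result.v[:, lat, :]):
        above = np.nonzero(snap > threshold)[0]
        if len(above):
            zf = z[above[-1]]
            if zf < 0.95 * grid.z_extent:
                fronts.append(zf)
                times.append(t)
    if len(fronts) < 10:
        raise PropagationError("no propagating impulse detected")
    fronts = np.asarray(fronts)
    times = np.asarray(times)
    half = len(times) // 2
    slope = np.polyfit(times[half:], fronts[half:], 1)[0]
    if slope <= 0:
        raise PropagationError(f"non-positive front speed {slope}")
    return float(slope)


def auto_z_extent(t_end: float, speed: float, dz: float = 0.5,
                  margin: float = 20.0) -> float:
    """Axial extent such that a pulse launched at t=0 stays inside."""
    extent = speed * t_end + margin
    return float(np.ceil(extent / dz) * dz)
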