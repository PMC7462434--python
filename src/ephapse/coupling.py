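"""Ephaptic coupling operator for a sheet of N axons.

The sheet model couples the axial diffusion of every axon to every other
axon through the shared extracellular space.  The coupling strengths are
the entries of the inverse of a symmetric tridiagonal matrix ``A`` with
constant diagonal ``D = 4(R + 1/2)`` and unit off-diagonals, where
``R = r_a / r_e`` is the ratio of axoplasmic to extracellular longitudinal
resistance per unit length.  Small ``R`` (high extracellular resistance)
means strong ephaptic interaction.

The object the solver consumes is the effective diffusion matrix
``B = 4(R + 1) * A^{-1}``: in the nondimensional sheet equations the axial
diffusion term of axon ``p`` reads ``sum_s B[p, s] d2v_s/dz2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalParameters",
    "NondimensionalParams",
    "CouplingMatrix",
    "build_coupling_matrix",
    "closed_form_inverse_entry",
    "physical_to_nondimensional",
]


class ParameterError(ValueError):
    """Raised for physically meaningless model parameters."""


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional cable and geometry parameters.

    Parameters
    ----------
    r_a, r_e : float
        Axoplasmic and extracellular longitudinal resistance per unit
        length (Ohm/length).
    c : float
        Membrane capacitance per unit length.
    g : float
        Membrane conductance per unit length.
    delta : float
        Interaxonal spacing (length).
    lam : float
        Characteristic lateral length scale, of the order of the axonal
        diameter (length).
    rho : float
        Extracellular-to-intracellular resistivity ratio (dimensionless).
        Values outside the physiologically plausible band [1, 4] trigger
        a warning, not an error.
    A_e, A_a : float
        Cross-sectional areas of the extracellular space and of the axon.
    """

    r_a: float
    r_e: float
    c: float
    g: float
    delta: float
    lam: float
    rho: float
    A_e: float
    A_a: float

    def __post_init__(self) -> None:
        for name in ("r_a", "r_e", "c", "g", "delta", "lam", "rho", "A_e", "A_a"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value!r}")
        if not (1.0 <= self.rho <= 4.0):
            warnings.warn(
                f"resistivity ratio rho={self.rho} lies outside the plausible "
                "band [1, 4]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NondimensionalParams:
    """Nondimensional coupling parameters and the rescaling factors.

    ``R`` controls the discrete sheet model, ``K`` the continuum field
    model; ``K = (delta^2/lambda^2) / (R + 1)``.  ``space_scale`` and
    ``time_scale`` are the factors that map dimensional ``z`` and ``t``
    onto the nondimensional variables (``z_nd = space_scale * z``,
    ``t_nd = time_scale * t``).
    """

    R: float
    K: float
    delta2_over_lam2: float = 0.01
    space_scale: float = field(default=np.nan)
    time_scale: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ParameterError(f"R must be > 0, got {self.R}")
        if self.K < 0:
            raise ParameterError(f"K must be >= 0, got {self.K}")


@dataclass(frozen=True)
class CouplingMatrix:
    """The tridiagonal operator ``A``, its inverse and the diffusion matrix.

    Attributes
    ----------
    n : int
        Number of axons.
    R : float
        Resistance ratio r_a/r_e.
    D : float
        Constant diagonal of ``A``, equal to ``4(R + 1/2)``.
    A : ndarray, shape (n, n)
        Symmetric tridiagonal matrix, diagonal ``D``, off-diagonals 1.
    alpha : ndarray, shape (n, n)
        Dense inverse of ``A``; ``alpha[p, s]`` is the coupling strength
        between axons ``p`` and ``s`` (sign alternating with distance).
    B : ndarray, shape (n, n)
        Effective diffusion matrix ``4(R + 1) * alpha``; tends to the
        identity in the weak-coupling limit R -> inf.
    """

    n: int
    R: float
    D: float
    A: np.ndarray
    alpha: np.ndarray
    B: np.ndarray

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


def build_coupling_matrix(n_axons: int, R: float) -> CouplingMatrix:
    """Construct the coupling operator for ``n_axons`` axons at ratio ``R``.

    The first and last rows of ``A`` carry a single unit off-diagonal:
    the edge axons feed current into only one interior extracellular
    node, which is exactly the edge form of the discrete sheet equations.

    Raises
    ------
    ParameterError
        If ``n_axons < 1`` or ``R <= 0``.
    """
    if int(n_axons) != n_axons or n_axons < 1:
        raise ParameterError(f"n_axons must be a positive integer, got {n_axons!r}")
    if not np.isfinite(R) or R <= 0:
        raise ParameterError(f"R must be strictly positive, got {R!r}")
    n = int(n_axons)
    D = 4.0 * (R + 0.5)
    A = np.diag(np.full(n, D))
    idx = np.arange(n - 1)
    A[idx, idx + 1] = 1.0
    A[idx + 1, idx] = 1.0
    # Strict diagonal dominance (D > 2 for R > 0) guarantees invertibility;
    # the dense inverse is cheap at the model's lateral sizes (n ~ 50).
    alpha = np.linalg.inv(A)
    alpha = 0.5 * (alpha + alpha.T)  # enforce exact symmetry against roundoff
    B = 4.0 * (R + 1.0) * alpha
    return CouplingMatrix(n=n, R=float(R), D=D, A=A, alpha=alpha, B=B)


def closed_form_inverse_entry(n: int, D: float, p: int, s: int) -> float:
    """Closed-form entry ``alpha[p, s]`` of the inverse tridiagonal matrix.

    Uses the continuant (three-term recurrence) form for a symmetric
    tridiagonal matrix with constant diagonal ``D`` and unit
    off-diagonals:

        alpha_ps = (-1)^(p+s) * theta_{min(p,s)-1} * theta_{n-max(p,s)} / theta_n

    with ``theta_0 = 1``, ``theta_1 = D``,
    ``theta_k = D theta_{k-1} - theta_{k-2}``.  Indices are 1-based.
    Serves as an independent oracle for :func:`build_coupling_matrix`.
    """
    if int(n) != n or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n!r}")
    if D <= 2.0:
        raise ParameterError(f"D must exceed 2 for an excitable sheet, got {D!r}")
    if not (1 <= p <= n) or not (1 <= s <= n):
        raise IndexError(f"indices (p={p}, s={s}) out of range for n={n}")
    theta = np.empty(n + 1)
    theta[0] = 1.0
    theta[1] = D
    for k in range(2, n + 1):
        theta[k] = D * theta[k - 1] - theta[k - 2]
    lo, hi = min(p, s), max(p, s)
    sign = -1.0 if (p + s) % 2 else 1.0
    return float(sign * theta[lo - 1] * theta[n - hi] / theta[n])


def physical_to_nondimensional(phys: PhysicalParameters) -> NondimensionalParams:
    """Map dimensional cable parameters to the nondimensional pair (R, K).

    ``R = (1/rho) * (A_e / A_a)`` and ``K = (delta^2 / lambda^2) / (R + 1)``.
    The returned scales nondimensionalize the axial coordinate and time:
    ``z_nd = sqrt(g (r_a + r_e)) * z`` and ``t_nd = (g / c) * t``.
    """
    R = (1.0 / phys.rho) * (phys.A_e / phys.A_a)
    d2l2 = (phys.delta / phys.lam) ** 2
    K = d2l2 / (R + 1.0)
    return NondimensionalParams(
        R=R,
        K=K,
        delta2_over_lam2=d2l2,
        space_scale=float(np.sqrt(phys.g * (phys.r_a + phys.r_e))),
        time_scale=phys.g / phys.c,
    )
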