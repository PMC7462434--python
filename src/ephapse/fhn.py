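"""FitzHugh-Nagumo membrane kinetics shared by both sheet models.

The membrane current nonlinearity is ``f(v, w) = -(v - v^3/3 - w)`` with
the slow recovery variable obeying ``dw/dt = eps * (v + a - b*w)``.  With
this sign convention the uncoupled nondimensional cable reads

    dv/dt = d2v/dz2 - f(v, w) + I = d2v/dz2 + v - v^3/3 - w + I,

i.e. the standard excitable FitzHugh-Nagumo cable: a suprathreshold
perturbation of the rest state elicits a full action-potential excursion
that propagates with its shape preserved, followed by a refractory
period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FHNParams", "RestingState", "fhn_reaction", "resting_state"]


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo constants.

    a : recovery offset (default 0.7)
    b : recovery decay (default 0.5)
    eps : timescale separation between v and w (default 0.1)
    """

    a: float = 0.7
    b: float = 0.5
    eps: float = 0.1

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")


@dataclass(frozen=True)
class RestingState:
    """Fixed point (v*, w*) of the point FHN model (no diffusion, no input)."""

    v_star: float
    w_star: float


def fhn_reaction(v: np.ndarray, w: np.ndarray, params: FHNParams):
    """Evaluate the membrane nonlinearity and the recovery rate elementwise.

    Returns
    -------
    f_value : ndarray
        ``-(v - v^3/3 - w)``; enters the cable equation with a minus sign.
    w_rate : ndarray
        ``eps * (v + a - b*w)``, the time derivative of ``w``.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"shape mismatch: v{v.shape} vs w{w.shape}")
    f_value = -(v - v * v * v / 3.0 - w)  # v*v*v: numpy's pow is slow for v<0
    w_rate = params.eps * (v + params.a - params.b * w)
    return f_value, w_rate


def resting_state(params: FHNParams) -> RestingState:
    """Solve the nullcline intersection for the rest state.

    Rest satisfies ``v - v^3/3 - w = 0`` and ``w = (v + a)/b``, i.e. the
    cubic ``b*(v - v^3/3) - (v + a) = 0``.  For the default parameters the
    cubic has a single real root, v* ~ -1.0329.  If several real roots
    exist (possible for other parameter choices) the most negative one is
    returned with a warning.

    The returned state is additionally checked for linear stability of
    the point model; an unstable rest state raises, because every
    simulation starts from it.
    """
    a, b = params.a, params.b
    # b*(v - v^3/3) - v - a = 0  ->  (-b/3) v^3 + (b - 1) v - a = 0
    roots = np.roots([-b / 3.0, 0.0, b - 1.0, -a])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    if len(real) == 0:  # pragma: no cover - cubic always has a real root
        raise RuntimeError("no real rest state found")
    if len(real) > 1:
        warnings.warn(
            f"{len(real)} real rest candidates for a={a}, b={b}; "
            "returning the most negative",
            stacklevel=2,
        )
    v_star = float(real[0])
    w_star = (v_star + a) / b
    # Jacobian of the point model dv/dt = v - v^3/3 - w, dw/dt = eps(v+a-bw)
    tr = (1.0 - v_star**2) - params.eps * b
    det = -(1.0 - v_star**2) * params.eps * b + params.eps
    if tr >= 0 or det <= 0:
        raise ValueError(
            f"rest state v*={v_star:.4f} is not linearly stable for "
            f"a={a}, b={b}, eps={params.eps}"
        )
    return RestingState(v_star=v_star, w_star=w_star)
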