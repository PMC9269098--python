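"""Three-compartment FLIP kinetics with closed-form eigenvalues.

The model describes fluorescence loss in a cell whose tagged protein
occupies three well-mixed pools: cytoplasmic aggregates ``A``, the
cytoplasm ``C``, and the nucleus ``N``. Repeated bleaching of a region in
the cytoplasm acts as a first-order loss with effective rate ``k3`` on the
whole cytoplasmic pool (the bleach-limited regime: diffusion is fast
relative to bleaching, so spatial gradients inside each compartment are
ignored). Protein shuttles between cytoplasm and nucleus with rates ``k1``
(C→N) and ``k_m1`` (N→C), and is slowly released from already-formed
aggregates at rate ``k2`` with no rebinding.

The linear ODE system is

    dA/dt = -k2 A
    dC/dt =  k2 A + k_m1 N - (k1 + k3) C
    dN/dt =  k1 C - k_m1 N

Because the aggregate pool feeds the rest but receives nothing back, its
eigenvalue decouples: ``l1 = -k2`` exactly. The remaining two eigenvalues
are the characteristic roots of the 2x2 cytoplasm/nucleus sub-system,

    l2, l3 = [-(k1 + k_m1 + k3) -/+ sqrt((k1 + k_m1 + k3)^2 - 4 k_m1 k3)] / 2

with l2 <= l3 <= 0 for non-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm


@dataclass(frozen=True)
class RateConstants:
    """Kinetic rate constants, all in s^-1 and non-negative.

    k1    : cytoplasm → nucleus exchange rate
    k_m1  : nucleus → cytoplasm exchange rate
    k2    : aggregate release rate (aggregates → cytoplasm)
    k3    : effective bleach rate acting on the cytoplasmic pool
    """

    k1: float
    k_m1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_m1", "k2", "k3"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0; got {val}")


@dataclass(frozen=True)
class CompartmentState:
    """Intensities (arbitrary units, >= 0) of the three pools."""

    A: float
    C: float
    N: float

    def __post_init__(self) -> None:
        for name in ("A", "C", "N"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"compartment intensity {name} must be finite and >= 0; got {val}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.C, self.N], dtype=float)


@dataclass(frozen=True)
class ModelEigenvalues:
    """Analytic eigenvalues of the kinetic system, in s^-1.

    l1 : aggregate eigenvalue, identically -k2
    l2 : fast eigenvalue of the cytoplasm/nucleus sub-system (most negative)
    l3 : slow eigenvalue of the cytoplasm/nucleus sub-system
    """

    l1: float
    l2: float
    l3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3], dtype=float)


def system_matrix(rates: RateConstants) -> np.ndarray:
    """Return the 3x3 matrix M with d[A, C, N]/dt = M @ [A, C, N].

    Mass leaves the system only through bleaching: every column sums to
    zero except the C column, which sums to -k3.
    """
    k1, k_m1, k2, k3 = rates.k1, rates.k_m1, rates.k2, rates.k3
    return np.array(
        [
            [-k2, 0.0, 0.0],
            [k2, -(k1 + k3), k_m1],
            [0.0, k1, -k_m1],
        ]
    )


def eigenvalues(rates: RateConstants) -> ModelEigenvalues:
    """Closed-form eigenvalues of :func:`system_matrix`.

    ``l1 = -k2`` (the aggregate pool is decoupled in the loss direction);
    ``l2``/``l3`` are the minus/plus characteristic roots of the 2x2
    nucleus–cytoplasm block. Both roots are real and non-positive for
    non-negative rates (the discriminant ``(k1+k_m1+k3)^2 - 4 k_m1 k3``
    is ``(k1+k_m1-k3)^2 + 4 k1 k3 >= 0``).
    """
    k1, k_m1, k3 = rates.k1, rates.k_m1, rates.k3
    trace = k1 + k_m1 + k3
    disc = trace * trace - 4.0 * k_m1 * k3
    root = np.sqrt(max(disc, 0.0))
    l2 = (-trace - root) / 2.0
    l3 = (-trace + root) / 2.0
    return ModelEigenvalues(l1=-rates.k2, l2=l2, l3=l3)


def solve(rates: RateConstants, init: CompartmentState, t: float) -> CompartmentState:
    """Exact state at time ``t`` (seconds) via the matrix exponential.

    ``A(t) = A0 exp(-k2 t)`` analytically; ``C`` and ``N`` follow the full
    linear system, each trajectory a linear combination of
    ``exp(l1 t), exp(l2 t), exp(l3 t)``.
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"time must be finite and >= 0; got {t}")
    out = expm(system_matrix(rates) * t) @ init.as_array()
    # exact-arithmetic non-negativity can be lost to rounding at ~1e-16
    out = np.where(np.abs(out) < 1e-12 * max(init.as_array().max(), 1.0), np.maximum(out, 0.0), out)
    return CompartmentState(A=out[0], C=out[1], N=out[2])


def trajectory(rates: RateConstants, init: CompartmentState, times: np.ndarray) -> np.ndarray:
    """Vectorised :func:`solve`: shape ``(len(times), 3)`` array of [A, C, N].

    Uses the eigen-decomposition of the system matrix, which is exact for
    this linear system and cheap to evaluate at many time points.
    """
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("times must be >= 0")
    M = system_matrix(rates)
    w, V = np.linalg.eig(M)
    if np.linalg.cond(V) < 1e8:
        coeffs = np.linalg.solve(V, init.as_array())
        out = np.real(np.exp(np.outer(times, w)) * coeffs @ V.T)
    else:
        # near-defective system (coincident eigenvalues): matrix exponential per time
        out = np.stack([expm(M * t) @ init.as_array() for t in times])
    return np.maximum(out, 0.0)


def rates_to_json_dict(rates: RateConstants) -> dict:
    return {"k1": rates.k1, "k_m1": rates.k_m1, "k2": rates.k2, "k3": rates.k3}


def rates_from_json_dict(d: dict) -> RateConstants:
    return RateConstants(k1=d["k1"], k_m1=d["k_m1"], k2=d["k2"], k3=d["k3"])
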