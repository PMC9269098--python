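"""Exact dynamic mode decomposition (DMD) of an image stack.

Each frame is flattened into a column vector; the stack becomes a pair of
snapshot matrices X (frames 1..k-1) and X' (frames 2..k) shifted by one
frame. DMD seeks the best linear propagator A with X' ≈ A X (a
finite-dimensional approximation of the Koopman operator), but never
forms A explicitly: a truncated SVD X ≈ U_r S_r V_r* projects the
dynamics onto rank r,

    A' = U_r* X' V_r S_r^{-1},

whose eigen-decomposition A' W = W Λ yields the DMD eigenvalues λ_j and
the (exact-DMD) spatial modes

    Φ = X' V_r S_r^{-1} W.

Discrete eigenvalues are rescaled to physical per-second rates via the
principal complex logarithm, ω_j = log(λ_j) / Δt, so that |λ| < 1
corresponds to Re ω < 0 (fluorescence decay). Mode amplitudes b solve the
least-squares problem Φ b ≈ x_1 (the first snapshot), and the stack is
approximated by

    x(t) = Σ_j φ_j e^{ω_j t} b_j .

The truncation rank defaults to the Gavish–Donoho optimal singular-value
hard threshold, which separates signal from additive-noise singular
values without a tuning parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .stack import ImageStack


@dataclass
class SnapshotPair:
    """Time-shifted snapshot matrices X, X' (n_pixels × (k-1) each)."""

    X: np.ndarray
    X_prime: np.ndarray
    dt: float
    image_shape: tuple[int, int]


@dataclass
class SVDFactors:
    """Truncated SVD of X with the full singular spectrum retained for
    diagnostics."""

    U_r: np.ndarray
    S_r: np.ndarray
    V_r: np.ndarray
    r: int
    full_spectrum: np.ndarray


@dataclass
class DMDModel:
    """A fitted DMD: modes Phi (n_pixels × r), discrete eigenvalues lam,
    continuous eigenvalues omega = log(lam)/dt (s^-1), amplitudes b.

    Modes are sorted by |omega| ascending (slowest dynamics first); this
    ordering defines mode indices in every output.
    """

    Phi: np.ndarray
    lam: np.ndarray
    omega: np.ndarray
    b: np.ndarray
    dt: float
    image_shape: tuple[int, int]
    r: int
    singular_values: np.ndarray | None = None
    n_input_frames: int | None = None

    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]


def stack_to_snapshots(stack: ImageStack) -> SnapshotPair:
    """Flatten frames (row-major) into the shifted snapshot pair.

    Column n of X is frame n; column n of X' is frame n+1. Invertible:
    :func:`snapshots_to_stack` restores the original stack bit-exactly.
    """
    k = stack.n_frames
    if k < 3:
        raise ValueError(f"need at least 3 frames to form a shifted snapshot pair; got {k}")
    flat = stack.data.reshape(k, -1).T  # n_pixels × k
    return SnapshotPair(
        X=flat[:, :-1].copy(),
        X_prime=flat[:, 1:].copy(),
        dt=stack.dt,
        image_shape=stack.image_shape,
    )


def snapshots_to_stack(pair: SnapshotPair) -> ImageStack:
    """Inverse of :func:`stack_to_snapshots` (all k frames)."""
    full = np.concatenate([pair.X, pair.X_prime[:, -1:]], axis=1)
    h, w = pair.image_shape
    return ImageStack(full.T.reshape(-1, h, w), pair.dt)


def gavish_donoho_omega(beta: float) -> float:
    """Approximate optimal hard-threshold coefficient ω(β) for unknown
    noise level: 0.56 β³ − 0.95 β² + 1.82 β + 1.43."""
    return 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43


def optimal_rank(singular_values: np.ndarray, n_rows: int, n_cols: int) -> int:
    """Gavish–Donoho optimal singular-value hard threshold.

    Keeps singular values above τ = ω(β) · σ_median with
    β = min(n_rows, n_cols)/max(n_rows, n_cols). At least one singular
    value is always retained. Singular values below 1e-10 of the leading
    one are numerical zeros and never counted (the median-based rule
    degenerates on an exactly low-rank spectrum, where the "noise" bulk
    is rounding error).
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular spectrum")
    beta = min(n_rows, n_cols) / max(n_rows, n_cols)
    tau = max(gavish_donoho_omega(beta) * np.median(s), 1e-10 * s[0])
    return max(int(np.sum(s > tau)), 1)


def truncated_svd(pair: SnapshotPair, rank: Union[int, str] = "optimal") -> SVDFactors:
    """Economy SVD of X, truncated at ``rank`` (or the Gavish–Donoho
    optimum when ``rank='optimal'``)."""
    U, s, Vh = np.linalg.svd(pair.X, full_matrices=False)
    if rank == "optimal":
        r = optimal_rank(s, *pair.X.shape)
    else:
        r = int(rank)
        if r < 1 or r > pair.X.shape[1]:
            raise ValueError(f"rank must be in [1, {pair.X.shape[1]}]; got {r}")
    if s[r - 1] <= s[0] * np.finfo(float).eps * max(pair.X.shape):
        raise ValueError(
            f"singular value {r} is numerically zero; lower the rank below {r}"
        )
    return SVDFactors(U_r=U[:, :r], S_r=s[:r], V_r=Vh[:r].T, r=r, full_spectrum=s)


def rescale(lam: np.ndarray, dt: float) -> np.ndarray:
    """Continuous eigenvalues ω = log(λ)/Δt (principal branch).

    Im ω lies in (−π/Δt, π/Δt]; eigenvalues on the negative real axis are
    aliased oscillations at the Nyquist frequency and trigger a warning.
    """
    lam = np.asarray(lam, dtype=complex)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if np.any(lam == 0):
        raise ValueError("lambda = 0 (infinitely fast decay) cannot be rescaled; "
                         "it should have been removed by rank truncation")
    if np.any((lam.real < 0) & (np.abs(lam.imag) < 1e-12 * np.abs(lam.real))):
        warnings.warn("negative real eigenvalue: dynamics alias to the Nyquist "
                      "frequency; the rescaled rate is ambiguous")
    return np.log(lam) / dt


def fit(stack: ImageStack, rank: Union[int, str] = "optimal", *,
        exact_modes: bool = True) -> DMDModel:
    """Fit a DMD model to a stack.

    Parameters
    ----------
    stack
        Input stack with at least 3 frames.
    rank
        Truncation rank, or ``'optimal'`` for the Gavish–Donoho threshold.
    exact_modes
        If True (default) use exact-DMD modes Φ = X' V S⁻¹ W; otherwise
        projected modes Φ = U W. Eigenvalues are identical either way.
    """
    if not np.any(stack.data):
        raise ValueError("all-zero stack has no dynamics to decompose")
    pair = stack_to_snapshots(stack)
    svd = truncated_svd(pair, rank)

    XVSinv = pair.X_prime @ (svd.V_r / svd.S_r)  # X' V S^{-1}
    A_tilde = svd.U_r.conj().T @ XVSinv
    lam, W = np.linalg.eig(A_tilde)
    Phi = (XVSinv @ W) if exact_modes else (svd.U_r @ W)

    b, *_ = np.linalg.lstsq(Phi, pair.X[:, 0].astype(complex), rcond=None)
    omega = rescale(lam, pair.dt)

    order = np.argsort(np.abs(omega), kind="stable")
    return DMDModel(
        Phi=Phi[:, order],
        lam=lam[order],
        omega=omega[order],
        b=b[order],
        dt=pair.dt,
        image_shape=pair.image_shape,
        r=svd.r,
        singular_values=svd.full_spectrum,
        n_input_frames=stack.n_frames,
    )


def reconstruct(model: DMDModel, frames: Union[Sequence[int], str] = "all",
                n_frames: int | None = None) -> ImageStack:
    """Reconstruct frames as Re Σ_j φ_j λ_j^n b_j (n = 0 at the first frame).

    ``frames`` is a list of frame indices or ``'all'`` (the fitted window;
    override its length with ``n_frames``).
    """
    if isinstance(frames, str):
        if frames != "all":
            raise ValueError("frames must be an index sequence or 'all'")
        if n_frames is None:
            n_frames = model.n_input_frames
        if n_frames is None:
            raise ValueError("n_frames is required with frames='all' for a "
                             "model without a recorded input length")
        idx = np.arange(n_frames)
    else:
        idx = np.asarray(frames, dtype=int)
    # Vandermonde in the discrete eigenvalues: time dynamics per mode
    dynamics = model.lam[:, None] ** idx[None, :] * model.b[:, None]
    frames_flat = (model.Phi @ dynamics).T.real
    h, w = model.image_shape
    return ImageStack(frames_flat.reshape(-1, h, w), model.dt)


def reconstruct_continuous(model: DMDModel, times: np.ndarray) -> ImageStack:
    """Continuous-time reconstruction Re Σ_j φ_j e^{ω_j t} b_j at arbitrary
    times (seconds); agrees with :func:`reconstruct` at t = n·dt."""
    times = np.asarray(times, dtype=float)
    dynamics = np.exp(np.outer(model.omega, times)) * model.b[:, None]
    frames_flat = (model.Phi @ dynamics).T.real
    h, w = model.image_shape
    return ImageStack(frames_flat.reshape(-1, h, w), model.dt)


def predict(model: DMDModel, n_future: int, *, n_fitted: int | None = None) -> ImageStack:
    """Extrapolate ``n_future`` frames beyond the fitted window of
    ``n_fitted`` frames (frame indices n_fitted … n_fitted+n_future−1)."""
    if n_future < 1:
        raise ValueError("n_future must be >= 1")
    if n_fitted is None:
        n_fitted = model.n_input_frames
    if n_fitted is None:
        raise ValueError("n_fitted is required for a model without a recorded input length")
    if np.any(np.abs(model.lam) > 1 + 1e-6):
        warnings.warn("model contains a growing mode (|lambda| > 1); "
                      "extrapolation is unreliable")
    return reconstruct(model, frames=np.arange(n_fitted, n_fitted + n_future))


# ---------------------------------------------------------------------------
# model archive: directory of .npy arrays + JSON metadata

def save_model(model: DMDModel, path: Union[str, Path]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "Phi_real.npy", model.Phi.real)
    np.save(path / "Phi_imag.npy", model.Phi.imag)
    np.save(path / "lam.npy", model.lam)
    np.save(path / "omega.npy", model.omega)
    np.save(path / "b.npy", model.b)
    if model.singular_values is not None:
        np.save(path / "singular_values.npy", model.singular_values)
    meta = {
        "dt": model.dt,
        "image_shape": list(model.image_shape),
        "rank": model.r,
        "n_input_frames": model.n_input_frames,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path: Union[str, Path]) -> DMDModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    Phi = np.load(path / "Phi_real.npy") + 1j * np.load(path / "Phi_imag.npy")
    sv_file = path / "singular_values.npy"
    return DMDModel(
        Phi=Phi,
        lam=np.load(path / "lam.npy"),
        omega=np.load(path / "omega.npy"),
        b=np.load(path / "b.npy"),
        dt=meta["dt"],
        image_shape=tuple(meta["image_shape"]),
        r=meta["rank"],
        singular_values=np.load(sv_file) if sv_file.exists() else None,
        n_input_frames=meta.get("n_input_frames"),
    )


def eigenvalue_table(model: DMDModel):
    """DataFrame of (mode_index, Re ω, Im ω, |λ|, Re b, Im b) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mode_index": np.arange(model.r),
            "re_omega": model.omega.real,
            "im_omega": model.omega.imag,
            "abs_lambda": np.abs(model.lam),
            "re_b": model.b.real,
            "im_b": model.b.imag,
        }
    )
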