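"""Interpretation of a fitted DMD model.

Turns the abstract factorization into the objects a microscopist looks
at: 2-D maps of each spatial mode, the per-mode temporal decay b_j λ_j^n,
eigenvalues on the unit circle, per-mode reconstruction stacks, and an
automatic association of modes with labelled image regions (nucleus,
cytoplasm, aggregates, neighbor cell, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmd import DMDModel
from .stack import ImageStack

log = logging.getLogger(__name__)

# A region is called "immobile/stable" when its mode decays slower than
# this rate (s^-1, magnitude); faster regions are "exchanging".
STABLE_RATE_THRESHOLD = 1e-4


def mode_map(model: DMDModel, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary images of mode j (reshaped to the stack frame)."""
    if not (0 <= j < model.r):
        raise IndexError(f"mode index {j} out of range [0, {model.r})")
    phi = model.Phi[:, j].reshape(model.image_shape)
    return phi.real.copy(), phi.imag.copy()


def mode_dynamics(model: DMDModel, j: int, n_frames: int) -> np.ndarray:
    """Complex temporal coefficient series b_j λ_j^n, n = 0 … n_frames−1."""
    if not (0 <= j < model.r):
        raise IndexError(f"mode index {j} out of range [0, {model.r})")
    return model.b[j] * model.lam[j] ** np.arange(n_frames)


def eigenvalue_circle(model: DMDModel) -> pd.DataFrame:
    """Unit-circle table: one row per mode with Re λ, Im λ, |λ| and a
    ``decaying`` flag (|λ| ≤ 1 + 1e−6)."""
    lam = model.lam
    return pd.DataFrame(
        {
            "mode_index": np.arange(model.r),
            "re_lambda": lam.real,
            "im_lambda": lam.imag,
            "abs_lambda": np.abs(lam),
            "decaying": np.abs(lam) <= 1 + 1e-6,
        }
    )


def mode_stack(model: DMDModel, j, n_frames: int) -> ImageStack:
    """Per-mode reconstruction Re(φ_j λ_j^n b_j) as a stack.

    ``j`` may be an index or a list of indices (their contributions are
    summed); summing over all modes reproduces the full reconstruction
    exactly, by linearity.
    """
    idx = np.atleast_1d(np.asarray(j, dtype=int))
    if np.any((idx < 0) | (idx >= model.r)):
        raise IndexError(f"mode index out of range [0, {model.r})")
    n = np.arange(n_frames)
    dynamics = model.lam[idx, None] ** n[None, :] * model.b[idx, None]
    frames = (model.Phi[:, idx] @ dynamics).T.real
    h, w = model.image_shape
    return ImageStack(frames.reshape(-1, h, w), model.dt)


@dataclass
class ModeReport:
    """Per-mode summary: eigenvalues, amplitude, maps, and the fraction of
    mode mass falling in each named region."""

    mode_index: int
    omega: complex
    lam: complex
    amplitude: complex
    map_real: np.ndarray
    map_imag: np.ndarray
    energy_by_region: dict[str, float] = field(default_factory=dict)
    label: str = ""
    mobility_class: str = ""

    def to_row(self) -> dict:
        row = {
            "mode_index": self.mode_index,
            "re_omega": self.omega.real,
            "im_omega": self.omega.imag,
            "abs_lambda": abs(self.lam),
            "label": self.label,
            "mobility_class": self.mobility_class,
        }
        row.update({f"frac_{k}": v for k, v in self.energy_by_region.items()})
        return row


def assign_modes_to_regions(
    model: DMDModel,
    region_masks: dict[str, np.ndarray],
    *,
    metric: str = "abs_real",
) -> list[ModeReport]:
    """Associate each mode with the region holding most of its mass.

    For every mode the fraction of Σ|Re φ| (or Σ|φ| with
    ``metric='abs'``) inside each region mask is computed; the mode's
    label is the argmax region. The |Re φ| default makes the assignment
    insensitive to the sign structure of the maps. Ties are broken toward
    the region listed first, with a logged warning. A mode's mobility
    class is "immobile/stable" when |Re ω| ≤ 1e−4 s⁻¹, else "exchanging".
    """
    if metric not in ("abs_real", "abs"):
        raise ValueError("metric must be 'abs_real' or 'abs'")
    h, w = model.image_shape
    for name, mask in region_masks.items():
        if mask.shape != (h, w):
            raise ValueError(f"mask {name!r} shape {mask.shape} != image shape {(h, w)}")
        if not np.any(mask):
            raise ValueError(f"region mask {name!r} is empty")

    reports = []
    names = list(region_masks)
    for j in range(model.r):
        phi_img = model.Phi[:, j].reshape(h, w)
        weight = np.abs(phi_img.real) if metric == "abs_real" else np.abs(phi_img)
        total = weight.sum()
        fracs = {
            name: float(weight[region_masks[name]].sum() / total) if total > 0 else 0.0
            for name in names
        }
        vals = np.array([fracs[n] for n in names])
        best = int(np.argmax(vals))
        if np.sum(np.isclose(vals, vals[best], rtol=0, atol=1e-12)) > 1:
            log.warning("mode %d: tie between regions; keeping %r", j, names[best])
        rate = abs(model.omega[j].real)
        reports.append(
            ModeReport(
                mode_index=j,
                omega=complex(model.omega[j]),
                lam=complex(model.lam[j]),
                amplitude=complex(model.b[j]),
                map_real=phi_img.real.copy(),
                map_imag=phi_img.imag.copy(),
                energy_by_region=fracs,
                label=names[best],
                mobility_class="immobile/stable" if rate <= STABLE_RATE_THRESHOLD else "exchanging",
            )
        )
    return reports


def reports_to_frame(reports: list[ModeReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
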