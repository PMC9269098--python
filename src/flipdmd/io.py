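"""TIFF stack I/O, sidecar configuration, and run reproducibility records.

Stacks travel as multi-page TIFF (one page per frame, time order = page
order, float32 preferred; unsigned-integer input is converted to float
without rescaling). The frame interval dt is never read from TIFF tags —
microscope exporters are too inconsistent — and must come from a flag or
a sidecar JSON (``<stack>.json`` with a ``dt`` key). Every CLI run writes
its fully resolved configuration next to its outputs, so any artifact on
disk can be regenerated from the sidecar alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import tifffile

from .stack import ImageStack


@dataclass
class RunConfig:
    """Flat, serializable record of one CLI invocation."""

    command: str
    params: dict[str, Any] = field(default_factory=dict)
    package_version: str = ""

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def sidecar_path(stack_path: Union[str, Path]) -> Path:
    return Path(stack_path).with_suffix(Path(stack_path).suffix + ".json")


def read_stack(path: Union[str, Path], dt: Optional[float] = None) -> ImageStack:
    """Read a single-channel multi-page TIFF as an ImageStack.

    ``dt`` (seconds per frame) must be supplied either directly or through
    a ``<stack>.tif.json`` sidecar with a ``dt`` entry.
    """
    path = Path(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] > 8 * data.shape[-1]):
        raise ValueError(
            f"{path.name}: multi-channel/RGB input is not supported; "
            "select a single channel and re-export as grayscale TIFF"
        )
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D (frames, h, w) stack; got shape {data.shape}")
    if dt is None:
        sc = sidecar_path(path)
        if sc.exists():
            dt = json.loads(sc.read_text()).get("dt")
    if dt is None:
        raise ValueError(
            f"{path.name}: frame interval dt not supplied; pass dt= or provide a "
            f"sidecar {sidecar_path(path).name} with a 'dt' key (TIFF metadata is not trusted)"
        )
    return ImageStack(data.astype(float), float(dt))


def write_stack(stack: ImageStack, path: Union[str, Path], *, write_sidecar: bool = True) -> None:
    """Write a stack as float32 multi-page TIFF plus a dt sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    if write_sidecar:
        sidecar_path(path).write_text(json.dumps({"dt": stack.dt}))
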