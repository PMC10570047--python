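"""Synthetic TIRF movie rendering: diffraction-limited spots on a noisy
camera background.

Each molecule is a 2-D Gaussian point-spread function scaled per frame by
its trace intensity; the camera adds Poisson shot noise on the expected
counts plus Gaussian read noise.  Spot positions are laid down on a jittered
grid with a minimum separation and written to a ground-truth sidecar table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import OpticsParams
from .photophysics import CHANNELS, Trace

__all__ = ["FieldGeometry", "render_movie"]


@dataclass
class FieldGeometry:
    """Imaging field for synthetic stacks."""

    shape: tuple[int, int] = (128, 128)  # (ny, nx) pixels
    psf_sigma: float = 1.2               # PSF width, px
    min_sep: float = 6.0                 # minimum spot separation, px
    margin: int = 6                      # keep-out border, px
    read_noise_sd: float = 2.0           # Gaussian camera noise, counts
    camera_background: float = 5.0       # counts/pixel/frame
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")


def _place_spots(
    n: int, field: FieldGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping spot centres via a jittered grid."""
    ny, nx = field.shape
    usable_y = ny - 2 * field.margin
    usable_x = nx - 2 * field.margin
    pitch = field.min_sep + 1.0
    rows = int(usable_y // pitch)
    cols = int(usable_x // pitch)
    if rows * cols < n:
        raise ValueError(
            f"field {field.shape} too small for {n} molecules at "
            f"min_sep {field.min_sep}"
        )
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    idx = rng.choice(len(cells), size=n, replace=False)
    jitter_max = max((pitch - field.min_sep) / 2.0, 0.0)
    out = np.empty((n, 2))
    for k, ci in enumerate(idx):
        r, c = cells[ci]
        y = field.margin + (r + 0.5) * pitch
        x = field.margin + (c + 0.5) * pitch
        out[k] = (
            y + rng.uniform(-jitter_max, jitter_max),
            x + rng.uniform(-jitter_max, jitter_max),
        )
    return out


def render_movie(
    traces: list[Trace],
    optics: OpticsParams,
    field: FieldGeometry,
    seed: int,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render traces into per-channel image stacks.

    Returns ``(stacks, spots)``: ``stacks`` maps channel name to a
    (n_frames, ny, nx) float32 array; ``spots`` is the ground-truth sidecar
    with columns molecule_id, y, x.  Trace background is removed before
    painting (the camera adds its own), so integrated spot intensity
    matches the background-subtracted trace value.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n_frames = traces[0].n_frames
    if any(tr.n_frames != n_frames for tr in traces):
        raise ValueError("all traces must share one time axis")
    rng = np.random.default_rng(seed)
    centres = _place_spots(len(traces), field, rng)
    spots = pd.DataFrame(
        {
            "molecule_id": [tr.molecule_id for tr in traces],
            "y": centres[:, 0],
            "x": centres[:, 1],
        }
    )
    ny, nx = field.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    stacks: dict[str, np.ndarray] = {}
    # precompute normalized PSFs per molecule (truncated at 4 sigma)
    psfs = []
    for cy, cx in centres:
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        psf = np.exp(-r2 / (2.0 * field.psf_sigma**2))
        psf /= 2.0 * np.pi * field.psf_sigma**2
        psf[r2 > (4.0 * field.psf_sigma) ** 2] = 0.0
        psfs.append(psf.astype(np.float32))
    for ch in CHANNELS:
        expected = np.full(
            (n_frames, ny, nx), field.camera_background, dtype=np.float32
        )
        for tr, psf in zip(traces, psfs):
            amp = np.clip(tr.channel(ch) - optics.background, 0.0, None)
            expected += amp[:, None, None].astype(np.float32) * psf[None, :, :]
        if field.shot_noise:
            img = rng.poisson(expected).astype(np.float32)
        else:
            img = expected.copy()
        if field.read_noise_sd > 0:
            img += rng.normal(0.0, field.read_noise_sd, img.shape).astype(
                np.float32
            )
        stacks[ch] = img
    return stacks, spots
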