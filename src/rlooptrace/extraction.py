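"""Front-end image analysis: spot detection, channel registration and
aperture photometry, turning TIRF stacks into per-molecule traces.

Molecules are surface-immobilized, so detection runs on the temporal
average of the first few frames; extraction is a fixed-aperture sum with
an annulus-median background per frame.  All thresholds are declared
defaults, exposed in the function signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import OpticsParams
from .photophysics import CHANNELS, Trace

__all__ = [
    "SpotSet",
    "detect_spots",
    "register_channels",
    "extract_trace",
    "traces_from_movie",
]


@dataclass
class SpotSet:
    """Detected spots in one image: (y, x, peak) per spot, brightest first."""

    spots: np.ndarray  # (n, 3): y, x, peak counts
    shape: tuple[int, int]
    channel: str | None = None

    def __post_init__(self) -> None:
        self.spots = np.asarray(self.spots, dtype=float).reshape(-1, 3)
        ny, nx = self.shape
        if self.spots.size and (
            self.spots[:, 0].min() < 0
            or self.spots[:, 0].max() >= ny
            or self.spots[:, 1].min() < 0
            or self.spots[:, 1].max() >= nx
        ):
            raise ValueError("spot coordinates outside image bounds")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def xy(self) -> np.ndarray:
        return self.spots[:, :2]


def detect_spots(
    image: np.ndarray,
    min_sep: float = 5.0,
    threshold_sigma: float = 5.0,
    channel: str | None = None,
) -> SpotSet:
    """Local maxima above background + threshold_sigma * robust SD.

    The robust SD is 1.4826 * MAD about the median.  Maxima closer than
    ``min_sep`` are non-maximum-suppressed (brightest wins); output is
    ordered by descending peak then raster order, deterministically.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    sd = 1.4826 * mad
    if sd == 0:
        sd = max(img.std(), 1e-12)
    thresh = med + threshold_sigma * sd
    size = max(int(round(min_sep)) | 1, 3)
    local_max = img == ndimage.maximum_filter(img, size=size, mode="nearest")
    cand = np.argwhere(local_max & (img > thresh))
    if len(cand) == 0:
        return SpotSet(np.empty((0, 3)), img.shape, channel)
    peaks = img[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -peaks))
    cand, peaks = cand[order], peaks[order]
    kept: list[int] = []
    for i in range(len(cand)):
        ok = True
        for j in kept:
            if np.hypot(*(cand[i] - cand[j])) < min_sep:
                ok = False
                break
        if ok:
            kept.append(i)
    spots = np.column_stack([cand[kept].astype(float), peaks[kept]])
    return SpotSet(spots, img.shape, channel)


def register_channels(
    a: SpotSet, b: SpotSet, tol: float = 2.0
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching of two spot sets under ``tol`` px.

    Pairs are formed in order of increasing distance; ties break toward
    the lower spot index.  Returns (index_in_a, index_in_b) pairs.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    da = a.xy[:, None, :] - b.xy[None, :, :]
    dist = np.hypot(da[..., 0], da[..., 1])
    pairs = [
        (dist[i, j], i, j)
        for i in range(len(a))
        for j in range(len(b))
        if dist[i, j] <= tol
    ]
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        out.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return out


def _disk_masks(shape, cy, cx, aperture, annulus):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.hypot(yy - cy, xx - cx)
    return r <= aperture, (r > annulus[0]) & (r <= annulus[1])


def extract_trace(
    stack: np.ndarray,
    spot: tuple[float, float],
    aperture: float = 3.0,
    annulus: tuple[float, float] = (5.0, 7.0),
) -> np.ndarray:
    """Background-subtracted aperture photometry of one spot per frame.

    Background per frame is the annulus median scaled by the aperture
    area.  Raises if the aperture is clipped by the image edge.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, ny, nx)")
    cy, cx = spot
    ny, nx = stack.shape[1:]
    if (
        cy - aperture < -0.5
        or cx - aperture < -0.5
        or cy + aperture > ny - 0.5
        or cx + aperture > nx - 0.5
    ):
        raise ValueError("aperture clipped by image edge")
    ap, ann = _disk_masks((ny, nx), cy, cx, aperture, annulus)
    n_ap = int(ap.sum())
    signal = stack[:, ap].sum(axis=1)
    bg = np.median(stack[:, ann], axis=1) * n_ap
    return signal - bg


def traces_from_movie(
    stacks: dict[str, np.ndarray],
    optics: OpticsParams,
    detect_channel: str = "acceptor_em_red_ex",
    n_avg_frames: int = 10,
    min_sep: float = 5.0,
    threshold_sigma: float = 5.0,
    aperture: float = 3.0,
    annulus: tuple[float, float] = (5.0, 7.0),
    t: np.ndarray | None = None,
) -> list[Trace]:
    """Detect molecules in one channel and extract all four channels.

    Detection uses the temporal average of the first ``n_avg_frames``
    frames of ``detect_channel`` (every immobilized molecule carries Cy5,
    making the red-excitation channel the natural reference).  The
    extracted intensities are re-offset by the trace background so the
    output is directly comparable with directly rendered traces.
    """
    ref = stacks[detect_channel]
    avg = ref[: min(n_avg_frames, len(ref))].mean(axis=0)
    spots = detect_spots(avg, min_sep=min_sep, threshold_sigma=threshold_sigma)
    n_frames = len(ref)
    if t is None:
        t = np.arange(n_frames) * optics.frame_dt
    out = []
    for k in range(len(spots)):
        cy, cx = spots.spots[k, 0], spots.spots[k, 1]
        channels = {}
        for ch in CHANNELS:
            sig = extract_trace(stacks[ch], (cy, cx), aperture, annulus)
            channels[ch] = sig + optics.background
        out.append(
            Trace(
                molecule_id=k,
                frame_dt=optics.frame_dt,
                t=np.asarray(t, dtype=float),
                channels=channels,
                provenance={"source": "movie", "y": float(cy), "x": float(cx)},
            )
        )
    return out
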