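"""Static versus diffuse classification of fluorescent protein in cells.

Freely diffusing molecules traverse a bacterium far faster than the frame
exposure, so their fluorescence blurs into a homogeneous cell body, whereas
genome-bound molecules appear as discrete spots that persist for the whole
movie.  A cell is called *static* when spot detection plus frame-to-frame
linking finds at least one track that persists through >= 90% of the movie
with a positional scatter of <= 2 px; otherwise it is *diffuse*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk, erosion
from skimage.segmentation import clear_border

from .detection import MovieStack, detect_spots

__all__ = [
    "CellObservation",
    "segment_cells",
    "classify_cell_static",
    "classify_cells",
    "static_fraction",
    "STATIC",
    "DIFFUSE",
]

STATIC = "static"
DIFFUSE = "diffuse"


@dataclass
class CellObservation:
    cell_id: int
    condition: str
    dose_J_m2: float
    n_static_spots: int
    classification: str
    experiment_id: int = 0

    def __post_init__(self) -> None:
        if self.dose_J_m2 < 0:
            raise ValueError("dose_J_m2 must be >= 0")
        expected = STATIC if self.n_static_spots >= 1 else DIFFUSE
        if self.classification != expected:
            raise ValueError("classification inconsistent with n_static_spots")


def segment_cells(image: np.ndarray, min_area: int = 50, max_area: int = 2000,
                  exclude_border: bool = True) -> list[np.ndarray]:
    """Otsu threshold + connected components + area filter -> boolean masks.

    Cells touching the image border are excluded by default since truncated
    masks bias spot detection.  Returns a (possibly empty) list of full-size
    boolean masks.
    """
    image = np.asarray(image, dtype=float)
    if image.max() <= image.min():
        return []
    mask = image > threshold_otsu(image)
    mask = ndimage.binary_fill_holes(mask)
    if exclude_border:
        mask = clear_border(mask)
    labelled = sk_label(mask)
    masks = []
    for lab in range(1, labelled.max() + 1):
        m = labelled == lab
        area = int(m.sum())
        if min_area <= area <= max_area:
            masks.append(m)
    return masks


def _link_2d(spots_by_frame, max_jump: float = 3.0, max_gap: int = 2):
    """Greedy nearest-neighbour linking of (x, y) detections over frames."""
    active: list[dict] = []
    finished: list[dict] = []
    for f, spots in enumerate(spots_by_frame):
        still = []
        for tr in active:
            (finished if f - tr["last"] > max_gap + 1 else still).append(tr)
        active = still
        cands = []
        for ti, tr in enumerate(active):
            for si, (x, y, inten) in enumerate(spots):
                d = np.hypot(x - tr["xy"][-1][0], y - tr["xy"][-1][1])
                if d <= max_jump:
                    cands.append((d, -inten, ti, si))
        cands.sort()
        used_t: set[int] = set()
        used_s: set[int] = set()
        for _d, _ni, ti, si in cands:
            if ti in used_t or si in used_s:
                continue
            x, y, inten = spots[si]
            active[ti]["xy"].append((x, y))
            active[ti]["frames"].append(f)
            active[ti]["last"] = f
            used_t.add(ti)
            used_s.add(si)
        for si, (x, y, inten) in enumerate(spots):
            if si not in used_s:
                active.append({"xy": [(x, y)], "frames": [f], "last": f})
    finished.extend(active)
    return finished


def _count_static_tracks(spots_by_frame, n_frames: int, persistence: float,
                         max_jump: float, max_gap: int, sd_max_px: float) -> int:
    tracks = _link_2d(spots_by_frame, max_jump=max_jump, max_gap=max_gap)
    n_static = 0
    for tr in tracks:
        if len(tr["frames"]) < persistence * n_frames:
            continue
        xy = np.array(tr["xy"])
        sd = float(np.sqrt(xy[:, 0].var() + xy[:, 1].var()))
        if sd <= sd_max_px:
            n_static += 1
    return n_static


def _inner_mask(mask: np.ndarray) -> np.ndarray:
    # edge intensity ridges of the cell body masquerade as spots; only
    # detections well inside the cell count
    inner = erosion(mask, disk(2))
    return inner if np.any(inner) else mask


def classify_cell_static(movie: MovieStack, mask: np.ndarray, channel: str,
                         cell_id: int = 0, condition: str = "",
                         dose_J_m2: float = 0.0, experiment_id: int = 0,
                         persistence: float = 0.9, snr_threshold: float = 5.0,
                         psf_sigma: float = 1.3, max_jump: float = 3.0,
                         max_gap: int = 2, sd_max_px: float = 2.0
                         ) -> CellObservation:
    """Classify one cell as static or diffuse from per-frame spot tracking.

    Spots are detected per frame within the cell's bounding box (plus a
    margin) and kept when their centre falls inside the mask eroded by
    ~2 px.  A cell is static iff at least one linked track covers
    >= ``persistence`` of the movie's frames with 2D positional SD
    <= ``sd_max_px``.
    """
    if not np.any(mask):
        raise ValueError("mask is empty")
    stack = movie.channels[channel]
    n_frames = stack.shape[0]
    inner = _inner_mask(mask)
    rows, cols = np.nonzero(mask)
    pad = int(np.ceil(6 * psf_sigma))
    r0, r1 = max(0, rows.min() - pad), min(mask.shape[0], rows.max() + pad + 1)
    c0, c1 = max(0, cols.min() - pad), min(mask.shape[1], cols.max() + pad + 1)
    spots_by_frame = []
    for f in range(n_frames):
        frame_spots = []
        for s in detect_spots(stack[f, r0:r1, c0:c1], psf_sigma=psf_sigma,
                              snr_threshold=snr_threshold):
            x, y = s.x + c0, s.y + r0
            r, c = int(round(y)), int(round(x))
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and inner[r, c]:
                frame_spots.append((x, y, s.intensity))
        spots_by_frame.append(frame_spots)
    n_static = _count_static_tracks(spots_by_frame, n_frames, persistence,
                                    max_jump, max_gap, sd_max_px)
    cls = STATIC if n_static >= 1 else DIFFUSE
    return CellObservation(cell_id=cell_id, condition=condition,
                           dose_J_m2=dose_J_m2, n_static_spots=n_static,
                           classification=cls, experiment_id=experiment_id)


def classify_cells(movie: MovieStack, masks: list[np.ndarray], channel: str,
                   condition: str = "", dose_J_m2: float = 0.0,
                   experiment_id: int = 0, persistence: float = 0.9,
                   snr_threshold: float = 5.0, psf_sigma: float = 1.3,
                   max_jump: float = 3.0, max_gap: int = 2,
                   sd_max_px: float = 2.0) -> list[CellObservation]:
    """Classify every cell in a field at once.

    Detection runs once per frame on the full field; detections are then
    assigned to cells and linked per cell, which is far cheaper than
    re-detecting per cell.  Classification is identical to
    :func:`classify_cell_static`.
    """
    if not masks:
        return []
    stack = movie.channels[channel]
    n_frames = stack.shape[0]
    cell_label = np.zeros(masks[0].shape, dtype=int)
    for i, m in enumerate(masks):
        cell_label[_inner_mask(m)] = i + 1
    per_cell: list[list[list[tuple]]] = [[[] for _ in range(n_frames)]
                                         for _ in masks]
    for f in range(n_frames):
        for s in detect_spots(stack[f], psf_sigma=psf_sigma,
                              snr_threshold=snr_threshold):
            r, c = int(round(s.y)), int(round(s.x))
            if 0 <= r < cell_label.shape[0] and 0 <= c < cell_label.shape[1]:
                lab = cell_label[r, c]
                if lab > 0:
                    per_cell[lab - 1][f].append((s.x, s.y, s.intensity))
    out = []
    for i in range(len(masks)):
        n_static = _count_static_tracks(per_cell[i], n_frames, persistence,
                                        max_jump, max_gap, sd_max_px)
        cls = STATIC if n_static >= 1 else DIFFUSE
        out.append(CellObservation(cell_id=i, condition=condition,
                                   dose_J_m2=dose_J_m2,
                                   n_static_spots=n_static, classification=cls,
                                   experiment_id=experiment_id))
    return out


def static_fraction(cells: list[CellObservation]):
    """Percent of static cells per (condition, dose), SEM over experiments.

    Returns a DataFrame with columns condition, dose_J_m2, n_cells,
    n_static, fraction_pct, sem_pct, n_experiments; sem_pct is NaN when a
    condition has a single experiment.
    """
    import pandas as pd

    if not cells:
        raise ValueError("no cells")
    rows = []
    groups: dict[tuple, list[CellObservation]] = {}
    for c in cells:
        groups.setdefault((c.condition, c.dose_J_m2), []).append(c)
    for (cond, dose), obs in sorted(groups.items()):
        n = len(obs)
        n_static = sum(1 for o in obs if o.classification == STATIC)
        exps: dict[int, list[CellObservation]] = {}
        for o in obs:
            exps.setdefault(o.experiment_id, []).append(o)
        sem = float("nan")
        if len(exps) > 1:
            per_exp = [100.0 * sum(1 for o in v if o.classification == STATIC) / len(v)
                       for v in exps.values()]
            sem = float(np.std(per_exp, ddof=1) / np.sqrt(len(per_exp)))
        rows.append({"condition": cond, "dose_J_m2": dose, "n_cells": n,
                     "n_static": n_static, "fraction_pct": 100.0 * n_static / n,
                     "sem_pct": sem, "n_experiments": len(exps)})
    return pd.DataFrame(rows)
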