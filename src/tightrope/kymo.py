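"""Kymographs, 1D track linking, and static/motile classification.

A kymograph resamples each frame along the tightrope axis, integrating
intensity over a narrow band perpendicular to it, yielding position-versus-
time images in which static molecules appear as vertical stripes and
diffusing molecules as wandering traces.  Tracks are built by greedy
nearest-neighbour linking of per-frame localizations projected onto the
axis; a molecule is called motile when its positional scatter exceeds what
localization noise alone can produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .detection import MovieStack, TightropeGeometry

__all__ = [
    "Kymograph",
    "Track1D",
    "DiffusionEstimate",
    "build_kymograph",
    "link_tracks",
    "classify_motility",
    "estimate_diffusion_constant",
    "STATIC",
    "MOTILE",
    "UNCLASSIFIED",
]

STATIC = "static"
MOTILE = "motile"
UNCLASSIFIED = "unclassified"


@dataclass
class Kymograph:
    values: np.ndarray  # (n_axial_bins, n_frames)
    channel: str
    bin_size_px: float = 1.0
    pixel_size_nm: float = 100.0

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Track1D:
    """A linked 1D trajectory along the tightrope axis."""

    molecule_id: int
    frames: list[int]
    s: np.ndarray            # axial position per listed frame (caller's units)
    intensity: np.ndarray = field(default_factory=lambda: np.array([]))
    channel: str = ""
    localization_precision: float = 0.3

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if len(self.frames) != len(self.s):
            raise ValueError("frames and s must have equal length")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DiffusionEstimate:
    d_um2_s: float
    se: float
    offset: float
    curvature_flag: bool  # True when MSD is markedly non-linear (e.g. drift)


def build_kymograph(movie: MovieStack, geometry: TightropeGeometry, channel: str,
                    half_width: int = 3) -> Kymograph:
    """Integrate intensity over a +-half_width band perpendicular to the
    tightrope axis, one axial-pixel bin at a time, for every frame."""
    stack = movie.channels[channel]
    h, w = stack.shape[1:]
    for ex, ey in geometry.endpoints:
        if not (0 <= ex <= w - 1 and 0 <= ey <= h - 1):
            raise ValueError("tightrope geometry lies outside the image")
    n_bins = int(np.floor(geometry.length_px)) + 1
    axis = geometry.axis
    normal = np.array([-axis[1], axis[0]])
    s_vals = np.arange(n_bins)
    offsets = np.arange(-half_width, half_width + 1)
    # sample coordinates: (n_bins, n_offsets, 2)
    pts = (geometry.endpoints[0][None, None, :]
           + s_vals[:, None, None] * axis[None, None, :]
           + offsets[None, :, None] * normal[None, None, :])
    rows = pts[..., 1].ravel()
    cols = pts[..., 0].ravel()
    values = np.empty((n_bins, stack.shape[0]))
    for f in range(stack.shape[0]):
        samples = ndimage.map_coordinates(stack[f], [rows, cols], order=1,
                                          mode="constant", cval=0.0)
        values[:, f] = samples.reshape(n_bins, offsets.size).sum(axis=1)
    return Kymograph(values=values, channel=channel,
                     pixel_size_nm=movie.pixel_size_nm)


def link_tracks(spots_by_frame, max_jump: float = 5.0, max_gap: int = 2,
                channel: str = "") -> list[Track1D]:
    """Greedy nearest-neighbour linking of per-frame axial localizations.

    ``spots_by_frame`` is a sequence over frames; each element is a sequence
    of ``(s, intensity)`` pairs (or bare positions).  Candidate links are
    taken in order of increasing distance, ties broken by brighter intensity;
    links longer than ``max_jump`` or across more than ``max_gap`` missing
    frames are forbidden, and unlinked spots seed new tracks.
    """
    active: list[dict] = []   # {frames, s, inten, last_frame}
    finished: list[dict] = []
    for f, spots in enumerate(spots_by_frame):
        parsed = []
        for sp in spots:
            if np.isscalar(sp):
                parsed.append((float(sp), 1.0))
            else:
                s, inten = sp
                parsed.append((float(s), float(inten)))
        # retire tracks that have gapped out
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        # candidate (distance, -intensity, track_idx, spot_idx), greedy smallest first
        cands = []
        for ti, tr in enumerate(active):
            for si, (s, inten) in enumerate(parsed):
                d = abs(s - tr["s"][-1])
                if d <= max_jump:
                    cands.append((d, -inten, ti, si))
        cands.sort()
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        for d, _ni, ti, si in cands:
            if ti in used_tracks or si in used_spots:
                continue
            tr = active[ti]
            s, inten = parsed[si]
            tr["frames"].append(f)
            tr["s"].append(s)
            tr["inten"].append(inten)
            tr["last_frame"] = f
            used_tracks.add(ti)
            used_spots.add(si)
        for si, (s, inten) in enumerate(parsed):
            if si not in used_spots:
                active.append({"frames": [f], "s": [s], "inten": [inten],
                               "last_frame": f})
    finished.extend(active)
    finished.sort(key=lambda tr: (tr["frames"][0], tr["s"][0]))
    return [Track1D(molecule_id=i, frames=tr["frames"], s=np.array(tr["s"]),
                    intensity=np.array(tr["inten"]), channel=channel)
            for i, tr in enumerate(finished)]


def classify_motility(track: Track1D, precision: float | None = None,
                      k: float = 3.0, min_length: int = 10) -> str:
    """Static/motile call from positional scatter.

    A track is motile when the standard deviation of its axial position
    exceeds ``k`` times the localization precision (same units as ``s``);
    tracks shorter than ``min_length`` frames are left unclassified.
    """
    if len(track) < min_length:
        return UNCLASSIFIED
    if precision is None:
        precision = track.localization_precision
    sd = float(np.std(track.s, ddof=1))
    return MOTILE if sd > k * precision else STATIC


def estimate_diffusion_constant(track: Track1D, frame_interval_s: float,
                                pixel_size_nm: float | None = None,
                                min_length: int = 20) -> DiffusionEstimate:
    """OLS fit of MSD(tau) = 2 D tau + offset over the first quarter of lags.

    ``track.s`` is taken in px when ``pixel_size_nm`` is given (converted to
    um), otherwise in um.  The constant offset absorbs localization noise.
    A quadratic refit flags tracks whose MSD curvature (directed drift)
    invalidates the linear model.
    """
    if len(track) < min_length:
        raise ValueError(f"track must have at least {min_length} points")
    s = track.s * (pixel_size_nm / 1000.0) if pixel_size_nm else track.s
    frames = np.asarray(track.frames)
    n = len(s)
    max_lag = max(2, n // 4)
    taus = np.arange(1, max_lag + 1)
    msd = np.empty(taus.size)
    for i, lag in enumerate(taus):
        # use frame-aware displacements so gaps do not corrupt lags
        d = []
        pos = dict(zip(frames, s))
        for f in frames:
            g = f + lag
            if g in pos:
                d.append(pos[g] - pos[f])
        if not d:
            msd[i] = np.nan
        else:
            msd[i] = float(np.mean(np.square(d)))
    ok = np.isfinite(msd)
    if ok.sum() < 2:
        raise ValueError("insufficient lags for MSD fit")
    t = taus[ok] * frame_interval_s
    y = msd[ok]
    res = stats.linregress(t, y)
    d_est = res.slope / 2.0
    se = res.stderr / 2.0 if res.stderr is not None else float("nan")
    # curvature diagnostic: does a quadratic term reduce residuals markedly?
    curvature = False
    if t.size >= 4:
        lin = np.polyval(np.polyfit(t, y, 1), t)
        quad = np.polyval(np.polyfit(t, y, 2), t)
        ss_lin = float(np.sum((y - lin) ** 2))
        ss_quad = float(np.sum((y - quad) ** 2))
        if ss_lin > 0 and (ss_lin - ss_quad) / ss_lin > 0.9:
            curvature = True
    return DiffusionEstimate(d_um2_s=float(d_est), se=float(se),
                             offset=float(res.intercept), curvature_flag=curvature)
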