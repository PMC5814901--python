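"""Synthetic movie and count-table generators with known ground truth.

This module emulates the three experimental data types of the assay:

* **Tightrope movies** — a taut 48.5 kbp / 16 um lambda-DNA molecule rendered
  as a straight line, decorated with quantum-dot labelled protein complexes.
  Each labelled protein is an isotropic 2D Gaussian point emitter in its
  emission channel; molecules are static or diffuse in 1D along the axis
  (reflected Brownian motion); a configurable fraction of dots is
  permanently dark; an optional damage-marker dot sits at a defined genomic
  coordinate.
* **Live-cell movies** — rod-shaped (elliptical) bacteria whose fluorescent
  protein is either fast-diffusing (motion-blurred into a homogeneous cell
  body) or genome-bound (a persistent immobile spot).
* **Survival count tables** — Poisson colony counts at serial dilutions
  under dose-dependent survival fractions.

All randomness flows from a single ``numpy.random.Generator`` seeded per
call, so identical ``(config, seed)`` reproduce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .detection import MovieStack, TightropeGeometry
from .survival import SurvivalRecord

__all__ = [
    "Species",
    "SimulationConfig",
    "MoleculeTruth",
    "CellTruth",
    "GroundTruth",
    "generate_tightrope_movie",
    "generate_livecell_movie",
    "expected_observed_composition",
    "generate_survival_counts",
    "reflected_brownian",
    "render_gaussian",
]

DEFAULT_CHANNEL_MAP = {"A": "565", "B": "605", "C": "655"}


@dataclass
class Species:
    """One simulated molecular species bound to the tightrope.

    ``composition`` lists the proteins in the complex (subset of A/B/C);
    each member carries one quantum dot in the channel the config's
    ``channel_map`` assigns to it, independently dark with probability
    ``dark_fraction`` (fixed per dot for the whole movie — non-fluorescent
    dots are permanently dark).
    """

    composition: tuple[str, ...]
    count: int = 1
    diffusion_constant_um2_s: float = 0.0
    dark_fraction: float = 0.0
    damage_bound_fraction: float = 0.0
    amplitude: float = 1000.0


@dataclass
class SimulationConfig:
    """Imaging and sample parameters shared by the movie generators.

    Defaults reflect the assay conditions: 10 fps acquisition, 16 um
    (48.5 kbp) tightropes, 100 nm pixels and a 1.3 px PSF sigma.
    """

    pixel_size_nm: float = 100.0
    frame_rate_hz: float = 10.0
    n_frames: int = 50
    psf_sigma_px: float = 1.3
    tightrope_length_kbp: float = 48.5
    tightrope_length_um: float = 16.0
    species: list[Species] = field(default_factory=list)
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    damage_positions_kbp: list[float] = field(default_factory=list)
    damage_marker_channel: str = "565"
    damage_marker_amplitude: float = 1000.0
    background_mean: float = 100.0
    read_noise_sigma: float = 2.0
    shot_noise: bool = True
    angle_deg: float = 0.0
    margin_px: int = 10
    min_separation_um: float = 0.0
    # optional two-state blinking telegraph (off by default; frame stacking
    # defeats blinking in the analysis, so it is rarely needed)
    blink_on_rate_hz: float | None = None
    blink_off_rate_hz: float | None = None

    def validate(self) -> None:
        for name in ("pixel_size_nm", "frame_rate_hz", "n_frames", "psf_sigma_px",
                     "tightrope_length_kbp", "tightrope_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_mean < 0 or self.read_noise_sigma < 0:
            raise ValueError("background_mean and read_noise_sigma must be non-negative")
        for i, sp in enumerate(self.species):
            if not sp.composition:
                raise ValueError(f"species[{i}].composition must be non-empty")
            if not 0 <= sp.dark_fraction <= 1:
                raise ValueError(f"species[{i}].dark_fraction must be in [0, 1]")
            if not 0 <= sp.damage_bound_fraction <= 1:
                raise ValueError(f"species[{i}].damage_bound_fraction must be in [0, 1]")
            if sp.diffusion_constant_um2_s < 0:
                raise ValueError(f"species[{i}].diffusion_constant_um2_s must be >= 0")
            if sp.count < 0:
                raise ValueError(f"species[{i}].count must be >= 0")
            unknown = set(sp.composition) - set(self.channel_map)
            if unknown:
                raise ValueError(f"species[{i}].composition labels {unknown} missing "
                                 f"from channel_map")
        for p in self.damage_positions_kbp:
            if not 0 <= p <= self.tightrope_length_kbp:
                raise ValueError(f"damage_positions_kbp entry {p} outside "
                                 f"[0, {self.tightrope_length_kbp}]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        species = [Species(composition=tuple(sp["composition"]),
                           **{k: v for k, v in sp.items() if k != "composition"})
                   for sp in data.pop("species", [])]
        cfg = cls(species=species, **data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for sp in out["species"]:
            sp["composition"] = list(sp["composition"])
        return out

    @property
    def um_per_px(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def length_px(self) -> float:
        return self.tightrope_length_um / self.um_per_px

    def kbp_to_um(self, kbp: float) -> float:
        return kbp / self.tightrope_length_kbp * self.tightrope_length_um


@dataclass
class MoleculeTruth:
    molecule_id: int
    tightrope_id: int
    composition: tuple[str, ...]
    positions_um: np.ndarray  # axial position per frame
    visible: dict[str, bool]  # per protein label
    damage_bound: bool

    @property
    def mean_position_um(self) -> float:
        return float(np.mean(self.positions_um))

    def observed_composition(self) -> frozenset[str]:
        return frozenset(p for p in self.composition if self.visible[p])


@dataclass
class CellTruth:
    cell_id: int
    dose_J_m2: float
    has_static_spot: bool
    centre_xy: tuple[float, float]
    axes_px: tuple[float, float]
    angle_deg: float
    spot_xy: tuple[float, float] | None = None


@dataclass
class GroundTruth:
    molecules: list[MoleculeTruth] = field(default_factory=list)
    cells: list[CellTruth] = field(default_factory=list)


def reflected_brownian(n_steps: int, dt: float, d_um2_s: float, length_um: float,
                       x0_um: float, rng: np.random.Generator) -> np.ndarray:
    """Exact reflected Brownian path on [0, L] by folding the free path."""
    steps = rng.normal(0.0, math.sqrt(2.0 * d_um2_s * dt), size=n_steps)
    free = x0_um + np.concatenate([[0.0], np.cumsum(steps)])
    folded = length_um - np.abs(np.mod(free, 2.0 * length_um) - length_um)
    return folded


def render_gaussian(image: np.ndarray, x: float, y: float, amplitude: float,
                    sigma: float) -> None:
    """Stamp an isotropic 2D Gaussian onto ``image`` in place.

    The stamp window extends +-ceil(6 sigma), so the clipped mass is
    negligible (< 1e-7 of the total) away from frame edges.
    """
    half = int(math.ceil(6.0 * sigma))
    r, c = int(round(y)), int(round(x))
    r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))


def _apply_camera(signal: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    out = signal + config.background_mean
    if config.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if config.read_noise_sigma > 0:
        out = out + rng.normal(0.0, config.read_noise_sigma, size=out.shape)
    return out


def _blink_trace(n_frames: int, dt: float, on_rate: float, off_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Two-state telegraph: True where the emitter is on."""
    p_on = on_rate / (on_rate + off_rate)
    state = rng.random() < p_on
    trace = np.empty(n_frames, dtype=bool)
    p_off_to_on = 1.0 - math.exp(-on_rate * dt)
    p_on_to_off = 1.0 - math.exp(-off_rate * dt)
    for i in range(n_frames):
        trace[i] = state
        flip = p_on_to_off if state else p_off_to_on
        if rng.random() < flip:
            state = not state
    return trace


def tightrope_geometry(config: SimulationConfig,
                       tightrope_id: int = 0) -> tuple[TightropeGeometry, tuple[int, int]]:
    """Geometry and frame shape for a tightrope rendered at ``angle_deg``."""
    theta = math.radians(config.angle_deg)
    direction = np.array([math.cos(theta), math.sin(theta)])
    length = config.length_px
    m = config.margin_px
    e0 = np.array([m, m]) + np.where(direction < 0, -direction * length, 0.0)
    e1 = e0 + direction * length
    width = int(math.ceil(max(e0[0], e1[0]))) + m + 1
    height = int(math.ceil(max(e0[1], e1[1]))) + m + 1
    geom = TightropeGeometry(endpoints=np.array([e0, e1]),
                             pixel_size_nm=config.pixel_size_nm,
                             tightrope_id=tightrope_id)
    return geom, (height, width)


def _draw_positions(config: SimulationConfig, n: int,
                    rng: np.random.Generator) -> list[float]:
    """Uniform initial positions, optionally with a minimum pairwise spacing.

    Spaced placement uses the order-statistics spacing transform: sorted
    uniforms on the interval shrunk by (n-1) spacings, plus the spacings —
    uniform over all valid configurations, then randomly permuted.
    """
    length = config.tightrope_length_um
    if config.min_separation_um <= 0 or n < 2:
        return list(rng.uniform(0.0, length, size=n))
    d = config.min_separation_um
    slack = length - (n - 1) * d
    if slack <= 0:
        raise ValueError("min_separation_um too large for requested molecule count")
    u = np.sort(rng.uniform(0.0, slack, size=n))
    positions = u + d * np.arange(n)
    return list(rng.permutation(positions))


def generate_tightrope_movie(config: SimulationConfig, seed: int,
                             tightrope_id: int = 0) -> tuple[MovieStack, GroundTruth]:
    """Render one tightrope movie and its ground truth.

    Each molecule of each species is assigned a fixed per-dot visibility
    (Bernoulli with ``1 - dark_fraction``), an initial axial position
    (a configured damage coordinate if damage-bound, else uniform), and a
    reflected-Brownian trajectory with the species' diffusion constant
    (damage-bound molecules stay put).  Visible dots are rendered every
    frame as 2D Gaussians of ``psf_sigma_px``; the damage marker dot is
    rendered at every configured damage coordinate.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    geom, shape = tightrope_geometry(config, tightrope_id)
    n_frames = config.n_frames
    dt = 1.0 / config.frame_rate_hz

    damage_um = [config.kbp_to_um(p) for p in config.damage_positions_kbp]
    free_damage = list(damage_um)

    channels = sorted(set(config.channel_map.values()) | {config.damage_marker_channel})
    truth = GroundTruth()
    mol_id = 0
    # molecule bookkeeping first, all from the single rng, in fixed order
    molecules: list[tuple[MoleculeTruth, Species]] = []
    # positions drawn jointly over all species so min_separation_um holds
    # across the whole tightrope, not just within a species
    total_count = sum(sp.count for sp in config.species)
    all_positions = iter(_draw_positions(config, total_count, rng))
    for sp in config.species:
        for i in range(sp.count):
            damage_bound = bool(free_damage) and rng.random() < sp.damage_bound_fraction
            if damage_bound:
                pos0 = free_damage.pop(int(rng.integers(len(free_damage))))
                traj = np.full(n_frames, pos0)
            else:
                pos0 = next(all_positions)
                if sp.diffusion_constant_um2_s > 0:
                    traj = reflected_brownian(n_frames - 1, dt,
                                              sp.diffusion_constant_um2_s,
                                              config.tightrope_length_um, pos0, rng)
                else:
                    traj = np.full(n_frames, pos0)
            visible = {p: bool(rng.random() >= sp.dark_fraction)
                       for p in sp.composition}
            rec = MoleculeTruth(molecule_id=mol_id, tightrope_id=tightrope_id,
                                composition=tuple(sp.composition),
                                positions_um=traj, visible=visible,
                                damage_bound=damage_bound)
            truth.molecules.append(rec)
            molecules.append((rec, sp))
            mol_id += 1

    blink = {}
    if config.blink_on_rate_hz and config.blink_off_rate_hz:
        for rec, sp in molecules:
            for p in rec.composition:
                blink[(rec.molecule_id, p)] = _blink_trace(
                    n_frames, dt, config.blink_on_rate_hz,
                    config.blink_off_rate_hz, rng)

    signal = {ch: np.zeros((n_frames,) + shape) for ch in channels}
    for rec, sp in molecules:
        pos_px = rec.positions_um / config.um_per_px
        xy = geom.point_at_px(pos_px)  # (n_frames, 2)
        for p in rec.composition:
            if not rec.visible[p]:
                continue
            ch = config.channel_map[p]
            trace = blink.get((rec.molecule_id, p))
            for f in range(n_frames):
                if trace is not None and not trace[f]:
                    continue
                render_gaussian(signal[ch][f], xy[f, 0], xy[f, 1],
                                sp.amplitude, config.psf_sigma_px)
    for pos in damage_um:
        xy = geom.point_at_px(pos / config.um_per_px)
        for f in range(n_frames):
            render_gaussian(signal[config.damage_marker_channel][f],
                            xy[0], xy[1], config.damage_marker_amplitude,
                            config.psf_sigma_px)

    pixels = {ch: _apply_camera(signal[ch], config, rng) for ch in channels}
    movie = MovieStack(channels=pixels, pixel_size_nm=config.pixel_size_nm,
                       frame_interval_s=dt)
    return movie, truth


def generate_livecell_movie(config: SimulationConfig, n_cells: int,
                            static_fraction: float, seed: int,
                            dose_J_m2: float = 0.0,
                            cell_fluorescence: float = 40.0,
                            spot_amplitude: float = 150.0,
                            channel: str = "egfp") -> tuple[MovieStack, GroundTruth]:
    """Render a field of rod-shaped cells, a fraction of which carry a
    persistent immobile fluorescent spot (genome-bound protein); the rest
    show only homogeneous motion-blurred fluorescence (diffusing protein).

    Cells are laid out on a grid so masks never touch; each cell is an
    ellipse with randomized elongation and orientation.
    """
    config.validate()
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not 0 <= static_fraction <= 1:
        raise ValueError("static_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    box = 30  # px per cell tile
    n_side = int(math.ceil(math.sqrt(n_cells)))
    shape = (n_side * box, n_side * box)
    n_frames = config.n_frames
    dt = 1.0 / config.frame_rate_hz

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    body = np.zeros(shape)
    truth = GroundTruth()
    static_flags = rng.random(n_cells) < static_fraction
    spots: list[tuple[float, float]] = []
    for i in range(n_cells):
        gy, gx = divmod(i, n_side)
        cx = gx * box + box / 2 + rng.uniform(-2, 2)
        cy = gy * box + box / 2 + rng.uniform(-2, 2)
        a = rng.uniform(9, 12)   # semi-major (rod length / 2)
        b = rng.uniform(4, 5.5)  # semi-minor
        ang = rng.uniform(0, 180)
        th = math.radians(ang)
        xr = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
        yr = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        body[mask] += cell_fluorescence
        spot_xy = None
        if static_flags[i]:
            # spot well inside the cell so detection is not clipped by the edge
            u = rng.uniform(-0.5, 0.5)
            v = rng.uniform(-0.4, 0.4)
            sx = cx + u * a * math.cos(th) - v * b * math.sin(th)
            sy = cy + u * a * math.sin(th) + v * b * math.cos(th)
            spot_xy = (float(sx), float(sy))
            spots.append(spot_xy)
        truth.cells.append(CellTruth(cell_id=i, dose_J_m2=dose_J_m2,
                                     has_static_spot=bool(static_flags[i]),
                                     centre_xy=(float(cx), float(cy)),
                                     axes_px=(float(a), float(b)),
                                     angle_deg=float(ang), spot_xy=spot_xy))

    frames = np.empty((n_frames,) + shape)
    for f in range(n_frames):
        sig = body.copy()
        for sx, sy in spots:
            render_gaussian(sig, sx, sy, spot_amplitude, config.psf_sigma_px)
        frames[f] = sig
    pixels = {channel: _apply_camera(frames, config, rng)}
    movie = MovieStack(channels=pixels, pixel_size_nm=config.pixel_size_nm,
                       frame_interval_s=dt)
    return movie, truth


def expected_observed_composition(true_composition, dark_fraction: float
                                  ) -> dict[frozenset, float]:
    """Distribution of the observable label subset under independent
    per-dot visibility Bernoulli(1 - dark_fraction).

    Returns every subset of ``true_composition`` (including the empty set,
    i.e. an entirely dark complex) with its probability; probabilities
    sum to 1.
    """
    members = sorted(set(true_composition))
    if not members:
        raise ValueError("true_composition must be non-empty")
    if not 0 <= dark_fraction <= 1:
        raise ValueError("dark_fraction must be in [0, 1]")
    q, p = dark_fraction, 1.0 - dark_fraction
    out: dict[frozenset, float] = {}
    for r in range(len(members) + 1):
        for subset in itertools.combinations(members, r):
            out[frozenset(subset)] = p ** len(subset) * q ** (len(members) - len(subset))
    return out


def generate_survival_counts(doses, survival_fractions, n0: int,
                             dilutions=(1.0, 0.1, 0.01, 0.001),
                             seed: int = 0, strain: str = "strain",
                             n_replicates: int = 3) -> list[SurvivalRecord]:
    """Poisson colony counts for each dose x dilution x replicate.

    ``dilutions`` are plated fractions of the undiluted culture (undiluted
    plus serial ten-fold dilutions by default); the expected count is
    ``n0 * fraction * dilution``.
    """
    doses = list(doses)
    survival_fractions = list(survival_fractions)
    if len(doses) != len(survival_fractions):
        raise ValueError("doses and survival_fractions must have equal length")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    for f in survival_fractions:
        if not 0 < f <= 1:
            raise ValueError("survival fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for dose, frac in zip(doses, survival_fractions):
        for rep in range(n_replicates):
            for dil in dilutions:
                mean = n0 * frac * dil
                records.append(SurvivalRecord(
                    strain=strain, dose_J_m2=float(dose), dilution=float(dil),
                    colony_count=int(rng.poisson(mean)), replicate=rep))
    return records
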