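"""Colocalization census and damage-binding statistics.

Registered localizations from up to three quantum-dot channels are grouped
into complexes: any two spots from *different* channels whose centres lie
within the colocalization radius (3 px by default, inclusive, well inside
the PSF) are connected, and connected components are complexes.  Connected-
component closure means an A-B edge plus a B-C edge suffices for a triple
complex even without an A-C edge, as the outer members of a physical trimer
can exceed the pairwise window.

Damage scoring applies two rules from the assay design: tightropes carrying
more than six complexes are discarded entirely (over-labelled DNA would
inflate coincidental colocalization), and once the complex nearest a damage
marker scores positive, every other complex on that tightrope is excluded
from both numerator and denominator (preventing over-representation of
non-damage-binding molecules).  The random-association baseline scores the
same statistic against a virtual marker at the tightrope midpoint; for
uniform binding its analytic expectation is ``2 r / L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .detection import Spot

__all__ = [
    "ColocGroup",
    "ComplexRecord",
    "CensusTable",
    "DamageColocResult",
    "colocalize_channels",
    "census_complexes",
    "apply_density_filter",
    "damage_colocalization_probability",
    "baseline_random_probability",
    "compare_probabilities",
    "composition_label",
]


def composition_label(composition) -> str:
    """Canonical string for a composition set, e.g. {'B','A'} -> 'AB'."""
    return "".join(sorted(composition))


@dataclass
class ColocGroup:
    """A connected component of multi-channel spots."""

    composition: frozenset
    x: float
    y: float
    intensity: float
    members: list[Spot]
    ambiguous: bool = False  # two same-channel spots in one component


@dataclass
class ComplexRecord:
    """One complex on one tightrope, ready for census/damage scoring."""

    composition: frozenset
    s_um: float
    tightrope_id: int = 0
    flow_cell_id: int = 0
    intensity: float = 0.0
    motility: str = "unclassified"
    damage_colocalized: bool | None = None
    ambiguous: bool = False


@dataclass
class CensusTable:
    """Per-composition counts and occurrence fractions with flow-cell SEM."""

    table: pd.DataFrame  # composition, count, fraction_pct, sem_pct
    total: int
    n_flow_cells: int

    def fraction_pct(self, composition) -> float:
        label = composition_label(composition) if not isinstance(composition, str) \
            else composition
        row = self.table[self.table["composition"] == label]
        if row.empty:
            raise KeyError(f"composition {label!r} not in census")
        return float(row["fraction_pct"].iloc[0])


@dataclass
class DamageColocResult:
    n_examined: int
    n_colocalized: int
    probability_pct: float
    sem_pct: float
    per_flow_cell_pct: dict = field(default_factory=dict)
    baseline_pct: float | None = None


def colocalize_channels(spots_by_channel: dict[str, list[Spot]],
                        radius: float = 3.0,
                        protein_map: dict[str, str] | None = None
                        ) -> list[ColocGroup]:
    """Group registered spots into complexes by connected components.

    An edge joins two spots from different channels whose Euclidean centre
    distance is <= ``radius`` (inclusive).  ``protein_map`` translates
    channel labels into protein labels for the composition; by default the
    channel labels themselves are used.  Components containing two spots
    from the same channel are flagged ambiguous (one dot per protein per
    colour cannot resolve them) and should be excluded from the census.
    """
    all_spots: list[Spot] = []
    chan_of: list[str] = []
    for ch, spots in sorted(spots_by_channel.items()):
        for s in spots:
            all_spots.append(s)
            chan_of.append(ch)
    n = len(all_spots)
    if n == 0:
        return []
    xy = np.array([[s.x, s.y] for s in all_spots])
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if chan_of[i] == chan_of[j]:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                rows.append(i)
                cols.append(j)
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups: list[ColocGroup] = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        members = [all_spots[i] for i in idx]
        chans = [chan_of[i] for i in idx]
        ambiguous = len(chans) != len(set(chans))
        weights = np.array([max(m.intensity, 1e-12) for m in members])
        pos = (xy[idx] * weights[:, None]).sum(axis=0) / weights.sum()
        if protein_map is not None:
            comp = frozenset(protein_map[ch] for ch in set(chans))
        else:
            comp = frozenset(chans)
        groups.append(ColocGroup(composition=comp, x=float(pos[0]), y=float(pos[1]),
                                 intensity=float(weights.sum()), members=members,
                                 ambiguous=ambiguous))
    groups.sort(key=lambda g: (g.y, g.x))
    return groups


def census_complexes(records, protein_map: dict[str, str] | None = None
                     ) -> CensusTable:
    """Composition census: counts, occurrence fractions and flow-cell SEM.

    ``records`` is either a list of :class:`ComplexRecord` (ambiguous ones
    are dropped) or a mapping ``composition -> count`` for census arithmetic
    on pre-tabulated data.  Fractions are 100 * count / total; the SEM is
    computed over per-flow-cell fractions when flow-cell ids are present.
    """
    if isinstance(records, dict):
        recs = []
        for comp, count in records.items():
            cset = frozenset(comp) if not isinstance(comp, frozenset) else comp
            recs.extend(ComplexRecord(composition=cset, s_um=0.0)
                        for _ in range(int(count)))
        records = recs
    records = [r for r in records if not r.ambiguous]
    if not records:
        raise ValueError("census requires at least one unambiguous record")
    if protein_map is not None:
        records = [ComplexRecord(
            composition=frozenset(protein_map.get(m, m) for m in r.composition),
            s_um=r.s_um, tightrope_id=r.tightrope_id, flow_cell_id=r.flow_cell_id,
            intensity=r.intensity, motility=r.motility) for r in records]
    total = len(records)
    labels = [composition_label(r.composition) for r in records]
    counts = pd.Series(labels).value_counts()
    flow_cells = sorted({r.flow_cell_id for r in records})
    sems = {}
    if len(flow_cells) > 1:
        per_fc = pd.crosstab(pd.Series(labels, name="comp"),
                             pd.Series([r.flow_cell_id for r in records], name="fc"))
        per_fc_frac = 100.0 * per_fc / per_fc.sum(axis=0)
        sems = (per_fc_frac.std(axis=1, ddof=1)
                / np.sqrt(len(flow_cells))).to_dict()
    rows = []
    for label in counts.index:
        count = int(counts[label])
        rows.append({"composition": label, "count": count,
                     "fraction_pct": 100.0 * count / total,
                     "sem_pct": sems.get(label, float("nan"))})
    table = pd.DataFrame(rows).sort_values("count", ascending=False,
                                           kind="stable").reset_index(drop=True)
    return CensusTable(table=table, total=total, n_flow_cells=len(flow_cells))


def apply_density_filter(records: list[ComplexRecord],
                         max_per_tightrope: int = 6) -> list[ComplexRecord]:
    """Drop every complex on tightropes carrying more than the cap.

    Six complexes on a 16 um tightrope corresponds to a uniform spacing of
    >2.5 um (>7.5 kbp), comfortably separable; denser tightropes would
    inflate coincidental damage colocalization and are excluded outright.
    """
    if max_per_tightrope < 1:
        raise ValueError("max_per_tightrope must be >= 1")
    counts: dict[tuple, int] = {}
    for r in records:
        key = (r.flow_cell_id, r.tightrope_id)
        counts[key] = counts.get(key, 0) + 1
    return [r for r in records
            if counts[(r.flow_cell_id, r.tightrope_id)] <= max_per_tightrope]


def _score_tightrope(complexes: list[ComplexRecord], markers_um: list[float],
                     radius_um: float) -> tuple[int, int]:
    """(colocalized, examined) for one tightrope under the exclusion rule.

    The complex nearest any marker (ties to the brighter complex) is tested
    against the radius; if it colocalizes, it alone is examined and every
    other complex on the tightrope is excluded, otherwise all complexes are
    examined and none colocalize.
    """
    if not complexes or not markers_um:
        return 0, 0
    dists = [min(abs(c.s_um - m) for m in markers_um) for c in complexes]
    order = sorted(range(len(complexes)),
                   key=lambda i: (dists[i], -complexes[i].intensity))
    nearest = order[0]
    if dists[nearest] <= radius_um:
        return 1, 1
    return 0, len(complexes)


def damage_colocalization_probability(records: list[ComplexRecord],
                                      damage_positions_um: dict,
                                      radius_px: float = 3.0,
                                      pixel_size_nm: float = 100.0
                                      ) -> DamageColocResult:
    """Probability (%) of finding a complex colocalized with a damage marker.

    ``damage_positions_um`` maps ``(flow_cell_id, tightrope_id)`` (or bare
    ``tightrope_id``) to a list of marker axial positions in um.  Scoring
    follows the exclusion rule (see :func:`_score_tightrope`); the SEM is
    taken over per-flow-cell probabilities.
    """
    radius_um = radius_px * pixel_size_nm / 1000.0
    by_tr: dict[tuple, list[ComplexRecord]] = {}
    for r in records:
        by_tr.setdefault((r.flow_cell_id, r.tightrope_id), []).append(r)

    def markers_for(key):
        if key in damage_positions_um:
            return damage_positions_um[key]
        return damage_positions_um.get(key[1], [])

    n_coloc = 0
    n_exam = 0
    per_fc: dict = {}
    for key, cplx in sorted(by_tr.items()):
        markers = markers_for(key)
        if not markers:
            continue
        c, e = _score_tightrope(cplx, list(markers), radius_um)
        n_coloc += c
        n_exam += e
        fc = key[0]
        cc, ee = per_fc.get(fc, (0, 0))
        per_fc[fc] = (cc + c, ee + e)
    if n_exam == 0:
        raise ValueError("no complexes on marker-bearing tightropes to examine")
    per_fc_pct = {fc: 100.0 * c / e for fc, (c, e) in per_fc.items() if e > 0}
    sem = float("nan")
    if len(per_fc_pct) > 1:
        vals = np.array(list(per_fc_pct.values()))
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return DamageColocResult(n_examined=n_exam, n_colocalized=n_coloc,
                             probability_pct=100.0 * n_coloc / n_exam,
                             sem_pct=sem, per_flow_cell_pct=per_fc_pct)


def baseline_random_probability(records: list[ComplexRecord],
                                length_um: float = 16.0,
                                radius_px: float = 3.0,
                                pixel_size_nm: float = 100.0
                                ) -> DamageColocResult:
    """Random-association baseline: score against a virtual midpoint marker.

    Applies the identical exclusion-rule scoring with a marker at L/2 on
    every (undamaged) tightrope.  ``baseline_pct`` carries the analytic
    expectation for uniform binding, ``100 * min(2 r, L) / L``.
    """
    tightropes = sorted({(r.flow_cell_id, r.tightrope_id) for r in records})
    if not tightropes:
        raise ValueError("no records")
    markers = {key: [length_um / 2.0] for key in tightropes}
    result = damage_colocalization_probability(records, markers,
                                               radius_px=radius_px,
                                               pixel_size_nm=pixel_size_nm)
    radius_um = radius_px * pixel_size_nm / 1000.0
    result.baseline_pct = 100.0 * min(2.0 * radius_um, length_um) / length_um
    return result


def compare_probabilities(group_a, group_b) -> tuple[float, float]:
    """Two-sided equal-variance two-sample Student's t-test on per-flow-cell
    fractions; returns (t statistic, p value)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance groups
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0  # zero pooled variance, equal means
    return float(t), float(p)
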