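"""UV survival curves from colony counts.

Survival at a dose is the colony concentration (count / plated dilution)
relative to the unirradiated control, reported on a log10 scale as is
conventional for UV kill curves.  Replicate fractions are averaged before
the log transform; spread is reported as the standard deviation of the
per-replicate fractions propagated onto the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "LogSurvival",
    "log_relative_survival",
    "percent_survival",
    "build_survival_curve",
    "plot_survival_curve",
]

LN10 = math.log(10.0)


@dataclass
class SurvivalRecord:
    """One plate: colony count at a given strain, dose, dilution, replicate.

    ``dilution`` is the plated fraction of the undiluted culture
    (1, 0.1, 0.01, ... for undiluted and serial ten-fold dilutions).
    """

    strain: str
    dose_J_m2: float
    dilution: float
    colony_count: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.dose_J_m2 < 0:
            raise ValueError("dose_J_m2 must be >= 0")
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")
        if self.colony_count < 0:
            raise ValueError("colony_count must be >= 0")


@dataclass
class LogSurvival:
    """log10 relative survival with replicate spread."""

    value: float
    sd: float
    n_replicates: int
    lower_bound: bool = False  # True when treated counts were all zero (LOD)

    @property
    def fraction(self) -> float:
        return 10.0 ** self.value


def _concentration(records: list[SurvivalRecord]) -> float:
    """Colony concentration in undiluted-culture units, pooled over plates."""
    counts = sum(r.colony_count for r in records)
    volume = sum(r.dilution for r in records)
    return counts / volume


def log_relative_survival(treated: list[SurvivalRecord],
                          control: list[SurvivalRecord]) -> LogSurvival:
    """log10 of treated / control colony concentration, replicate-averaged.

    Per replicate the survival fraction is the ratio of pooled colony
    concentrations; fractions are averaged over replicates before taking
    log10.  A replicate with zero treated colonies yields a
    limit-of-detection lower bound of 0.5 colonies on its most concentrated
    plate, and the result is flagged ``lower_bound``.
    """
    if not treated or not control:
        raise ValueError("treated and control record sets must be non-empty")
    ctrl_by_rep = _group_by_replicate(control)
    trt_by_rep = _group_by_replicate(treated)
    fractions = []
    lower = False
    for rep, trt in sorted(trt_by_rep.items()):
        ctrl = ctrl_by_rep.get(rep)
        if ctrl is None:  # unmatched replicate: compare against pooled control
            ctrl = control
        c_conc = _concentration(ctrl)
        if c_conc <= 0:
            raise ValueError("control counts must be positive")
        t_conc = _concentration(trt)
        if t_conc == 0:
            # limit of detection: < 0.5 colonies on the densest plate
            t_conc = 0.5 / max(r.dilution for r in trt)
            lower = True
        fractions.append(t_conc / c_conc)
    mean_frac = float(np.mean(fractions))
    value = math.log10(mean_frac)
    if len(fractions) > 1:
        sd_frac = float(np.std(fractions, ddof=1))
        sd = sd_frac / (mean_frac * LN10)
    else:
        sd = float("nan")
    return LogSurvival(value=value, sd=sd, n_replicates=len(fractions),
                       lower_bound=lower)


def _group_by_replicate(records: list[SurvivalRecord]) -> dict[int, list[SurvivalRecord]]:
    out: dict[int, list[SurvivalRecord]] = {}
    for r in records:
        out.setdefault(r.replicate, []).append(r)
    return out


def percent_survival(log10_value: float) -> float:
    """Convert log10 relative survival to percent (e.g. -1.3 -> 5.0%)."""
    if not math.isfinite(log10_value):
        raise ValueError("log10_value must be finite")
    return 100.0 * 10.0 ** log10_value


def build_survival_curve(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Per-strain dose-response table of log10 relative survival.

    Requires a dose-0 control per strain.  Columns: strain, dose_J_m2,
    log10_survival, sd, n_replicates, lower_bound.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    by_strain: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_strain.setdefault(r.strain, []).append(r)
    for strain, recs in sorted(by_strain.items()):
        doses = sorted({r.dose_J_m2 for r in recs})
        if 0.0 not in doses:
            raise ValueError(f"strain {strain!r} lacks a dose-0 control")
        if len(doses) < 2:
            raise ValueError(f"strain {strain!r} needs at least 2 doses")
        control = [r for r in recs if r.dose_J_m2 == 0.0]
        for dose in doses:
            treated = [r for r in recs if r.dose_J_m2 == dose]
            ls = log_relative_survival(treated, control)
            rows.append({"strain": strain, "dose_J_m2": dose,
                         "log10_survival": ls.value, "sd": ls.sd,
                         "n_replicates": ls.n_replicates,
                         "lower_bound": ls.lower_bound})
    return pd.DataFrame(rows)


def plot_survival_curve(curve: pd.DataFrame, path=None):
    """Plot log10 survival versus dose per strain (SD error bars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for strain, sub in curve.groupby("strain"):
        sub = sub.sort_values("dose_J_m2")
        yerr = np.nan_to_num(sub["sd"].to_numpy())
        ax.errorbar(sub["dose_J_m2"], sub["log10_survival"], yerr=yerr,
                    marker="o", capsize=3, label=str(strain))
    ax.set_xlabel("UV dose (J/m$^2$)")
    ax.set_ylabel("log$_{10}$ relative survival")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
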