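"""Spike-stability validation battery.

Checks that the comb filtering leaves sorted units stable across laser
conditions: per-minute means and SEMs of the three spike features, per-minute
spike counts, laser-on/off comparison summaries, and the distribution of
spike times within the artifact period (which would reveal laser-locked
artifact spikes leaking into the sorted units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SegmentLabel
from .spikes import autocorrelogram

__all__ = [
    "StabilityReport",
    "PhaseHistogram",
    "stability_report",
    "laser_phase_histogram",
    "condition_compare",
]


@dataclass
class StabilityReport:
    """Per-unit, per-minute feature statistics and spike counts.

    ``table`` columns: unit, minute, segment, n_spikes, then mean/sem for each
    of v_trough, v_pre5, v_post5. Minutes with no spikes carry NaN means and
    zero counts. SEM = SD / sqrt(n).
    """

    table: pd.DataFrame
    minute_edges: np.ndarray

    def unit(self, u: int) -> pd.DataFrame:
        return self.table[self.table["unit"] == u]


@dataclass
class PhaseHistogram:
    """Spike counts per phase bin of one artifact period [0, 1/D_F)."""

    bin_edges: np.ndarray  # phase in [0, 1], n_bins + 1 edges
    counts: np.ndarray
    n_spikes: int = 0

    def __post_init__(self) -> None:
        self.n_spikes = int(np.sum(self.counts))


FEATURE_NAMES = ("v_trough", "v_pre5", "v_post5")


def _segment_of(t: float, segments: list[SegmentLabel] | None) -> str:
    if segments:
        for seg in segments:
            if seg.start <= t < seg.end:
                return seg.kind
    return "unlabelled"


def stability_report(
    labels: np.ndarray,
    spike_times_s: np.ndarray,
    features: np.ndarray,
    segments: list[SegmentLabel] | None = None,
    total_duration: float | None = None,
    t0: float = 0.0,
) -> StabilityReport:
    """Per-minute (non-overlapping 60 s bins from t0) feature means/SEMs and
    spike counts for every sorted unit.

    ``features`` is the n_spikes x 3 matrix (v_trough, v_pre5, v_post5).
    """
    labels = np.asarray(labels)
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if total_duration is None:
        total_duration = spike_times_s.max() - t0 if spike_times_s.size else 60.0
    n_minutes = max(int(np.ceil(total_duration / 60.0)), 1)
    edges = t0 + 60.0 * np.arange(n_minutes + 1)

    rows = []
    for u in np.unique(labels) if labels.size else []:
        in_u = labels == u
        for m in range(n_minutes):
            t_lo, t_hi = edges[m], edges[m + 1]
            sel = in_u & (spike_times_s >= t_lo) & (spike_times_s < t_hi)
            n = int(np.sum(sel))
            row = {
                "unit": int(u), "minute": m,
                "segment": _segment_of(0.5 * (t_lo + t_hi), segments),
                "n_spikes": n,
            }
            for j, name in enumerate(FEATURE_NAMES):
                vals = features[sel, j]
                row[f"{name}_mean"] = float(vals.mean()) if n else np.nan
                row[f"{name}_sem"] = (
                    float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
                )
            rows.append(row)
    cols = ["unit", "minute", "segment", "n_spikes"] + [
        f"{n}_{s}" for n in FEATURE_NAMES for s in ("mean", "sem")
    ]
    return StabilityReport(table=pd.DataFrame(rows, columns=cols), minute_edges=edges)


def laser_phase_histogram(
    spike_times_s: np.ndarray,
    frame_start_times_s: np.ndarray | None = None,
    frame_period_s: float | None = None,
    n_bins: int = 20,
    laser_on: tuple[float, float] | None = None,
) -> PhaseHistogram:
    """Occurrence of each spike within the artifact (imaging frame) period.

    Phase = (spike time - nearest preceding frame start) / period. The frame
    clock can be given explicitly (``frame_start_times_s``) or derived from
    the period alone with origin at the first laser-on spike's preceding
    frame; counts conserve the number of laser-on spikes.
    """
    spike_times_s = np.sort(np.asarray(spike_times_s, dtype=float))
    if laser_on is not None:
        spike_times_s = spike_times_s[
            (spike_times_s >= laser_on[0]) & (spike_times_s < laser_on[1])
        ]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if frame_start_times_s is not None:
        starts = np.sort(np.asarray(frame_start_times_s, dtype=float))
        if starts.size == 0:
            raise ValueError("no frame starts in segment")
        if frame_period_s is None:
            frame_period_s = float(np.median(np.diff(starts))) if starts.size > 1 else None
            if frame_period_s is None:
                raise ValueError("need >= 2 frame starts or an explicit period")
        idx = np.searchsorted(starts, spike_times_s, side="right") - 1
        valid = idx >= 0
        phase = (spike_times_s[valid] - starts[idx[valid]]) / frame_period_s
        phase = phase[phase < 1.0]  # spikes past the last frame's period drop out
    elif frame_period_s is not None:
        origin = laser_on[0] if laser_on is not None else 0.0
        phase = ((spike_times_s - origin) / frame_period_s) % 1.0
    else:
        raise ValueError("need frame_start_times_s or frame_period_s")
    counts, _ = np.histogram(phase, bins=edges)
    return PhaseHistogram(bin_edges=edges, counts=counts)


def condition_compare(
    report: StabilityReport,
    segments: list[SegmentLabel],
    labels: np.ndarray | None = None,
    spike_times_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Laser-on vs laser-off summary per unit.

    For each unit and feature: difference of segment means in pooled-SEM
    units; plus the on/off firing-rate ratio and, when spike times are given,
    the maximum absolute difference of the normalised on/off autocorrelograms.
    Missing segments produce a partial report with a warning.
    """
    present = {s.kind for s in segments}
    missing = {"laser_off_pre", "laser_on", "laser_off_post"} - present
    if missing:
        warnings.warn(f"segments missing: {sorted(missing)}; partial report",
                      stacklevel=2)
    tab = report.table
    off_kinds = ("laser_off_pre", "laser_off_post")
    dur = {
        "on": sum(s.end - s.start for s in segments if s.kind == "laser_on"),
        "off": sum(s.end - s.start for s in segments if s.kind in off_kinds),
    }
    rows = []
    for u in sorted(tab["unit"].unique()):
        t_u = tab[tab["unit"] == u]
        on = t_u[t_u["segment"] == "laser_on"]
        off = t_u[t_u["segment"].isin(off_kinds)]
        row: dict = {"unit": int(u)}
        for name in FEATURE_NAMES:
            m_on = np.nansum(on["n_spikes"] * on[f"{name}_mean"]) / max(on["n_spikes"].sum(), 1)
            m_off = np.nansum(off["n_spikes"] * off[f"{name}_mean"]) / max(off["n_spikes"].sum(), 1)
            sems = pd.concat([on[f"{name}_sem"], off[f"{name}_sem"]]).dropna()
            pooled = float(np.sqrt(np.mean(sems**2))) if len(sems) else np.nan
            row[f"{name}_diff_sem"] = (m_on - m_off) / pooled if pooled else np.nan
        n_on, n_off = on["n_spikes"].sum(), off["n_spikes"].sum()
        r_on = n_on / dur["on"] if dur["on"] else np.nan
        r_off = n_off / dur["off"] if dur["off"] else np.nan
        row["rate_on_hz"] = r_on
        row["rate_off_hz"] = r_off
        row["rate_ratio"] = r_on / r_off if r_off else np.nan
        if labels is not None and spike_times_s is not None:
            times_u = np.asarray(spike_times_s)[np.asarray(labels) == u]
            on_mask = np.zeros(times_u.size, dtype=bool)
            for s in segments:
                if s.kind == "laser_on":
                    on_mask |= s.contains(times_u)
            _, ac_on = autocorrelogram(times_u[on_mask])
            _, ac_off = autocorrelogram(times_u[~on_mask])
            with np.errstate(invalid="ignore", divide="ignore"):
                p_on = ac_on / max(ac_on.sum(), 1)
                p_off = ac_off / max(ac_off.sum(), 1)
            row["acg_max_abs_diff"] = float(np.max(np.abs(p_on - p_off)))
        rows.append(row)
    return pd.DataFrame(rows)
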