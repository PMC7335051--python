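"""Automated gating of cytometry event tables.

The pipeline mirrors a standard LCL immunostaining workflow, applied
independently within each experimental batch ("set"):

1. saturation trimming at pooled per-channel 5th/95th percentiles, with a
   positive shift on channels whose lower bound is negative;
2. removal of unstained-DAPI debris below the first peak-valley-peak valley;
3. a pooled 75%-mass density gate in the FSC-A/SSC-A plane (homogeneous size);
4. a pooled 80%-mass density gate in the FSC-A/FSC-W plane (doublet removal);
5. per-sample G1 selection below the DAPI density valley right of the G1 mode;
6. removal of samples left with <= 1000 events;
7. robust (Huber) size correction of log fluorescence on log scatter;
8. landmark-based warping of replicates of the same line and protein;
9. replicate-outlier flagging by the mean pairwise Kolmogorov-Smirnov
   statistic K, thresholded at the batch-wide 95th percentile of K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._density import density_peaks, first_valley, kde_1d, kde_2d
from .core import CHANNELS, EventTable, NoValleyError, QCReport

__all__ = [
    "ChannelBounds",
    "GateRegion2D",
    "GatingConfig",
    "pooled_channel_bounds",
    "filter_saturated",
    "dapi_stain_threshold",
    "density_gate_2d",
    "apply_gate",
    "g1_threshold",
    "size_correct",
    "warp_align",
    "replicate_outlier_scores",
    "run_gating",
]


@dataclass(frozen=True)
class ChannelBounds:
    channel: str
    lower: float
    upper: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate bounds for {self.channel}: {self.lower}..{self.upper}")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")


@dataclass
class GateRegion2D:
    """Highest-density region of a 2-D KDE holding >= ``fraction`` of mass.

    Membership is a deterministic grid lookup: an event lies inside iff its
    (chX, chY) bin belongs to the selected level set.
    """

    channel_x: str
    channel_y: str
    fraction: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    inside: np.ndarray  # boolean (nx, ny) bin membership
    achieved_fraction: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ix = np.digitize(x, self.x_edges) - 1
        iy = np.digitize(y, self.y_edges) - 1
        nx, ny = self.inside.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(x.shape, dtype=bool)
        out[ok] = self.inside[ix[ok], iy[ok]]
        return out


def pooled_channel_bounds(samples: Sequence[EventTable], channel: str) -> ChannelBounds:
    """5th/95th percentile bounds of the channel pooled over all samples.

    When the lower bound is negative, ``shift`` is its absolute value: the
    shift is later added to the channel so downstream values are >= 0.
    """
    values = np.concatenate([s.channel(channel) for s in samples]) if samples else np.array([])
    if values.size == 0:
        raise ValueError("empty pooled channel")
    if np.ptp(values) == 0:
        raise ValueError(f"constant channel {channel!r}: degenerate bounds")
    lower, upper = np.percentile(values, [5, 95])  # linear interpolation
    return ChannelBounds(channel, float(lower), float(upper), shift=abs(min(lower, 0.0)))


def filter_saturated(sample: EventTable, bounds: Sequence[ChannelBounds]) -> EventTable:
    """Drop events outside the closed [lower, upper] on any channel, then shift."""
    covered = {b.channel for b in bounds}
    missing = [c for c in CHANNELS if c not in covered]
    if missing:
        raise ValueError(f"bounds missing for channels: {missing}")
    keep = np.ones(sample.n_events, dtype=bool)
    for b in bounds:
        v = sample.channel(b.channel)
        keep &= (v >= b.lower) & (v <= b.upper)
    data = sample.data.loc[keep].copy()
    for b in bounds:
        if b.shift > 0:
            data[b.channel] = data[b.channel] + b.shift
    return sample.with_data(data)


def dapi_stain_threshold(dapi: np.ndarray, grid_size: int = 512) -> float:
    """Valley of the first peak-valley-peak motif of the DAPI density.

    Events below the returned intensity are unstained debris. Raises
    :class:`NoValleyError` on a unimodal density; the caller should then skip
    this filter.
    """
    dapi = np.asarray(dapi, dtype=float)
    grid, dens = kde_1d(dapi, grid_size=grid_size)
    peaks = density_peaks(grid, dens, min_rel_height=0.02)
    if len(peaks) < 2:
        raise NoValleyError("DAPI density is unimodal; no valley found")
    mode = int(np.argmax(dens))
    if peaks[0] >= mode:
        # the leftmost peak is the stained G1 mode itself: there is no
        # separate low-DAPI debris population to cut away
        raise NoValleyError("no unstained sub-peak left of the main DAPI mode")
    valley = first_valley(grid, dens, int(peaks[0]), int(peaks[1]))
    return float(grid[valley])


def density_gate_2d(
    pooled: Sequence[EventTable],
    channel_x: str,
    channel_y: str,
    fraction: float,
    grid_size: int = 256,
) -> GateRegion2D:
    """Highest-density 2-D gate containing >= ``fraction`` of pooled events.

    Grid bins are ranked by kernel density and accumulated (by pooled event
    count) until the target mass is reached, yielding the smallest level set
    with mass >= ``fraction``; one gate per batch, applied to every sample.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    x = np.concatenate([s.channel(channel_x) for s in pooled])
    y = np.concatenate([s.channel(channel_y) for s in pooled])
    if x.size < 100:
        raise ValueError("need at least 100 pooled events for a density gate")
    x_edges, y_edges, dens = kde_2d(x, y, grid_size=grid_size)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    order = np.argsort(dens, axis=None)[::-1]
    cum = np.cumsum(counts.ravel()[order]) / x.size
    n_in = int(np.searchsorted(cum, fraction) + 1)
    inside = np.zeros(dens.size, dtype=bool)
    inside[order[:n_in]] = True
    return GateRegion2D(
        channel_x=channel_x,
        channel_y=channel_y,
        fraction=fraction,
        x_edges=x_edges,
        y_edges=y_edges,
        inside=inside.reshape(dens.shape),
        achieved_fraction=float(cum[n_in - 1]),
    )


def apply_gate(sample: EventTable, region: GateRegion2D) -> EventTable:
    keep = region.contains(sample.channel(region.channel_x), sample.channel(region.channel_y))
    return sample.with_data(sample.data.loc[keep])


def g1_threshold(dapi: np.ndarray, min_events: int = 100, grid_size: int = 512) -> float:
    """DAPI cut-off separating the G1 peak from S/G2 cells.

    The threshold sits at the first density valley to the right of the global
    mode (where the falling flank of the G1 peak flattens out before the G2
    peak); cells below it are called G1. A unimodal density (pure G1) puts
    the threshold at the right edge of the density support, retaining
    essentially all cells.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size < min_events:
        raise ValueError(f"need >= {min_events} events to set a G1 threshold")
    grid, dens = kde_1d(dapi, grid_size=grid_size)
    mode = int(np.argmax(dens))
    right_peaks = [p for p in density_peaks(grid, dens) if p > mode]
    if right_peaks:
        valley = first_valley(grid, dens, mode, int(right_peaks[0]))
        return float(grid[valley])
    return float(grid[-1])


def size_correct(sample: EventTable, report: QCReport | None = None) -> EventTable:
    """Remove the size trend from log fluorescence.

    Fits a Huber M-estimated linear model FL ~ log(FSC-A) + log(SSC-A) per
    sample and replaces each value by ``mean(FL) + residual`` (arithmetic
    mean, matching the printed transform; the robust intercept is not used).
    A singular design leaves the sample uncorrected, logged.
    """
    y = sample.channel("FL")
    log_fsc = np.log(sample.channel("FSC-A"))
    log_ssc = np.log(sample.channel("SSC-A"))
    if np.ptp(log_fsc) < 1e-12 or np.ptp(log_ssc) < 1e-12 or y.size < 10:
        if report is not None:
            report.log(f"{sample.sample_id}: singular size design; correction skipped")
        return sample
    X = sm.add_constant(np.column_stack([log_fsc, log_ssc]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(maxiter=50, tol=1e-8)
    corrected = y.mean() + (y - fit.fittedvalues)
    data = sample.data.copy()
    data["FL"] = corrected
    return sample.with_data(data)


def _fl_landmarks(sample: EventTable, max_landmarks: int = 2) -> np.ndarray:
    """Positions of the up-to-two tallest FL density modes, left to right."""
    grid, dens = kde_1d(sample.channel("FL"))
    peaks = density_peaks(grid, dens, min_rel_height=0.15)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    tallest = peaks[np.argsort(dens[peaks])[::-1][:max_landmarks]]
    return np.sort(grid[tallest])


def _piecewise_warp(values: np.ndarray, own: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map sending ``own`` landmarks to ``target``.

    Outside the landmark span the map extends with unit slope, so the rank
    order of values is always preserved.
    """
    if len(own) == 1:
        return values + (target[0] - own[0])
    lo, hi = own
    t_lo, t_hi = target
    slope = (t_hi - t_lo) / (hi - lo)
    out = np.empty_like(values)
    left = values < lo
    right = values > hi
    mid = ~(left | right)
    out[left] = values[left] + (t_lo - lo)
    out[right] = values[right] + (t_hi - hi)
    out[mid] = t_lo + slope * (values[mid] - lo)
    return out


def warp_align(group: Sequence[EventTable], report: QCReport | None = None) -> list[EventTable]:
    """Align FL densities of replicates of one line/protein group.

    Up to two primary density modes per sample are registered to their
    group-consensus (mean) positions by a monotone piecewise-linear warp.
    With mismatched landmark counts only the shared leading landmark is
    aligned (a shift), logged. A single sample is returned unchanged.
    """
    if len(group) < 2:
        return list(group)
    landmarks = [_fl_landmarks(s) for s in group]
    counts = {len(l) for l in landmarks}
    if counts == {2}:
        target = np.mean(np.vstack(landmarks), axis=0)
        use = landmarks
    else:
        if len(counts) > 1 and report is not None:
            report.log("warp: landmark count mismatch; aligning on the leading landmark")
        use = [l[:1] for l in landmarks]
        target = np.array([np.mean([l[0] for l in use])])
    out = []
    for sample, own in zip(group, use):
        data = sample.data.copy()
        data["FL"] = _piecewise_warp(sample.channel("FL"), own, target)
        out.append(sample.with_data(data))
    return out


def replicate_outlier_scores(
    group: Sequence[EventTable],
    pooled_k: np.ndarray | None = None,
    percentile: float = 95.0,
    report: QCReport | None = None,
) -> list[tuple[float, bool]]:
    """Reproducibility score K and outlier flag per replicate.

    K is the mean two-sample Kolmogorov-Smirnov statistic against the other
    replicates of the group (defined only for groups of >= 3). Flags compare
    K to the ``percentile`` of ``pooled_k`` (all K scores of the batch) or,
    absent a pool, of the group's own scores.
    """
    if len(group) < 3:
        if report is not None and group:
            report.log(
                f"group of {group[0].line_id}/{group[0].protein}: fewer than 3 replicates; K undefined"
            )
        return [(float("nan"), False) for _ in group]
    fls = [s.channel("FL") for s in group]
    ks = np.zeros((len(group), len(group)))
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            d = stats.ks_2samp(fls[i], fls[j], method="asymp").statistic
            ks[i, j] = ks[j, i] = d
    k_scores = ks.sum(axis=1) / (len(group) - 1)
    pool = np.asarray(pooled_k, dtype=float) if pooled_k is not None else k_scores
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        return [(float(k), False) for k in k_scores]
    cut = np.percentile(pool, percentile)
    return [(float(k), bool(k > cut)) for k in k_scores]


@dataclass
class GatingConfig:
    size_gate_fraction: float = 0.75
    doublet_gate_fraction: float = 0.80
    min_events: int = 1000
    k_percentile: float = 95.0
    saturation: bool = True
    dapi_filter: bool = True
    size_gate: bool = True
    doublet_gate: bool = True
    g1_gate: bool = True
    size_correction: bool = True
    warp: bool = True
    outlier_filter: bool = True
    drop_outliers: bool = True
    grid_size: int = 256


def _record_all(report: QCReport, samples: Sequence[EventTable], step: str) -> None:
    for s in samples:
        report.record(s.sample_id, step, s.n_events)


def run_gating(
    samples: Sequence[EventTable], config: GatingConfig | None = None
) -> tuple[list[EventTable], QCReport]:
    """Run the full filtering/normalization pipeline, batch by batch.

    Batches never share bounds, gates or K-score pools. Samples left with
    <= ``min_events`` events after G1 selection are dropped (reason
    ``min-events``); replicate outliers (K above the batch 95th percentile)
    are dropped with reason ``k-outlier`` unless ``drop_outliers`` is off.
    """
    config = config or GatingConfig()
    report = QCReport()
    retained: list[EventTable] = []
    by_batch: dict[str, list[EventTable]] = {}
    for s in samples:
        by_batch.setdefault(s.batch_id, []).append(s)

    for batch_id, batch in by_batch.items():
        _record_all(report, batch, "input")

        if config.saturation:
            bounds = [pooled_channel_bounds(batch, ch) for ch in CHANNELS]
            batch = [filter_saturated(s, bounds) for s in batch]
            _record_all(report, batch, "saturation")

        if config.dapi_filter:
            filtered = []
            for s in batch:
                try:
                    cut = dapi_stain_threshold(s.channel("DAPI"))
                except (NoValleyError, ValueError):
                    report.log(f"{s.sample_id}: no DAPI valley; unstained filter skipped")
                    filtered.append(s)
                    continue
                filtered.append(s.with_data(s.data.loc[s.channel("DAPI") > cut]))
            batch = filtered
            _record_all(report, batch, "dapi-unstained")

        if config.size_gate:
            gate = density_gate_2d(
                batch, "FSC-A", "SSC-A", config.size_gate_fraction, config.grid_size
            )
            batch = [apply_gate(s, gate) for s in batch]
            _record_all(report, batch, "size-gate")

        if config.doublet_gate:
            gate = density_gate_2d(
                batch, "FSC-A", "FSC-W", config.doublet_gate_fraction, config.grid_size
            )
            batch = [apply_gate(s, gate) for s in batch]
            _record_all(report, batch, "doublet-gate")

        if config.g1_gate:
            gated = []
            for s in batch:
                try:
                    cut = g1_threshold(s.channel("DAPI"))
                except ValueError as exc:
                    report.dropped[s.sample_id] = f"g1-threshold: {exc}"
                    continue
                gated.append(s.with_data(s.data.loc[s.channel("DAPI") < cut]))
            batch = gated
            _record_all(report, batch, "g1")

        survivors = []
        for s in batch:
            if s.n_events <= config.min_events:
                report.dropped[s.sample_id] = "min-events"
            else:
                survivors.append(s)
        batch = survivors
        _record_all(report, batch, "min-events")

        if config.size_correction:
            batch = [size_correct(s, report) for s in batch]
            _record_all(report, batch, "size-correct")

        groups: dict[tuple, list[EventTable]] = {}
        for s in batch:
            groups.setdefault((s.line_id, s.protein), []).append(s)

        if config.warp:
            batch = [s for key in groups for s in warp_align(groups[key], report)]
            groups = {}
            for s in batch:
                groups.setdefault((s.line_id, s.protein), []).append(s)
            _record_all(report, batch, "warp")

        if config.outlier_filter:
            per_group = {
                key: [k for k, _ in replicate_outlier_scores(g, pooled_k=np.array([]), report=report)]
                for key, g in groups.items()
            }
            pooled = np.array(
                [k for scores in per_group.values() for k in scores if np.isfinite(k)]
            )
            cut = np.percentile(pooled, config.k_percentile) if pooled.size else np.inf
            final = []
            for key, g in groups.items():
                for s, k in zip(g, per_group[key]):
                    flag = bool(np.isfinite(k) and k > cut)
                    report.k_scores[s.sample_id] = k
                    report.outliers[s.sample_id] = flag
                    if flag and config.drop_outliers:
                        report.dropped[s.sample_id] = "k-outlier"
                    else:
                        final.append(s)
            batch = final
            _record_all(report, batch, "k-outlier")

        retained.extend(batch)
    return retained, report
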