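"""Observables of the sheet dynamics.

Everything here is a pure function of a :class:`SimulationResult` (or of a
:class:`SpikeRaster` derived from one): spike detection and rasters,
impulse lags and phase locking, traveling-front widths, backward
(retrograde) propagation, mean interspike intervals along the fiber,
spatial Fourier spectra, cross-model spectral similarity, and a
qualitative regime classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeRaster",
    "LagSeries",
    "MisiTable",
    "SpectrumSeries",
    "RegimeLabel",
    "detect_spikes",
    "default_z_stations",
    "build_raster",
    "measure_lag",
    "front_width",
    "detect_backward_propagation",
    "compute_misi",
    "spatial_spectrum",
    "spectrum_cosine_similarity",
    "classify_regime",
]

#: spike threshold: midway between rest (~ -1.03) and pulse peak (~ +1.8)
DEFAULT_THRESHOLD = 0.0
#: minimum inter-spike separation; below the FHN refractory at eps = 0.1
DEFAULT_REFRACTORY = 5.0
#: first-spike times within this window count as one phase-locked front
DEFAULT_LOCK_WINDOW = 5.0


@dataclass
class SpikeRaster:
    """Detected spike times per (1-based lateral index, axial station)."""

    spikes: dict  # (lateral_index, z_station) -> np.ndarray of times
    threshold: float
    refractory: float
    z_stations: np.ndarray
    n_lateral: int

    def row(self, lateral_index: int):
        """All (z_station, times) entries of one axon, ordered by z."""
        return [
            (z, self.spikes[(lateral_index, z)])
            for z in self.z_stations
            if len(self.spikes.get((lateral_index, z), ())) > 0
        ]

    def active_laterals(self, z_station: float) -> np.ndarray:
        """1-based lateral indices with at least one spike at the station."""
        out = [
            p
            for p in range(1, self.n_lateral + 1)
            if len(self.spikes.get((p, z_station), ())) > 0
        ]
        return np.asarray(out, dtype=int)

    def first_spike(self, lateral_index: int, z_station: float) -> float | None:
        times = self.spikes.get((lateral_index, z_station))
        if times is None or len(times) == 0:
            return None
        return float(times[0])


def detect_spikes(trace: np.ndarray, times: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD,
                  refractory: float = DEFAULT_REFRACTORY) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    Crossing times are linearly interpolated between samples; a crossing
    closer than ``refractory`` to the previously accepted spike is
    suppressed.  Returns a sorted array (empty for subthreshold traces).
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    below = trace[:-1] < threshold
    above = trace[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    out = []
    last = -np.inf
    for i in idx:
        frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
        t_cross = times[i] + frac * (times[i + 1] - times[i])
        if t_cross - last >= refractory:
            out.append(t_cross)
            last = t_cross
    return np.asarray(out)


def default_z_stations(grid, n_stations: int = 10) -> np.ndarray:
    """Equally spaced axial stations excluding the stimulus inlet window
    and the final 10% of the domain (boundary effects)."""
    z_lo = max(8.0, 2 * grid.dz)
    z_hi = 0.9 * grid.z_extent
    stations = np.linspace(z_lo, z_hi, n_stations)
    return np.round(stations / grid.dz) * grid.dz


def build_raster(result, z_stations=None, threshold: float = DEFAULT_THRESHOLD,
                 refractory: float = DEFAULT_REFRACTORY) -> SpikeRaster:
    """Apply :func:`detect_spikes` at every (lateral, station) node.

    Snapshot cadence must be at most half the refractory period so no
    spike can fall between samples.
    """
    grid = result.grid
    if grid.snapshot_every > refractory / 2:
        raise ValueError(
            f"snapshot cadence {grid.snapshot_every} too coarse for "
            f"refractory {refractory}; spikes could be missed"
        )
    if z_stations is None:
        z_stations = default_z_stations(grid)
    z_stations = np.asarray(z_stations, dtype=float)
    if np.any(z_stations < 0) or np.any(z_stations > grid.z_extent):
        raise ValueError("z_stations outside the domain")
    z_idx = np.round(z_stations / grid.dz).astype(int)
    spikes = {}
    for p in range(grid.n_lateral):
        for z, j in zip(z_stations, z_idx):
            trace = result.v[:, p, j]
            spikes[(p + 1, z)] = detect_spikes(trace, result.times,
                                               threshold, refractory)
    return SpikeRaster(spikes=spikes, threshold=threshold,
                       refractory=refractory, z_stations=z_stations,
                       n_lateral=grid.n_lateral)


@dataclass
class LagSeries:
    """First-spike lag between two axons at successive axial stations."""

    z_stations: np.ndarray
    lags: np.ndarray
    dropped_stations: int
    locked_after: int | None  # station index, or None if never locks

    @property
    def plateau_lag(self) -> float:
        return float(self.lags[-1])


def measure_lag(raster: SpikeRaster, pair, lock_tol: float = 0.02) -> LagSeries:
    """Per-station difference of first-spike times of ``pair = (p, q)``.

    ``locked_after`` is the first station index after which the lag
    changes by less than ``lock_tol`` (relative, with a small absolute
    floor for near-zero lags) at every subsequent station.  Stations
    where either axon is silent are dropped with a warning count.
    """
    p, q = pair
    stations, lags = [], []
    dropped = 0
    for z in raster.z_stations:
        tp = raster.first_spike(p, z)
        tq = raster.first_spike(q, z)
        if tp is None or tq is None:
            dropped += 1
            continue
        stations.append(z)
        lags.append(tq - tp)
    stations = np.asarray(stations)
    lags = np.asarray(lags)
    locked_after = None
    if len(lags) >= 2:
        scale = max(np.max(np.abs(lags)), 1.0)
        change = np.abs(np.diff(lags))
        ok = change < np.maximum(lock_tol * np.abs(lags[:-1]), 0.02 * scale)
        for i in range(len(ok)):
            if ok[i:].all():
                locked_after = i
                break
    return LagSeries(z_stations=stations, lags=lags,
                     dropped_stations=dropped, locked_after=locked_after)


def front_width(raster: SpikeRaster, z_station: float,
                time_window: float = DEFAULT_LOCK_WINDOW) -> list:
    """Sizes of laterally contiguous, phase-locked impulse clusters.

    At the given station, lateral indices with a first spike are grouped
    into clusters: consecutive members must be adjacent axons and their
    first-spike times must differ by at most ``time_window``.  A solitary
    impulse reports ``[1]``; a finite traveling front of k locked
    impulses reports k.
    """
    entries = []
    for plat in raster.active_laterals(z_station):
        entries.append((int(plat), raster.first_spike(int(plat), z_station)))
    if not entries:
        return []
    sizes = []
    current = 1
    for (p0, t0), (p1, t1) in zip(entries[:-1], entries[1:]):
        if p1 - p0 == 1 and abs(t1 - t0) <= time_window:
            current += 1
        else:
            sizes.append(current)
            current = 1
    sizes.append(current)
    return sizes


def detect_backward_propagation(raster: SpikeRaster, t_min: float = 0.0,
                                min_speed: float = 0.2) -> int:
    """Count retrograde spike chains (waves moving toward -z).

    A chain is, on one axon, a triple of spikes at three consecutive
    stations whose times strictly decrease with increasing z, with
    station-to-station delays consistent with a wave no slower than
    ``min_speed``.  Forward-only regimes yield 0.  ``t_min`` ignores
    chains that end before it (stimulus-onset transients).
    """
    if len(raster.z_stations) < 3:
        raise ValueError("need >= 3 z-stations to detect retrograde waves")
    z = raster.z_stations
    count = 0
    for p in range(1, raster.n_lateral + 1):
        rows = [np.asarray(raster.spikes.get((p, zz), ())) for zz in z]
        for j in range(len(z) - 2):
            dt1_max = (z[j + 1] - z[j]) / min_speed
            dt2_max = (z[j + 2] - z[j + 1]) / min_speed
            for t_a in rows[j]:
                if t_a < t_min:
                    continue
                b = rows[j + 1]
                b = b[(b < t_a) & (b > t_a - dt1_max)]
                for t_b in b:
                    c = rows[j + 2]
                    c = c[(c < t_b) & (c > t_b - dt2_max)]
                    count += len(c)
    return count


@dataclass
class MisiTable:
    """Mean interspike intervals per node and averaged per station."""

    per_node: pd.DataFrame  # columns: lateral_index, z_station, misi, n_spikes
    per_station: pd.DataFrame  # columns: z_station, misi, n_nodes

    def station_values(self) -> np.ndarray:
        return self.per_station["misi"].to_numpy()


def compute_misi(raster: SpikeRaster) -> MisiTable:
    """Mean interspike interval per node; station average over axons.

    Nodes with fewer than two spikes carry no interval and are excluded
    from the station average (their counts remain visible in
    ``per_node``).
    """
    rows = []
    for (p, z), times in raster.spikes.items():
        misi = np.nan
        if len(times) >= 2:
            misi = float(np.mean(np.diff(times)))
        rows.append({"lateral_index": p, "z_station": z,
                     "misi": misi, "n_spikes": len(times)})
    per_node = pd.DataFrame(rows).sort_values(
        ["z_station", "lateral_index"]).reset_index(drop=True)
    grouped = per_node.dropna(subset=["misi"]).groupby("z_station")
    per_station = grouped.agg(misi=("misi", "mean"),
                              n_nodes=("misi", "size")).reset_index()
    return MisiTable(per_node=per_node, per_station=per_station)


@dataclass
class SpectrumSeries:
    """Per-snapshot magnitude of the 2D spatial DFT, flattened."""

    times: np.ndarray
    magnitudes: np.ndarray  # (n_snapshots, n_modes)


def spatial_spectrum(result, axis: str = "2d") -> SpectrumSeries:
    """Magnitude of the discrete Fourier transform of each v snapshot.

    ``axis='2d'`` (default) transforms the full (lateral x axial)
    pattern; ``axis='x'`` transforms along the lateral direction only and
    averages magnitudes over axial positions (sensitivity variant).
    """
    v = result.v
    if axis == "2d":
        mags = np.abs(np.fft.fft2(v, axes=(1, 2))).reshape(len(v), -1)
    elif axis == "x":
        mags = np.abs(np.fft.fft(v, axis=1)).mean(axis=2)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return SpectrumSeries(times=result.times.copy(), magnitudes=mags)


def spectrum_cosine_similarity(a: SpectrumSeries, b: SpectrumSeries):
    """Cosine similarity between two spectrum series, per matched time.

    Returns ``(similarities, mean, std)``.  Snapshot times must match;
    times where either spectrum has zero norm are dropped with a warning.
    """
    if a.magnitudes.shape[1] != b.magnitudes.shape[1]:
        raise ValueError("spectra computed on mismatched grids")
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
        raise ValueError("snapshot times do not match")
    na = np.linalg.norm(a.magnitudes, axis=1)
    nb = np.linalg.norm(b.magnitudes, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.all():
        warnings.warn(f"dropped {np.count_nonzero(~ok)} zero-norm snapshots",
                      stacklevel=2)
    sims = np.einsum("ij,ij->i", a.magnitudes[ok], b.magnitudes[ok])
    sims = sims / (na[ok] * nb[ok])
    return sims, float(np.mean(sims)), float(np.std(sims))


@dataclass
class RegimeLabel:
    """Qualitative dynamical regime with its measured evidence."""

    kind: str  # independent | locked | front | complex | diffusive_front
    width: int | None = None
    low_confidence: bool = False
    evidence: dict = field(default_factory=dict)

    def __str__(self) -> str:
        if self.kind == "front" and self.width is not None:
            return f"front({self.width})"
        return self.kind


def classify_regime(result, raster: SpikeRaster | None = None,
                    lock_window: float = DEFAULT_LOCK_WINDOW) -> RegimeLabel:
    """Decision tree over measured evidence for a two-impulse scenario.

    * sustained retrograde chains -> ``complex``
    * no recruitment beyond the stimulated axons: constant lag ->
      ``independent``; converged lag between adjacent stimulated axons ->
      ``locked``
    * recruitment with a stable cluster size k and no retrograde chains
      -> ``front(k)``
    * cluster size growing along z without retrograde chains ->
      ``diffusive_front``

    Ambiguous evidence yields ``complex`` flagged low-confidence, never a
    silent guess.  Retrograde chains occurring only in the early quarter
    of the run count as onset transients and are ignored.
    """
    if raster is None:
        raster = build_raster(result)
    stimulated = sorted({e.lateral_index for e in result.protocol.events})
    t_transient = 0.25 * result.grid.t_end
    n_backward = detect_backward_propagation(raster, t_min=t_transient)
    evidence: dict = {"n_backward": n_backward, "stimulated": stimulated}
    # stations with any activity, ordered along z
    widths_per_station = []
    active_counts = []
    for z in raster.z_stations:
        sizes = front_width(raster, z, time_window=lock_window)
        if sizes:
            widths_per_station.append((z, sizes))
            active_counts.append(len(raster.active_laterals(z)))
    evidence["widths_per_station"] = widths_per_station
    if n_backward > 0:
        return RegimeLabel(kind="complex", evidence=evidence)
    if not widths_per_station:
        return RegimeLabel(kind="complex", low_confidence=True,
                           evidence=evidence)
    recruited = max(active_counts) > len(stimulated)
    if not recruited:
        if len(stimulated) == 2:
            lag = measure_lag(raster, tuple(stimulated))
            evidence["lags"] = lag.lags.tolist()
            evidence["locked_after"] = lag.locked_after
            if len(lag.lags) >= 2:
                span = np.ptp(lag.lags)
                rel = span / max(abs(lag.lags).max(), 1e-12)
                adjacent = abs(stimulated[0] - stimulated[1]) == 1
                if rel < 0.05:
                    return RegimeLabel(kind="independent", evidence=evidence)
                if adjacent and lag.locked_after is not None:
                    return RegimeLabel(kind="locked", evidence=evidence)
            return RegimeLabel(kind="complex", low_confidence=True,
                               evidence=evidence)
        return RegimeLabel(kind="independent", evidence=evidence)
    # recruitment occurred: stable front vs laterally growing front,
    # judged over the downstream half of the active stations
    half = len(widths_per_station) // 2
    downstream = widths_per_station[half:] or widths_per_station
    max_sizes = [max(sizes) for _, sizes in downstream]
    evidence["downstream_max_sizes"] = max_sizes
    if max(max_sizes) - min(max_sizes) <= 1:
        width = int(round(np.median(max_sizes)))
        return RegimeLabel(kind="front", width=width, evidence=evidence)
    growth = max_sizes[-1] - max_sizes[0]
    if growth >= 2:
        return RegimeLabel(kind="diffusive_front", evidence=evidence)
    return RegimeLabel(kind="complex", low_confidence=True, evidence=evidence)
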