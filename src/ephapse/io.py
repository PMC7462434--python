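"""Configuration files, HDF5 result archives, fixtures, and parameter scans.

A run is described by a YAML config with blocks ``model``, ``grid``,
``fhn``, ``stimulus`` and ``output``; exactly one of ``R`` (discrete
model) or ``K`` (continuum model) must be present.  Results are stored as
self-describing HDF5 archives carrying the full config and protocol echo,
so every analysis is reproducible from the archive alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import classify_regime
from .coupling import build_coupling_matrix
from .fhn import FHNParams
from .solvers import (
    GridSpec,
    PropagationError,
    SimulationResult,
    simulate_continuum,
    simulate_discrete,
)
from .stimulation import (
    StimulusProtocol,
    impulse_protocol,
    poisson_train_protocol,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "save_result",
    "load_result",
    "run_config",
    "make_fixture",
    "scan",
]

log = logging.getLogger("ephapse")


class ConfigError(ValueError):
    """Raised for malformed or contradictory run configurations."""


_GRID_KEYS = {"n_lateral", "dz", "dx", "dt", "z_extent", "t_end", "snapshot_every"}
_FHN_KEYS = {"a", "b", "eps"}
_STIM_KEYS = {"pairs", "train", "events", "generator", "seed"}
_TRAIN_KEYS = {"n_impulses", "mean_interval", "seed", "randomize_count"}
_OUTPUT_KEYS = {"path", "store_w"}
_MODEL_KEYS = {"kind", "R", "K"}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully resolved description of one simulation run."""

    model: str  # "discrete" | "continuum"
    coupling: float  # R or K
    grid: GridSpec
    fhn: FHNParams
    protocol: StimulusProtocol
    store_w: bool = False
    out_path: str | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "model": {"kind": self.model,
                      ("R" if self.model == "discrete" else "K"): self.coupling},
            "grid": asdict(self.grid),
            "fhn": asdict(self.fhn),
            "stimulus": json.loads(self.protocol.to_json()),
            "output": {"path": self.out_path, "store_w": self.store_w},
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed config mapping."""
    _check_keys(raw, {"model", "grid", "fhn", "stimulus", "output", "seed"},
                "top level")
    model_block = dict(raw.get("model") or {})
    _check_keys(model_block, _MODEL_KEYS, "model")
    has_R = "R" in model_block
    has_K = "K" in model_block
    if has_R == has_K:
        raise ConfigError("exactly one of R (discrete) or K (continuum) "
                          "must be given in [model]")
    model = model_block.get("kind") or ("discrete" if has_R else "continuum")
    if (model == "discrete") != has_R:
        raise ConfigError(f"model kind {model!r} inconsistent with the "
                          f"coupling parameter given")
    coupling = float(model_block["R"] if has_R else model_block["K"])

    grid_block = dict(raw.get("grid") or {})
    _check_keys(grid_block, _GRID_KEYS, "grid")
    if "z_extent" not in grid_block or "t_end" not in grid_block:
        raise ConfigError("[grid] must give z_extent and t_end")
    grid = GridSpec(**grid_block)

    fhn_block = dict(raw.get("fhn") or {})
    _check_keys(fhn_block, _FHN_KEYS, "fhn")
    fhn = FHNParams(**fhn_block)

    stim_block = dict(raw.get("stimulus") or {})
    _check_keys(stim_block, _STIM_KEYS, "stimulus")
    given = [k for k in ("pairs", "train", "events") if k in stim_block]
    if len(given) != 1:
        raise ConfigError(
            "[stimulus] must give exactly one of pairs, train or events")
    if "events" in stim_block:
        # fully resolved protocol echo (as written by RunConfig.to_dict or a
        # result archive); round-trips losslessly
        protocol = StimulusProtocol.from_json(json.dumps(stim_block))
    elif "pairs" in stim_block:
        protocol = impulse_protocol(stim_block["pairs"],
                                    n_lateral=grid.n_lateral)
    else:
        train = dict(stim_block["train"] or {})
        _check_keys(train, _TRAIN_KEYS, "stimulus.train")
        protocol = poisson_train_protocol(grid.n_lateral, **train)

    out_block = dict(raw.get("output") or {})
    _check_keys(out_block, _OUTPUT_KEYS, "output")
    seed = raw.get("seed")
    return RunConfig(model=model, coupling=coupling, grid=grid, fhn=fhn,
                     protocol=protocol, store_w=bool(out_block.get("store_w", False)),
                     out_path=out_block.get("path"),
                     seed=None if seed is None else int(seed))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def run_config(config: RunConfig) -> SimulationResult:
    """Execute the simulation a config describes."""
    log.info("run %s %s=%.4g grid=%dx%d t_end=%g hash=%s",
             config.model, "R" if config.model == "discrete" else "K",
             config.coupling, config.grid.n_lateral, config.grid.n_z,
             config.grid.t_end, config.config_hash())
    if config.model == "discrete":
        cond = build_coupling_matrix(config.grid.n_lateral,
                                     config.coupling).condition_number()
        log.info("coupling matrix condition number: %.3f", cond)
    sim = simulate_discrete if config.model == "discrete" else simulate_continuum
    t0 = time.perf_counter()
    result = sim(config.grid, config.coupling, config.fhn, config.protocol,
                 store_w=config.store_w, seed=config.seed)
    elapsed = time.perf_counter() - t0
    log.info("wall time: %.1f s (%.0f ms per 1000 steps)", elapsed,
             1000.0 * elapsed / max(config.grid.n_steps, 1) * 1000.0)
    return result


# ---------------------------------------------------------------------------
# HDF5 archives


def save_result(result: SimulationResult, path) -> None:
    """Write a result archive: /times, /v, optional /w, full provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=result.times)
        fh.create_dataset("v", data=result.v)
        if result.w is not None:
            fh.create_dataset("w", data=result.w)
        fh.attrs["model"] = result.model
        fh.attrs["coupling"] = result.coupling
        fh.attrs["coupling_name"] = result.coupling_name
        fh.attrs["grid"] = json.dumps(asdict(result.grid))
        fh.attrs["fhn"] = json.dumps(asdict(result.fhn))
        fh.attrs["protocol"] = result.protocol.to_json()
        fh.attrs["version"] = __version__
        if result.seed is not None:
            fh.attrs["seed"] = int(result.seed)
        if result.model == "discrete":
            # coupling-operator provenance: A is determined by (n, R, D);
            # alpha is stored dense
            cm = build_coupling_matrix(result.grid.n_lateral, result.coupling)
            grp = fh.create_group("coupling")
            grp.attrs["n"] = cm.n
            grp.attrs["R"] = cm.R
            grp.attrs["A_diagonal"] = cm.D
            grp.attrs["A_off_diagonal"] = 1.0
            grp.create_dataset("alpha", data=cm.alpha)


def load_result(path) -> SimulationResult:
    """Invert :func:`save_result` losslessly."""
    with h5py.File(path, "r") as fh:
        grid = GridSpec(**json.loads(fh.attrs["grid"]))
        fhn = FHNParams(**json.loads(fh.attrs["fhn"]))
        protocol = StimulusProtocol.from_json(fh.attrs["protocol"])
        return SimulationResult(
            times=fh["times"][...],
            v=fh["v"][...],
            w=fh["w"][...] if "w" in fh else None,
            model=str(fh.attrs["model"]),
            coupling=float(fh.attrs["coupling"]),
            grid=grid,
            fhn=fhn,
            protocol=protocol,
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
        )


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic synthetic analysis inputs with embedded ground truth.

    Kinds
    -----
    ``trace_with_spikes``
        Rest-level trace with FHN-like pulse templates inserted at known
        times; ground truth: the threshold-crossing times.
    ``raster_uniform``
        Evenly spaced spike times at every node of a small raster;
        ground truth: the interval.
    ``snapshot_sinusoid``
        Single lateral Fourier mode injected on a quiet field; ground
        truth: the mode index.

    Returns ``(data, ground_truth)``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "trace_with_spikes":
        t_end = params.get("t_end", 200.0)
        dt = params.get("dt", 1.0)
        spike_times = params.get("spike_times", (50.0, 120.0))
        rest = params.get("rest", -1.0328)
        times = np.arange(0.0, t_end + dt / 2, dt)
        trace = np.full_like(times, rest)
        # stylized action potential: fast upstroke to ~1.8, slow decay
        for t0 in spike_times:
            tau = times - t0
            pulse = np.where((tau >= 0) & (tau < 12.0),
                             2.8 * np.exp(-tau / 6.0), 0.0)
            trace = trace + pulse
        trace = trace + params.get("noise", 0.0) * rng.standard_normal(len(times))
        return {"times": times, "trace": trace}, {"spike_times": np.asarray(spike_times)}
    if kind == "raster_uniform":
        from .analysis import SpikeRaster

        interval = params.get("interval", 10.0)
        n_lateral = params.get("n_lateral", 5)
        n_spikes = params.get("n_spikes", 6)
        stations = np.asarray(params.get("z_stations", [10.0, 50.0, 90.0]))
        spikes = {
            (p, z): np.arange(n_spikes) * interval + 3.0
            for p in range(1, n_lateral + 1)
            for z in stations
        }
        raster = SpikeRaster(spikes=spikes, threshold=0.0, refractory=5.0,
                             z_stations=stations, n_lateral=n_lateral)
        return raster, {"interval": interval}
    if kind == "snapshot_sinusoid":
        n_lateral = params.get("n_lateral", 50)
        n_z = params.get("n_z", 101)
        mode = params.get("mode", 3)
        x = np.arange(n_lateral)
        snap = np.tile(np.cos(2 * np.pi * mode * x / n_lateral)[:, None],
                       (1, n_z))
        return snap, {"mode": mode}
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# parameter scans


def scan(values, base: RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the base scenario per coupling value and classify each regime.

    Returns a table with columns ``coupling``, ``label``, ``width``,
    ``low_confidence``, ``status``.  With ``out_dir`` set, each run's
    archive is written to ``<out_dir>/<hash>.h5`` and completed runs
    found on disk are reused rather than re-simulated, so an interrupted
    sweep resumes where it stopped.  A propagation failure at some value
    is recorded and the scan continues.
    """
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for value in values:
        cfg = RunConfig(model=base.model, coupling=float(value),
                        grid=base.grid, fhn=base.fhn, protocol=base.protocol,
                        store_w=base.store_w, out_path=base.out_path,
                        seed=base.seed)
        row = {"coupling": float(value), "label": None, "width": None,
               "low_confidence": None, "status": "ok"}
        try:
            result = None
            if out_dir is not None:
                cache = out_dir / f"{cfg.config_hash()}.h5"
                if cache.exists():
                    result = load_result(cache)
            if result is None:
                result = run_config(cfg)
                if out_dir is not None:
                    save_result(result, cache)
            label = classify_regime(result)
            row.update(label=str(label), width=label.width,
                       low_confidence=label.low_confidence)
        except PropagationError as exc:
            row["status"] = f"propagation failure: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["coupling", "label", "width",
                                       "low_confidence", "status"])
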