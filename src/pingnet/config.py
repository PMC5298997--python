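"""Configuration files, run manifests and structured result output.

Configs are YAML with three top-level sections -- ``network`` (cell
parameters, circuits, projections), ``stimuli`` (noise, pulses, sinusoids,
epoch schedule) and ``run`` (duration, dt, seed) -- validated strictly:
unknown keys and out-of-range values are rejected with the offending key
named.  Every result directory carries a manifest (full config snapshot
plus the seed registry) sufficient to regenerate the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import CircuitSpec, NetworkSpec, ProjectionSpec, SpikeRaster
from .neurons import GolombAmitaiParams, WangBuzsakiParams
from .stimuli import Epoch, NoiseSpec, PulseSpec, SinusoidSpec, StimulusSet

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "dump_config",
    "write_results",
    "read_raster",
]


@dataclass
class RunConfig:
    """Validated experiment specification: network + stimuli + run settings."""

    network: NetworkSpec
    stimuli: StimulusSet
    duration: float = 1500.0
    dt: float = 0.05
    seed: int = 11
    discard: float = 500.0


@dataclass
class RunManifest:
    """Reproducibility record written alongside every result set."""

    config: dict
    seed: int
    software_version: str
    created: str = ""
    wall_time_s: float = np.nan

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, section: dict, path: str):
    """Instantiate a dataclass from a config mapping, rejecting unknown keys."""
    if not isinstance(section, dict):
        raise ValueError(f"config section '{path}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown key '{path}.{sorted(unknown)[0]}'")
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid value in '{path}': {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML experiment config."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"network", "stimuli", "run"}
    if unknown:
        raise ValueError(f"unknown key '{sorted(unknown)[0]}'")

    net_raw = dict(raw.get("network") or {})
    unknown = set(net_raw) - {"circuits", "projections", "pyramidal", "interneuron"}
    if unknown:
        raise ValueError(f"unknown key 'network.{sorted(unknown)[0]}'")
    circuits = [
        _build(CircuitSpec, c, f"network.circuits[{i}]")
        for i, c in enumerate(net_raw.get("circuits") or [{}])
    ]
    projections = []
    for i, p in enumerate(net_raw.get("projections") or []):
        p = dict(p)
        total_ee = p.pop("total_ee", None)
        total_ei = p.pop("total_ei", None)
        if total_ee is not None:
            keys = {"source", "target"}
            extra = set(p) - keys - {"delay_ms", "p_ee", "p_ei"}
            if extra:
                raise ValueError(
                    f"unknown key 'network.projections[{i}].{sorted(extra)[0]}'")
            src, tgt = p.pop("source"), p.pop("target")
            n_e = circuits[src].n_pyramidal
            projections.append(ProjectionSpec.from_total_conductance(
                src, tgt, total_ee, total_ei, n_source_E=n_e, **p))
        else:
            projections.append(_build(ProjectionSpec, p,
                                      f"network.projections[{i}]"))
    network = NetworkSpec(
        circuits, projections,
        pyramidal_params=_build(GolombAmitaiParams,
                                net_raw.get("pyramidal") or {},
                                "network.pyramidal"),
        interneuron_params=_build(WangBuzsakiParams,
                                  net_raw.get("interneuron") or {},
                                  "network.interneuron"))

    stim_raw = dict(raw.get("stimuli") or {})
    unknown = set(stim_raw) - {"noise", "pulses", "sinusoids", "epochs"}
    if unknown:
        raise ValueError(f"unknown key 'stimuli.{sorted(unknown)[0]}'")
    stimuli = StimulusSet(
        pulses=[_build(PulseSpec, dict(p, times=tuple(p.get("times", ()))),
                       f"stimuli.pulses[{i}]")
                for i, p in enumerate(stim_raw.get("pulses") or [])],
        noise=[_build(NoiseSpec, n, f"stimuli.noise[{i}]")
               for i, n in enumerate(stim_raw.get("noise") or [])],
        sinusoids=[_build(SinusoidSpec, s, f"stimuli.sinusoids[{i}]")
                   for i, s in enumerate(stim_raw.get("sinusoids") or [])],
        epochs=[_build(Epoch, e, f"stimuli.epochs[{i}]")
                for i, e in enumerate(stim_raw.get("epochs") or [])])

    run_raw = dict(raw.get("run") or {})
    unknown = set(run_raw) - {"duration", "dt", "seed", "discard"}
    if unknown:
        raise ValueError(f"unknown key 'run.{sorted(unknown)[0]}'")
    return RunConfig(network, stimuli, **run_raw)


def dump_config(cfg: RunConfig) -> dict:
    """Config as a plain dict; ``config_from_dict`` inverts it exactly."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {(list(k) if isinstance(k, tuple) else k): clean(v)
                    for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    net = cfg.network
    return {
        "network": {
            "circuits": [
                {k: clean(v) for k, v in dataclasses.asdict(c).items()
                 if k != "connection_table"}
                | {"connection_table": {f"{a}->{b}": list(v) for (a, b), v
                                        in c.connection_table.items()}}
                for c in net.circuits],
            "projections": [clean(p) for p in net.projections],
            "pyramidal": {k: clean(v) for k, v in
                          dataclasses.asdict(net.pyramidal_params).items()},
            "interneuron": {k: clean(v) for k, v in
                            dataclasses.asdict(net.interneuron_params).items()},
        },
        "stimuli": {
            "pulses": [clean(p) for p in cfg.stimuli.pulses],
            "noise": [clean(n) for n in cfg.stimuli.noise],
            "sinusoids": [clean(s) for s in cfg.stimuli.sinusoids],
            "epochs": [clean(e) for e in cfg.stimuli.epochs],
        },
        "run": {"duration": cfg.duration, "dt": cfg.dt, "seed": cfg.seed,
                "discard": cfg.discard},
    }


def write_results(out_dir: str | Path, raster: SpikeRaster | None = None,
                  traces: pd.DataFrame | None = None,
                  tables: dict[str, pd.DataFrame] | None = None,
                  manifest: RunManifest | None = None) -> list[Path]:
    """Write rasters (two-column text), trace/sweep tables (CSV with units
    in headers) and the manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if raster is not None:
        p = out / "spikes.txt"
        with open(p, "w") as fh:
            for label, sl in raster.populations.items():
                fh.write(f"# population {label} {sl.start} {sl.stop}\n")
            fh.write("# time_ms neuron_id\n")
            for t, i in zip(raster.times, raster.ids):
                fh.write(f"{t:.2f} {i}\n")
        written.append(p)
    if traces is not None:
        p = out / "traces.csv"
        traces.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    if manifest is not None:
        if not manifest.created:
            manifest.created = datetime.datetime.now().isoformat(timespec="seconds")
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest.to_dict(), indent=2, default=str))
        written.append(p)
    return written


def read_raster(path: str | Path) -> SpikeRaster:
    """Re-read a two-column spike file written by :func:`write_results`."""
    populations = {}
    times, ids = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# population"):
            _, _, label, a, b = line.split()
            populations[label] = slice(int(a), int(b))
        elif line.startswith("#") or not line.strip():
            continue
        else:
            t, i = line.split()
            times.append(float(t))
            ids.append(int(i))
    times = np.asarray(times)
    ids = np.asarray(ids, dtype=np.int32)
    duration = float(times.max()) if times.size else 0.0
    return SpikeRaster(times, ids, populations, duration, 0.05)
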