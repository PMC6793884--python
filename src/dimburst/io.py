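"""Run configuration, trajectory files, and provenance.

Snapshots are stored as JSON-lines (one object per line, streamable and
appendable mid-run) with a header line carrying the engine kind, the full
run configuration and the seed, so every output file can be re-run
bit-for-bit.  Density-field snapshots go to an HDF5 container instead
(one dataset per snapshot with a time attribute).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .adaptive import ADConfig, ADTrajectory
from .equilibrium import Cluster, Community
from .ibs import IBSConfig, IBSTrajectory
from .model import ModelParams
from .pde import DensityField, PDEConfig

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_fields",
    "read_fields",
]

_ENGINES = ("ad", "ibs", "pde")
_ENGINE_CONFIG = {"ad": ADConfig, "ibs": IBSConfig, "pde": PDEConfig}


@dataclass(frozen=True)
class RunConfig:
    """A complete, validated description of one simulation run."""

    model: ModelParams
    engine: str
    ad: ADConfig | None = None
    ibs: IBSConfig | None = None
    pde: PDEConfig | None = None
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in _ENGINES:
            raise ValueError(f"engine must be one of {_ENGINES}, got {self.engine!r}")
        if getattr(self, self.engine) is None:
            object.__setattr__(
                self, self.engine, _ENGINE_CONFIG[self.engine](seed=self.seed)
                if self.engine != "pde"
                else PDEConfig()
            )

    @property
    def engine_config(self):
        return getattr(self, self.engine)


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"{context}: unknown field(s) {sorted(unknown)}; "
            f"known fields: {sorted(known)}"
        )
    coerced = {}
    for name, value in data.items():
        if name == "extent" and isinstance(value, (list, tuple)):
            value = tuple(value)
        coerced[name] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration.

    Unknown fields and out-of-range values are rejected with field-level
    messages; omitted fields fall back to the package defaults (the
    five-dimensional reference parameter set).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    engine = data.pop("engine", "ad")
    seed = data.pop("seed", 0)
    out = data.pop("out", None)
    model = _build(ModelParams, data.pop("model", {}), "model")
    blocks = {}
    for name, cls in _ENGINE_CONFIG.items():
        if name in data:
            block = dict(data.pop(name))
            if name != "pde":
                block.setdefault("seed", seed)
            blocks[name] = _build(cls, block, name)
    if data:
        raise ValueError(
            f"{path}: unknown top-level field(s) {sorted(data)}"
        )
    return RunConfig(model=model, engine=engine, seed=seed, out=out, **blocks)


def _config_dict(cfg: RunConfig) -> dict:
    out: dict = {
        "engine": cfg.engine,
        "seed": cfg.seed,
        "model": dataclasses.asdict(cfg.model),
    }
    if cfg.out is not None:
        out["out"] = cfg.out
    block = cfg.engine_config
    if block is not None:
        d = dataclasses.asdict(block)
        if "extent" in d:
            d["extent"] = list(d["extent"])
        out[cfg.engine] = d
    return out


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))


# ---------------------------------------------------------------------------
# trajectory files (JSON-lines)


def write_trajectory(path, trajectory, config: RunConfig | None = None) -> None:
    """Write an AD or IBS trajectory as JSON-lines with a header record."""
    if isinstance(trajectory, ADTrajectory):
        engine = "ad"
    elif isinstance(trajectory, IBSTrajectory):
        engine = "ibs"
    else:
        raise TypeError(f"cannot serialize {type(trajectory).__name__}")
    with open(path, "w") as fh:
        header = {"kind": "header", "engine": engine, "schema": 1}
        if config is not None:
            header["config"] = _config_dict(config)
        if engine == "ibs":
            header["status"] = trajectory.status
        fh.write(json.dumps(header) + "\n")
        if engine == "ad":
            rows = [
                ("snapshot", t, c) for t, c in trajectory.snapshots
            ] + [("event", t, (kind, detail)) for t, kind, detail in trajectory.events]
            rows.sort(key=lambda r: (r[1], 0 if r[0] == "snapshot" else 1))
            for kind, t, payload in rows:
                if kind == "snapshot":
                    fh.write(json.dumps({
                        "kind": "snapshot", "t": t,
                        "clusters": [
                            {"x": c.phenotype.tolist(), "N": c.population}
                            for c in payload.clusters
                        ],
                    }) + "\n")
                else:
                    fh.write(json.dumps({
                        "kind": "event", "t": t,
                        "event": payload[0], "detail": payload[1],
                    }) + "\n")
        else:
            for t, X in trajectory.snapshots:
                fh.write(json.dumps({
                    "kind": "snapshot", "t": t, "individuals": X.tolist(),
                }) + "\n")


def read_trajectory(path, params: ModelParams | None = None):
    """Read a trajectory file back; returns ``(trajectory, header)``.

    A truncated final line is reported with a warning and the valid prefix
    is returned.  The header records which engine produced the file.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = json.loads(lines[0])
    engine = header.get("engine")
    if params is None and "config" in header:
        params = _build(ModelParams, header["config"].get("model", {}), "model")
    if params is None:
        params = ModelParams()
    records = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            records.append(json.loads(line))
        except json.JSONDecodeError:
            warnings.warn(
                f"{path}: truncated record at line {i}; returning the valid prefix"
            )
            break
    if engine == "ad":
        traj = ADTrajectory()
        for rec in records:
            if rec["kind"] == "snapshot":
                community = Community(
                    [
                        Cluster(np.array(c["x"]), c["N"])
                        for c in rec["clusters"]
                    ],
                    params,
                    rec["t"],
                )
                traj.snapshots.append((rec["t"], community))
            elif rec["kind"] == "event":
                traj.events.append((rec["t"], rec["event"], rec["detail"]))
        return traj, header
    if engine == "ibs":
        traj = IBSTrajectory(status=header.get("status", "completed"))
        for rec in records:
            if rec["kind"] == "snapshot":
                traj.snapshots.append(
                    (rec["t"], np.array(rec["individuals"], dtype=float).reshape(-1, params.d_max)
                     if rec["individuals"] else np.empty((0, params.d_max)))
                )
        return traj, header
    raise ValueError(f"{path}: unknown engine {engine!r} in header")


# ---------------------------------------------------------------------------
# density-field files (HDF5)


def write_fields(path, fields: list[DensityField], config: RunConfig | None = None) -> None:
    """Store density-field snapshots in one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["engine"] = "pde"
        if config is not None:
            fh.attrs["config"] = json.dumps(_config_dict(config))
        xs, ys = fields[0].coords
        fh.create_dataset("x1", data=xs)
        fh.create_dataset("x2", data=ys)
        for k, fld in enumerate(fields):
            ds = fh.create_dataset(f"phi_{k:05d}", data=fld.phi)
            ds.attrs["time"] = fld.time
            ds.attrs["clip_events"] = fld.clip_events


def read_fields(path) -> list[DensityField]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        xs = fh["x1"][:]
        ys = fh["x2"][:]
        keys = sorted(k for k in fh if k.startswith("phi_"))
        for k in keys:
            ds = fh[k]
            out.append(
                DensityField(
                    ds[:], (xs, ys), float(ds.attrs["time"]),
                    int(ds.attrs.get("clip_events", 0)),
                )
            )
    return out
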