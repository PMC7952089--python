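"""Text-format trajectory I/O, flat config files, and run manifests.

Trajectories are exchanged as LAMMPS-style dump text (columns
``id type x y z``, box bounds per frame) or XYZ.  Neither format carries
chain topology, so readers accept an optional ``topology`` — a sequence
of (species, chain_length) tuples in bead order — to reconstruct
polymer identities; without it every bead is treated as its own polymer,
which is sufficient for density profiles and coexistence extraction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import UsageError
from .simulate import Configuration, SimulationSpec, Trajectory
from .theory import TheoryParams

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "load_config",
    "save_config",
    "RunManifest",
]

_SPECIES_TO_TYPE = {0: 1, 1: 2}
_TYPE_TO_SPECIES = {1: 0, 2: 1}
_SPECIES_TO_SYMBOL = {0: "A", 1: "B"}
_SYMBOL_TO_SPECIES = {"A": 0, "B": 1}


def _topology_arrays(n_beads: int, topology):
    if topology is None:
        return (
            np.arange(n_beads, dtype=np.int64),
            np.zeros(n_beads, dtype=np.int64),
        )
    pid = np.empty(n_beads, dtype=np.int64)
    cidx = np.empty(n_beads, dtype=np.int64)
    k = 0
    for chain_id, (_, length) in enumerate(topology):
        if k + length > n_beads:
            raise UsageError("topology describes more beads than the frame holds")
        pid[k : k + length] = chain_id
        cidx[k : k + length] = np.arange(length)
        k += length
    if k != n_beads:
        raise UsageError("topology does not cover all beads")
    return pid, cidx


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

def _write_dump_frame(fh, time: float, config: Configuration):
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{time:.10g}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{config.n_beads}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for d in range(3):
        fh.write(f"0 {config.box[d]:.10g}\n")
    fh.write("ITEM: ATOMS id type x y z\n")
    for i in range(config.n_beads):
        x, y, z = config.positions[i]
        fh.write(
            f"{i + 1} {_SPECIES_TO_TYPE[int(config.species[i])]} "
            f"{x:.8g} {y:.8g} {z:.8g}\n"
        )


def _read_dump(path: Path, topology) -> Trajectory:
    traj = Trajectory()
    lines = path.read_text().splitlines()
    i = 0
    n_total = len(lines)
    frame_no = 0
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        start_line = i + 1
        try:
            if not lines[i].startswith("ITEM: TIMESTEP"):
                raise UsageError(
                    f"line {i + 1}: expected 'ITEM: TIMESTEP', got {lines[i]!r}"
                )
            t = float(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise UsageError(f"line {i + 3}: expected 'ITEM: NUMBER OF ATOMS'")
            n = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise UsageError(f"line {i + 5}: expected 'ITEM: BOX BOUNDS'")
            box = np.empty(3)
            for d in range(3):
                lo, hi = map(float, lines[i + 5 + d].split()[:2])
                box[d] = hi - lo
            header = lines[i + 8]
            if not header.startswith("ITEM: ATOMS"):
                raise UsageError(f"line {i + 9}: expected 'ITEM: ATOMS'")
            cols = header.split()[2:]
            if cols[:5] != ["id", "type", "x", "y", "z"]:
                raise UsageError(
                    f"line {i + 9}: unsupported column layout {cols!r}"
                )
            body = lines[i + 9 : i + 9 + n]
            if len(body) < n:
                raise UsageError("truncated frame")
            ids = np.empty(n, dtype=np.int64)
            types = np.empty(n, dtype=np.int64)
            pos = np.empty((n, 3))
            for k, ln in enumerate(body):
                parts = ln.split()
                if len(parts) != 5:
                    raise UsageError(
                        f"line {i + 10 + k}: expected 5 columns, got {len(parts)}"
                    )
                ids[k] = int(parts[0])
                types[k] = int(parts[1])
                pos[k] = [float(parts[2]), float(parts[3]), float(parts[4])]
            order = np.argsort(ids, kind="stable")
            ids, types, pos = ids[order], types[order], pos[order]
            species = np.array(
                [_TYPE_TO_SPECIES.get(int(tp), 1) for tp in types], dtype=np.int8
            )
            pid, cidx = _topology_arrays(n, topology)
            traj.append(
                t, Configuration(pos, species, pid, cidx, box)
            )
            frame_no += 1
            i += 9 + n
        except (ValueError, IndexError, UsageError) as exc:
            raise UsageError(
                f"malformed dump frame starting at line {start_line} "
                f"(last complete frame: {frame_no}): {exc}"
            ) from exc
    return traj


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _write_xyz_frame(fh, time: float, config: Configuration):
    fh.write(f"{config.n_beads}\n")
    bx, by, bz = config.box
    fh.write(f"time={time:.10g} box={bx:.10g},{by:.10g},{bz:.10g}\n")
    for i in range(config.n_beads):
        x, y, z = config.positions[i]
        fh.write(
            f"{_SPECIES_TO_SYMBOL[int(config.species[i])]} "
            f"{x:.8g} {y:.8g} {z:.8g}\n"
        )


def _read_xyz(path: Path, topology) -> Trajectory:
    traj = Trajectory()
    lines = path.read_text().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        start_line = i + 1
        try:
            n = int(lines[i])
            comment = lines[i + 1]
            meta = dict(
                kv.split("=", 1) for kv in comment.split() if "=" in kv
            )
            t = float(meta.get("time", frame_no))
            box = np.array(
                [float(v) for v in meta["box"].split(",")]
                if "box" in meta
                else [np.inf] * 3
            )
            body = lines[i + 2 : i + 2 + n]
            if len(body) < n:
                raise UsageError("truncated frame")
            species = np.empty(n, dtype=np.int8)
            pos = np.empty((n, 3))
            for k, ln in enumerate(body):
                parts = ln.split()
                if len(parts) != 4:
                    raise UsageError(
                        f"line {i + 3 + k}: expected 4 columns, got {len(parts)}"
                    )
                species[k] = _SYMBOL_TO_SPECIES.get(parts[0], 1)
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            pid, cidx = _topology_arrays(n, topology)
            traj.append(t, Configuration(pos, species, pid, cidx, box))
            frame_no += 1
            i += 2 + n
        except (ValueError, IndexError, KeyError, UsageError) as exc:
            raise UsageError(
                f"malformed xyz frame starting at line {start_line} "
                f"(last complete frame: {frame_no}): {exc}"
            ) from exc
    return traj


def read_trajectory(
    path: str | Path, format: str = "lammps_dump", topology=None
) -> Trajectory:
    """Read a text trajectory; frames re-sorted by atom id."""
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    if format == "lammps_dump":
        return _read_dump(path, topology)
    if format == "xyz":
        return _read_xyz(path, topology)
    raise UsageError(f"unknown trajectory format {format!r}")


def write_trajectory(
    traj: Trajectory | Iterable[tuple[float, Configuration]],
    path: str | Path,
    format: str = "lammps_dump",
):
    """Write frames incrementally (works for generators of frames)."""
    if format not in ("lammps_dump", "xyz"):
        raise UsageError(f"unknown trajectory format {format!r}")
    writer = _write_dump_frame if format == "lammps_dump" else _write_xyz_frame
    frames = traj if not isinstance(traj, Trajectory) else zip(traj.times, traj.frames)
    with open(path, "w") as fh:
        for t, config in frames:
            writer(fh, t, config)


# ---------------------------------------------------------------------------
# flat key-value configs
# ---------------------------------------------------------------------------

_BOOLS = {"true": True, "false": False, "1": True, "0": False}


def _parse_kv(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UsageError(f"{path}:{ln_no}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in out:
            raise UsageError(f"{path}:{ln_no}: duplicate key {key!r}")
        out[key] = value
    return out


def _coerce(cls, raw: dict[str, str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise UsageError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    required = {
        f.name
        for f in fields.values()
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(raw)
    if missing:
        raise UsageError(f"missing required keys: {sorted(missing)}")
    kwargs = {}
    for key, value in raw.items():
        ftype = fields[key].type
        if "int" in str(ftype) and "tuple" not in str(ftype):
            kwargs[key] = int(value)
        elif "float" in str(ftype) and "tuple" not in str(ftype):
            kwargs[key] = float(value) if value.lower() != "none" else None
        elif "tuple" in str(ftype):
            kwargs[key] = tuple(float(v) for v in value.replace(",", " ").split())
        elif "bool" in str(ftype):
            kwargs[key] = _BOOLS[value.lower()]
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> SimulationSpec | TheoryParams:
    """Load a flat key-value file as a SimulationSpec or TheoryParams.

    The target type is inferred from the keys present (``valence_A`` vs
    ``L1``); unknown and duplicate keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    raw = _parse_kv(path)
    if "L1" in raw or "Kd" in raw:
        return _coerce(TheoryParams, raw)
    return _coerce(SimulationSpec, raw)


def save_config(obj: SimulationSpec | TheoryParams, path: str | Path):
    lines = []
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        if value is None:
            continue
        if isinstance(value, tuple):
            value = " ".join(f"{v:.10g}" for v in value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI invocation, sufficient to re-run it."""

    command: str
    parameters: dict
    seed: int | None
    code_version: str
    timestamp: str
    input_digests: dict
    output_digests: dict

    @classmethod
    def create(cls, command, parameters, seed, inputs=(), outputs=()):
        from . import __version__

        return cls(
            command=command,
            parameters=parameters,
            seed=seed,
            code_version=__version__,
            timestamp=_time.strftime("%Y-%m-%dT%H:%M:%S"),
            input_digests={str(p): _digest(Path(p)) for p in inputs},
            output_digests={str(p): _digest(Path(p)) for p in outputs},
        )

    def write(self, path: str | Path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
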