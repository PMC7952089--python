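"""Coarse-grained Langevin dynamics of two-component sticker polymers.

Polymers are linear bead-spring chains; every bead is one sticker.
Opposite species attract through a short-ranged well (depth ``U0``),
identical species repel over at least twice the attraction range, which
geometrically enforces one-to-one binding.  Dynamics are integrated with
the BAOAB splitting of the Langevin equation.

Units: lengths nm, energies k_BT, mass 1, time reduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np

from . import potentials
from ._kernels import count_double_occupancy, forces_energy
from .errors import IntegrationBlowUpError, PackingError, UsageError

__all__ = [
    "SimulationSpec",
    "Configuration",
    "Trajectory",
    "pair_potential",
    "build_system",
    "run_langevin",
    "total_energy",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a simulated system.

    ``valence_A`` / ``valence_B`` are the sticker counts per chain,
    ``U0`` the attraction depth in k_BT.  Temperature is fixed at 1.
    """

    valence_A: int
    valence_B: int
    count_A: int
    count_B: int
    box: tuple[float, float, float]
    U0: float
    sticker_diameter: float = potentials.STICKER_DIAMETER
    mean_linker_length: float = potentials.MEAN_LINKER_LENGTH
    bond_stiffness: float = 2.0
    friction: float = 1.0
    timestep: float = 0.0  # 0 -> auto: bond period / 50
    temperature: float = 1.0
    seed: int = 0
    init_mode: Literal["slab", "uniform", "planted"] = "uniform"
    attraction_range: float = potentials.ATTRACTION_RANGE
    repulsion_strength: float | None = None

    def __post_init__(self):
        if min(self.valence_A, self.valence_B) < 1:
            raise UsageError("valences must be >= 1")
        if min(self.count_A, self.count_B) < 0 or self.count_A + self.count_B < 1:
            raise UsageError("need at least one polymer")
        cutoff = max(self.attraction_range, self.repulsion_range)
        if min(self.box) <= 2.0 * cutoff:
            raise UsageError(
                f"box lengths must exceed 2 x interaction cutoff ({2 * cutoff:.2f} nm)"
            )
        if self.dt <= 0:
            raise UsageError("timestep must be positive")

    @property
    def repulsion_range(self) -> float:
        return potentials.repulsion_range(self.sticker_diameter)

    @property
    def repulsion_amplitude(self) -> float:
        if self.repulsion_strength is not None:
            return self.repulsion_strength
        return potentials.repulsion_strength(self.U0)

    @property
    def bond_period(self) -> float:
        return 2.0 * math.pi / math.sqrt(self.bond_stiffness)

    @property
    def dt(self) -> float:
        return self.timestep if self.timestep > 0 else self.bond_period / 50.0

    @property
    def n_beads(self) -> int:
        return self.count_A * self.valence_A + self.count_B * self.valence_B

    def metadata(self) -> dict:
        """Chosen numerical parameters, for run manifests."""
        return {
            "timestep": self.dt,
            "friction": self.friction,
            "bond_period": self.bond_period,
            "attraction_range": self.attraction_range,
            "repulsion_range": self.repulsion_range,
            "repulsion_amplitude": self.repulsion_amplitude,
        }


@dataclass
class Configuration:
    """Instantaneous system state."""

    positions: np.ndarray  # (N, 3) nm, wrapped into the box
    species: np.ndarray  # (N,) 0 = A, 1 = B
    polymer_id: np.ndarray  # (N,)
    chain_index: np.ndarray  # (N,) index of the bead within its chain
    box: np.ndarray  # (3,)
    periodic: tuple[bool, bool, bool] = (True, True, True)
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.species = np.asarray(self.species, dtype=np.int8)
        self.polymer_id = np.asarray(self.polymer_id, dtype=np.int64)
        self.chain_index = np.asarray(self.chain_index, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if not np.all(np.isfinite(self.positions)):
            raise UsageError("positions must be finite")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bonds(self) -> np.ndarray:
        """Backbone bond index pairs (consecutive beads of one chain)."""
        order = np.lexsort((self.chain_index, self.polymer_id))
        pid = self.polymer_id[order]
        cidx = self.chain_index[order]
        same = (pid[1:] == pid[:-1]) & (cidx[1:] == cidx[:-1] + 1)
        return np.column_stack([order[:-1][same], order[1:][same]]).astype(np.int64)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.species.copy(),
            self.polymer_id.copy(),
            self.chain_index.copy(),
            self.box.copy(),
            self.periodic,
            None if self.velocities is None else self.velocities.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered configurations at a fixed recording stride."""

    times: list[float] = field(default_factory=list)
    frames: list[Configuration] = field(default_factory=list)
    stride: int = 1
    metadata: dict = field(default_factory=dict)

    def append(self, time: float, config: Configuration):
        if self.times and time <= self.times[-1]:
            raise UsageError("frame times must be strictly increasing")
        if self.frames and config.n_beads != self.frames[0].n_beads:
            raise UsageError("bead count must be constant along a trajectory")
        self.times.append(time)
        self.frames.append(config)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[float, Configuration]]:
        return iter(zip(self.times, self.frames))


def pair_potential(r: float, kind: str, spec: SimulationSpec) -> float:
    """Pair energy in k_BT at separation ``r`` (nm)."""
    if np.any(np.asarray(r) < 0):
        raise UsageError("separation must be >= 0")
    if kind == "cross_attract":
        return potentials.cross_attract(r, spec.U0, spec.attraction_range)
    if kind == "same_repel":
        return potentials.same_repel(
            r, spec.repulsion_amplitude, spec.repulsion_range
        )
    if kind == "harmonic_bond":
        return potentials.harmonic_bond(
            r, spec.bond_stiffness, spec.mean_linker_length
        )
    raise UsageError(f"unknown interaction kind {kind!r}")


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _random_chain(rng, start, n_beads, r0):
    """Random walk with fixed step length r0."""
    steps = rng.normal(size=(n_beads - 1, 3))
    steps /= np.linalg.norm(steps, axis=1)[:, None]
    return start + np.vstack([np.zeros(3), np.cumsum(steps * r0, axis=0)])


def _min_image_dist2(delta, box):
    delta = delta - box * np.rint(delta / box)
    return np.einsum("...i,...i->...", delta, delta)


def build_system(spec: SimulationSpec, seed: int | None = None) -> Configuration:
    """Place polymers according to ``spec.init_mode``.

    slab    -- chain centres uniform in the middle third of the x axis
    uniform -- chain centres uniform in the whole box
    planted -- deterministic straight chains along +x, used by fixtures

    Same-species beads are kept at least one sticker diameter apart
    (rejection sampling); persistent failure raises ``PackingError``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    box = np.asarray(spec.box, dtype=float)
    r0 = spec.mean_linker_length
    core = spec.sticker_diameter

    chains = [(0, spec.valence_A)] * spec.count_A + [(1, spec.valence_B)] * spec.count_B

    positions, species, polymer_id, chain_index = [], [], [], []
    placed_by_species = {0: [], 1: []}

    if spec.init_mode == "planted":
        gap = 2.0 * spec.repulsion_range
        for cid, (sp, L) in enumerate(chains):
            start = np.array([0.0, cid * gap, 0.0])
            coords = start + np.outer(np.arange(L), np.array([r0, 0.0, 0.0]))
            positions.append(coords)
            species.extend([sp] * L)
            polymer_id.extend([cid] * L)
            chain_index.extend(range(L))
        pos = np.vstack(positions) % box
        return Configuration(
            pos,
            np.array(species),
            np.array(polymer_id),
            np.array(chain_index),
            box,
        )

    if spec.init_mode not in ("slab", "uniform"):
        raise UsageError(f"unknown init mode {spec.init_mode!r}")

    for cid, (sp, L) in enumerate(chains):
        ok = False
        for _ in range(500):
            centre = rng.uniform(0.0, 1.0, 3) * box
            if spec.init_mode == "slab":
                centre[0] = box[0] / 2.0 + (rng.uniform() - 0.5) * box[0] / 3.0
            coords = _random_chain(rng, np.zeros(3), L, r0)
            coords += centre - coords.mean(axis=0)
            if spec.init_mode == "slab":
                # keep the centre criterion exact under later wrapping
                if abs(coords.mean(axis=0)[0] - box[0] / 2.0) >= box[0] / 6.0:
                    continue
            same = placed_by_species[sp]
            if same:
                prev = np.vstack(same)
                d2 = _min_image_dist2(coords[:, None, :] - prev[None, :, :], box)
                if d2.min() < core * core:
                    continue
            # also enforce the core within the new chain (non-adjacent beads)
            if L > 2:
                d2self = _min_image_dist2(
                    coords[:, None, :] - coords[None, :, :], box
                )
                iu = np.triu_indices(L, k=2)
                if d2self[iu].min() < core * core:
                    continue
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place chain {cid} without same-species core overlap"
            )
        placed_by_species[sp].append(coords)
        positions.append(coords)
        species.extend([sp] * L)
        polymer_id.extend([cid] * L)
        chain_index.extend(range(L))

    pos = np.vstack(positions) % box
    return Configuration(
        pos, np.array(species), np.array(polymer_id), np.array(chain_index), box
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _kernel_args(config: Configuration, spec: SimulationSpec):
    return (
        config.species,
        config.bonds(),
        config.box,
        spec.U0,
        spec.attraction_range,
        spec.repulsion_amplitude,
        spec.repulsion_range,
        spec.bond_stiffness,
        spec.mean_linker_length,
    )


def total_energy(config: Configuration, spec: SimulationSpec) -> float:
    """Potential energy (bonds + pairs, minimum image), k_BT."""
    sp_, bonds, box, *rest = _kernel_args(config, spec)
    _, energy = forces_energy(config.positions, sp_, bonds, box, *rest)
    return float(energy)


def run_langevin(
    config: Configuration,
    spec: SimulationSpec,
    n_steps: int,
    seed: int | None = None,
    record_every: int = 100,
    thermostat: bool = True,
) -> Trajectory:
    """Integrate with BAOAB; returns the recorded trajectory.

    With ``thermostat=False`` (and zero friction) the scheme reduces to
    velocity Verlet, which is used by the energy-conservation tests.
    Identical (config, spec, seed) give bit-identical trajectories.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dt = spec.dt
    gamma = spec.friction
    kT = spec.temperature

    sp_, bonds, box, *rest = _kernel_args(config, spec)
    pos = config.positions.copy()
    vel = (
        config.velocities.copy()
        if config.velocities is not None
        else np.zeros_like(pos)
    )

    if thermostat:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(max(0.0, (1.0 - c1 * c1) * kT))
    else:
        c1, c2 = 1.0, 0.0

    forces, _ = forces_energy(pos, sp_, bonds, box, *rest)
    traj = Trajectory(stride=record_every, metadata=spec.metadata())

    def snapshot(t):
        snap = config.copy()
        snap.positions = pos % box
        snap.velocities = vel.copy()
        traj.append(t, snap)

    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * forces
        pos += 0.5 * dt * vel
        if thermostat:
            vel *= c1
            if c2 > 0:
                vel += c2 * rng.standard_normal(vel.shape)
        pos += 0.5 * dt * vel
        forces, _ = forces_energy(pos, sp_, bonds, box, *rest)
        vel += 0.5 * dt * forces
        if not np.all(np.isfinite(pos)) or np.abs(pos).max() > 1e8:
            raise IntegrationBlowUpError(step)
        if step % record_every == 0:
            snapshot(step * dt)

    if n_steps % record_every != 0:
        snapshot(n_steps * dt)
    return traj


def double_occupancy_count(config: Configuration, spec: SimulationSpec) -> int:
    """Number of B stickers with two or more A stickers inside the well."""
    return int(
        count_double_occupancy(
            config.positions, config.species, config.box, spec.attraction_range
        )
    )
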