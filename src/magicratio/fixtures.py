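"""Planted synthetic inputs with known ground truth.

Everything downstream of the simulator (bond detection, clustering,
profiles, coexistence extraction) is testable against these fixtures
without running dynamics.  All fixtures are byte-reproducible from
(spec, seed) and respect the simulator's same-species core constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import potentials
from .analysis import BondPairing, DensityProfile
from .errors import PackingError, UsageError
from .simulate import Configuration, SimulationSpec, build_system

__all__ = [
    "PlantedProfileSpec",
    "PlantedClusterSpec",
    "make_planted_profile",
    "make_planted_clusters",
    "make_dilute_gas",
]


@dataclass(frozen=True)
class PlantedProfileSpec:
    """tanh slab density profile with optional multiplicative noise."""

    c_dilute: float  # mM, total stickers
    c_dense: float  # mM, total stickers
    interface_position: float  # nm, |x| of the interface centre
    interface_width: float  # nm
    box: tuple[float, float, float] = (250.0, 50.0, 50.0)
    bin_width: float = 2.5
    stoich_dilute: float = 1.0  # c_A / c_B on the dilute plateau
    stoich_dense: float = 1.0
    noise_sd: float = 0.0  # relative
    seed: int = 0

    def __post_init__(self):
        if not (self.c_dense >= self.c_dilute >= 0):
            raise UsageError("require c_dense >= c_dilute >= 0")
        if self.interface_width <= 0:
            raise UsageError("interface width must be positive")


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Clusters with prescribed composition and bonding pattern.

    ``compositions`` entries are (n_A_polymers, n_B_polymers, pattern)
    with pattern one of fully_bonded | maximal | none.
    """

    compositions: tuple[tuple[int, int, str], ...]
    valence_A: int
    valence_B: int
    box: tuple[float, float, float] = (250.0, 50.0, 50.0)
    linker_length: float = potentials.MEAN_LINKER_LENGTH
    pair_offset: float = 0.4  # nm, bound-pair separation (inside the well)
    cutoff: float = potentials.ATTRACTION_RANGE
    seed: int = 0


def make_planted_profile(spec: PlantedProfileSpec) -> DensityProfile:
    """Symmetric tanh slab centred at x = 0, plateau values as planted."""
    lx = spec.box[0]
    n_bins = max(1, int(round(lx / spec.bin_width)))
    edges = np.linspace(0.0, lx, n_bins + 1)
    x = 0.5 * (edges[:-1] + edges[1:]) - lx / 2.0

    shape = 0.5 * (
        np.tanh((x + spec.interface_position) / spec.interface_width)
        - np.tanh((x - spec.interface_position) / spec.interface_width)
    )
    total = spec.c_dilute + (spec.c_dense - spec.c_dilute) * shape

    fa_dil = spec.stoich_dilute / (1.0 + spec.stoich_dilute)
    fa_den = spec.stoich_dense / (1.0 + spec.stoich_dense)
    frac_a = fa_dil + (fa_den - fa_dil) * shape
    conc_a = total * frac_a
    conc_b = total * (1.0 - frac_a)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        conc_a = conc_a * (1.0 + spec.noise_sd * rng.standard_normal(n_bins))
        conc_b = conc_b * (1.0 + spec.noise_sd * rng.standard_normal(n_bins))

    return DensityProfile(
        x=x,
        conc_A=conc_a,
        conc_B=conc_b,
        n_frames=1,
        box=np.asarray(spec.box, dtype=float),
    )


def _build_cluster(n_a, n_b, pattern, spec: PlantedClusterSpec):
    """Cluster geometry: A chains end-to-end along x; B beads ride the
    A sticker sequence at a small +y offset (one bond each); leftover B
    beads turn away perpendicular, leftover A beads stay bare."""
    m, n = spec.valence_A, spec.valence_B
    r0 = spec.linker_length
    off = spec.pair_offset
    if pattern not in ("fully_bonded", "maximal", "none"):
        raise UsageError(f"unknown bonding pattern {pattern!r}")
    if pattern == "fully_bonded" and n_a * m != n_b * n:
        raise UsageError(
            f"({n_a}, {n_b}) cannot be fully bonded at valences ({m}, {n})"
        )

    coords, species, chain, cidx = [], [], [], []
    # A chains: global sticker slots 0 .. n_a*m-1 along x
    for k in range(n_a):
        for t in range(m):
            coords.append(((k * m + t) * r0, 0.0, 0.0))
            species.append(0)
            chain.append(k)
            cidx.append(t)
    n_bonds = 0 if pattern == "none" else min(n_a * m, n_b * n)
    pairs = []
    for j in range(n_b):
        prev = None
        for t in range(n):
            slot = j * n + t
            if pattern == "none":
                # detached chain: parallel line far outside the well
                pos = (slot * r0, 2.0 * potentials.repulsion_range(), 0.0)
            elif slot < n_a * m:
                pos = (slot * r0, off, 0.0)
                pairs.append((slot, len(coords)))  # (A slot, local B index)
            else:
                # dangling continuation, perpendicular to the backbone
                pos = (prev[0], prev[1] + r0, 0.0)
            coords.append(pos)
            species.append(1)
            chain.append(n_a + j)
            cidx.append(t)
            prev = pos
    assert len(pairs) == n_bonds
    return np.asarray(coords, float), species, chain, cidx, pairs


def make_planted_clusters(
    spec: PlantedClusterSpec,
) -> tuple[Configuration, BondPairing]:
    """Build all requested clusters, separated by > 2 x cutoff."""
    box = np.asarray(spec.box, dtype=float)
    margin = 2.0 * spec.cutoff + 1.0

    all_pos, all_species, all_chain, all_cidx = [], [], [], []
    truth = []
    chain_offset = 0
    y_cursor = margin
    for n_a, n_b, pattern in spec.compositions:
        coords, species, chain, cidx, pairs = _build_cluster(
            n_a, n_b, pattern, spec
        )
        extent_y = coords[:, 1].max() - coords[:, 1].min()
        coords = coords + np.array([margin, y_cursor, box[2] / 2.0])
        if coords[:, 0].max() > box[0] - margin:
            raise PackingError("cluster does not fit the box along x")
        y_cursor += extent_y + margin
        if y_cursor > box[1]:
            raise PackingError("clusters do not fit the box along y")
        bead_offset = len(all_pos)
        a_slot_to_bead = {}
        k = 0
        for i, sp in enumerate(species):
            if sp == 0:
                a_slot_to_bead[k] = bead_offset + i
                k += 1
        for a_slot, b_local in pairs:
            truth.append((a_slot_to_bead[a_slot], bead_offset + b_local))
        all_pos.extend(coords)
        all_species.extend(species)
        all_chain.extend(c + chain_offset for c in chain)
        all_cidx.extend(cidx)
        chain_offset += n_a + n_b

    config = Configuration(
        np.asarray(all_pos) % box,
        np.asarray(all_species),
        np.asarray(all_chain),
        np.asarray(all_cidx),
        box,
    )
    return config, BondPairing(tuple(sorted(truth)))


def make_dilute_gas(
    valence_A: int,
    valence_B: int,
    count_A: int,
    count_B: int,
    box: tuple[float, float, float],
    seed: int = 0,
    U0: float = 0.0,
) -> Configuration:
    """Uniformly placed, initially unbound chains.

    Rejection sampling additionally keeps every A bead outside the
    attraction well of every B bead so the gas starts bond-free.
    """
    if count_A + count_B == 0:
        return Configuration(
            np.zeros((0, 3)),
            np.zeros(0, dtype=np.int8),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.asarray(box, dtype=float),
        )
    spec = SimulationSpec(
        valence_A=valence_A,
        valence_B=valence_B,
        count_A=count_A,
        count_B=count_B,
        box=tuple(box),
        U0=U0,
        seed=seed,
        init_mode="uniform",
    )
    for attempt in range(50):
        config = build_system(spec, seed=seed + 1000 * attempt)
        a = config.positions[config.species == 0]
        b = config.positions[config.species == 1]
        if len(a) == 0 or len(b) == 0:
            return config
        delta = a[:, None, :] - b[None, :, :]
        delta -= config.box * np.rint(delta / config.box)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        if d2.min() > spec.attraction_range**2:
            return config
    raise PackingError("could not place an unbound gas at this density")
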