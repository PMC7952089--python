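"""Bond, cluster, density-profile and coexistence analysis.

Works on :class:`~magicratio.simulate.Configuration` /
:class:`~magicratio.simulate.Trajectory` objects regardless of whether
they came from the integrator, from a trajectory file, or from the
planted fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import UsageError
from .potentials import ATTRACTION_RANGE
from .simulate import Configuration, Trajectory
from .units import MM_PER_COUNT_PER_NM3

__all__ = [
    "BondPairing",
    "ClusterStats",
    "DensityProfile",
    "CoexistencePoint",
    "detect_bonds",
    "find_clusters",
    "density_profile",
    "extract_coexistence",
    "stickers_to_mM",
    "minimal_fully_bonded_oligomer",
    "unpaired_stickers",
]


@dataclass(frozen=True)
class BondPairing:
    """One-to-one A-B bead pairs (bead indices)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        seen = set()
        for a, b in self.pairs:
            if a in seen or b in seen:
                raise UsageError("a bead appears in more than one bond")
            seen.update((a, b))

    def __len__(self):
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        out = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out


@dataclass(frozen=True)
class Cluster:
    n_polymers_A: int
    n_polymers_B: int
    size_stickers: int
    fully_bonded: bool
    polymer_ids: tuple[int, ...]


@dataclass
class ClusterStats:
    clusters: list[Cluster]
    size_histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.size_histogram:
            for cl in self.clusters:
                self.size_histogram[cl.size_stickers] = (
                    self.size_histogram.get(cl.size_stickers, 0) + 1
                )

    @property
    def total_stickers(self) -> int:
        return sum(cl.size_stickers for cl in self.clusters)

    def modal_composition(self) -> tuple[int, int]:
        """Most common (n_A, n_B) polymer composition over clusters."""
        counts: dict[tuple[int, int], int] = {}
        for cl in self.clusters:
            key = (cl.n_polymers_A, cl.n_polymers_B)
            counts[key] = counts.get(key, 0) + 1
        return max(counts, key=counts.get)


@dataclass
class DensityProfile:
    """Sticker concentrations binned along x, averaged over frames."""

    x: np.ndarray  # bin centres, nm
    conc_A: np.ndarray  # mM
    conc_B: np.ndarray  # mM
    n_frames: int
    box: np.ndarray

    @property
    def conc_total(self) -> np.ndarray:
        return self.conc_A + self.conc_B

    @property
    def bin_width(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else float("nan")


@dataclass(frozen=True)
class CoexistencePoint:
    """Dilute and dense (c_A, c_B) pairs in mM."""

    dilute: tuple[float, float]
    dense: tuple[float, float]

    @property
    def dilute_total(self) -> float:
        return sum(self.dilute)

    @property
    def dense_total(self) -> float:
        return sum(self.dense)


# ---------------------------------------------------------------------------
# bonds and clusters
# ---------------------------------------------------------------------------

def _cross_distances(config: Configuration, cutoff: float):
    pos = config.positions
    a_idx = np.flatnonzero(config.species == 0)
    b_idx = np.flatnonzero(config.species == 1)
    if len(a_idx) == 0 or len(b_idx) == 0:
        return a_idx, b_idx, np.zeros((len(a_idx), len(b_idx)))
    delta = pos[a_idx][:, None, :] - pos[b_idx][None, :, :]
    delta -= config.box * np.rint(delta / config.box)
    return a_idx, b_idx, np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def detect_bonds(
    config: Configuration, cutoff: float = ATTRACTION_RANGE
) -> BondPairing:
    """Greedy one-to-one matching of cross-species pairs within cutoff.

    Candidate pairs are taken in order of increasing distance; ties are
    broken by the lower (A id, B id), so the result is deterministic and
    independent of input ordering.  For well-separated (planted) bonded
    pairs this coincides with minimum-weight matching.
    """
    a_idx, b_idx, dist = _cross_distances(config, cutoff)
    ii, jj = np.nonzero(dist <= cutoff)
    order = np.lexsort((b_idx[jj], a_idx[ii], dist[ii, jj]))
    used_a, used_b = set(), set()
    pairs = []
    for k in order:
        a, b = int(a_idx[ii[k]]), int(b_idx[jj[k]])
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        pairs.append((a, b))
    return BondPairing(tuple(sorted(pairs)))


def find_clusters(config: Configuration, pairing: BondPairing) -> ClusterStats:
    """Polymer-level connected components linked by sticker bonds."""
    n_beads = config.n_beads
    for a, b in pairing.pairs:
        if not (0 <= a < n_beads and 0 <= b < n_beads):
            raise UsageError("pairing references beads outside the configuration")

    g = nx.Graph()
    g.add_nodes_from(np.unique(config.polymer_id).tolist())
    for a, b in pairing.pairs:
        g.add_edge(int(config.polymer_id[a]), int(config.polymer_id[b]))

    bonded_beads = {x for pair in pairing.pairs for x in pair}
    clusters = []
    for comp in nx.connected_components(g):
        members = np.isin(config.polymer_id, list(comp))
        sp = config.species[members]
        bead_ids = np.flatnonzero(members)
        n_a = len(np.unique(config.polymer_id[members][sp == 0]))
        n_b = len(np.unique(config.polymer_id[members][sp == 1]))
        unpaired = sum(1 for i in bead_ids if int(i) not in bonded_beads)
        clusters.append(
            Cluster(
                n_polymers_A=n_a,
                n_polymers_B=n_b,
                size_stickers=int(members.sum()),
                fully_bonded=(unpaired == 0),
                polymer_ids=tuple(sorted(int(p) for p in comp)),
            )
        )
    stats = ClusterStats(sorted(clusters, key=lambda c: c.polymer_ids))
    assert stats.total_stickers == n_beads, "cluster sizes must sum to bead count"
    return stats


# ---------------------------------------------------------------------------
# density profiles and coexistence
# ---------------------------------------------------------------------------

def _frame_histograms(config: Configuration, edges: np.ndarray):
    x = config.positions[:, 0] % config.box[0]
    h_a = np.histogram(x[config.species == 0], bins=edges)[0]
    h_b = np.histogram(x[config.species == 1], bins=edges)[0]
    return h_a, h_b


def _align_shift(total: np.ndarray, window_bins: int) -> int:
    """Circular shift placing the densest window's centre at the middle."""
    kernel = np.ones(window_bins)
    # circular windowed sum via FFT-free convolution on the doubled array
    doubled = np.concatenate([total, total[: window_bins - 1]])
    sums = np.convolve(doubled, kernel, mode="valid")
    start = int(np.argmax(sums))
    centre = (start + window_bins // 2) % len(total)
    return len(total) // 2 - centre


def density_profile(
    traj: Trajectory | Configuration,
    bin_width: float = 2.5,
    align: bool = True,
    dense_window_fraction: float = 0.08,
) -> DensityProfile:
    """Per-frame x histograms in mM, optionally aligned, frame-averaged.

    Alignment circularly shifts each frame so that the centre of the
    densest window (width ``dense_window_fraction`` of the box) maps to
    x = 0 (reported coordinates are centred: x in [-Lx/2, Lx/2)).
    """
    if isinstance(traj, Configuration):
        frames = [traj]
    else:
        frames = traj.frames
    if not frames:
        raise UsageError("need at least one frame")
    box = frames[0].box
    if bin_width > box[0]:
        raise UsageError("bin width exceeds the box")
    n_bins = max(1, int(round(box[0] / bin_width)))
    edges = np.linspace(0.0, box[0], n_bins + 1)
    window_bins = max(1, int(round(n_bins * dense_window_fraction)))

    acc_a = np.zeros(n_bins)
    acc_b = np.zeros(n_bins)
    for fr in frames:
        h_a, h_b = _frame_histograms(fr, edges)
        if align:
            shift = _align_shift((h_a + h_b).astype(float), window_bins)
            h_a = np.roll(h_a, shift)
            h_b = np.roll(h_b, shift)
        acc_a += h_a
        acc_b += h_b

    slab_volume = (box[0] / n_bins) * box[1] * box[2]
    conv = MM_PER_COUNT_PER_NM3 / slab_volume / len(frames)
    centres = 0.5 * (edges[:-1] + edges[1:]) - box[0] / 2.0
    return DensityProfile(
        x=centres,
        conc_A=acc_a * conv,
        conc_B=acc_b * conv,
        n_frames=len(frames),
        box=box.copy(),
    )


def extract_coexistence(
    profile: DensityProfile,
    dilute_window: tuple[float, float] | None = None,
    dense_window: tuple[float, float] | None = None,
) -> CoexistencePoint:
    """Window means of the aligned profile.

    Defaults reproduce the reference windows (|x| >= 100 nm dilute,
    |x| <= 10 nm dense, for a 250 nm box) rescaled by box_x / 250.
    Windows are (lo, hi) in |x|.
    """
    lx = profile.box[0]
    bw = profile.bin_width if np.isfinite(profile.bin_width) else 0.0
    if dilute_window is None:
        dilute_window = (min(0.4 * lx, 0.5 * lx - bw), 0.5 * lx)
    if dense_window is None:
        # at least one bin wide even for small boxes / coarse binning
        dense_window = (0.0, max(0.04 * lx, 0.75 * bw))

    def window_mean(lo, hi):
        m = (np.abs(profile.x) >= lo) & (np.abs(profile.x) <= hi)
        if not m.any():
            raise UsageError(f"window ({lo}, {hi}) contains no bins")
        return float(profile.conc_A[m].mean()), float(profile.conc_B[m].mean())

    dilute = window_mean(*dilute_window)
    dense = window_mean(*dense_window)
    return CoexistencePoint(dilute=dilute, dense=dense)


def stickers_to_mM(count: int, box_volume_nm3: float) -> float:
    """Sticker count in a volume (nm^3) as a concentration in mM."""
    if count < 0:
        raise UsageError("count must be >= 0")
    if box_volume_nm3 <= 0:
        raise UsageError("volume must be positive")
    return count / box_volume_nm3 * MM_PER_COUNT_PER_NM3


# ---------------------------------------------------------------------------
# oligomer combinatorics
# ---------------------------------------------------------------------------

def minimal_fully_bonded_oligomer(m: int, n: int) -> tuple[int, int]:
    """Smallest (a, b) with a*m == b*n: a = n/gcd, b = m/gcd."""
    if m < 1 or n < 1:
        raise UsageError("valences must be >= 1")
    g = math.gcd(m, n)
    return n // g, m // g


def unpaired_stickers(composition: tuple[int, int], m: int, n: int) -> int:
    """Minimum unbindable stickers in an (a, b) oligomer: |a m - b n|."""
    a, b = composition
    if a < 0 or b < 0:
        raise UsageError("composition counts must be >= 0")
    return abs(a * m - b * n)
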