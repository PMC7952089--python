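"""Free-energy landscapes and convex-hull phase diagrams.

The total free-energy density is evaluated on a uniform (c1, c2) grid;
the lower convex hull of the lifted points (c1, c2, F) identifies the
coexistence region: grid nodes strictly above the hull that fall inside
hull facets of large projected area are two-phase, and the long edges of
those facets are tie lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import NumericalError, UsageError
from .theory import SpeciesConcentrations, TheoryParams, f_total

__all__ = [
    "FreeEnergyLandscape",
    "PhaseDiagram",
    "build_landscape",
    "binodal_from_hull",
    "dilute_branch_scan",
]

#: facet projected-area threshold, in grid-cell areas
DEFAULT_ALPHA = 1.5


@dataclass
class FreeEnergyLandscape:
    """F(c1, c2) in k_BT * mM on a uniform rectangular grid."""

    c1: np.ndarray  # (n,) axis, mM
    c2: np.ndarray  # (n,) axis, mM
    F: np.ndarray  # (n, n), F[i, j] at (c1[i], c2[j])
    params: TheoryParams
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.c1) <= 0) or np.any(np.diff(self.c2) <= 0):
            raise UsageError("grid axes must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise NumericalError("landscape contains non-finite values")

    @property
    def cell_area(self) -> float:
        return float((self.c1[1] - self.c1[0]) * (self.c2[1] - self.c2[0]))


@dataclass
class PhaseDiagram:
    """Hull classification of a landscape."""

    landscape: FreeEnergyLandscape
    two_phase: np.ndarray  # (n, n) bool node labels
    gap: np.ndarray  # (n, n) F minus lower hull, >= 0
    tie_lines: list[tuple[tuple[float, float], tuple[float, float]]]
    tie_facets: np.ndarray  # (m, 3, 2) projected triangles of large facets
    degenerate: bool = False

    @property
    def hull_values(self) -> np.ndarray:
        return self.landscape.F - self.gap

    def tie_line_through(
        self, c1: float, c2: float
    ) -> tuple[tuple[float, float], tuple[float, float]] | None:
        """Tie line of the coexistence facet containing a composition."""
        for tri, tie in zip(self.tie_facets, self.tie_lines):
            lam = _barycentric(tri, c1, c2)
            if lam is not None:
                return tie
        return None


def build_landscape(
    p: TheoryParams, c_max: float = 30.0, n_grid: int = 200
) -> FreeEnergyLandscape:
    """Evaluate f_total on an n_grid x n_grid uniform grid up to c_max."""
    if c_max <= 0:
        raise UsageError("c_max must be positive")
    if n_grid < 50:
        raise UsageError("n_grid must be >= 50")
    axis = np.linspace(0.0, c_max, n_grid)
    F = np.empty((n_grid, n_grid))
    for i, a in enumerate(axis):
        for j, b in enumerate(axis):
            try:
                F[i, j] = f_total(SpeciesConcentrations(a, b), p).value
            except Exception as exc:  # solver diagnostics name the node
                raise NumericalError(
                    f"free-energy evaluation failed at node ({i}, {j}) "
                    f"= ({a:.4g}, {b:.4g}) mM: {exc}"
                ) from exc
    return FreeEnergyLandscape(
        c1=axis,
        c2=axis.copy(),
        F=F,
        params=p,
        metadata={"c_max": c_max, "n_grid": n_grid, "alpha": DEFAULT_ALPHA},
    )


def _barycentric(tri: np.ndarray, x: float, y: float, tol: float = 1e-9):
    a = np.array(
        [
            [tri[1, 0] - tri[0, 0], tri[2, 0] - tri[0, 0]],
            [tri[1, 1] - tri[0, 1], tri[2, 1] - tri[0, 1]],
        ]
    )
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-14:
        return None
    rhs = np.array([x - tri[0, 0], y - tri[0, 1]])
    lam = np.linalg.solve(a, rhs)
    if lam[0] >= -tol and lam[1] >= -tol and lam.sum() <= 1 + tol:
        return np.array([1 - lam.sum(), lam[0], lam[1]])
    return None


def _longest_edge(tri: np.ndarray):
    best, bl = None, -1.0
    for a in range(3):
        p0, p1 = tri[a], tri[(a + 1) % 3]
        d = float(np.hypot(*(p0 - p1)))
        if d > bl:
            bl, best = d, (p0, p1)
    p0, p1 = best
    if p0.sum() > p1.sum():
        p0, p1 = p1, p0
    return (float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))


def binodal_from_hull(
    ls: FreeEnergyLandscape, alpha: float = DEFAULT_ALPHA
) -> PhaseDiagram:
    """Classify nodes and extract tie lines from the lower convex hull.

    A node is two-phase when it lies strictly above the lower hull and
    inside the projection of a facet whose projected area exceeds
    ``alpha`` grid cells.  Facets below the area threshold are treated
    as triangulation slivers.  The long edge of each coexistence facet
    is its tie line (dilute endpoint first).
    """
    n = len(ls.c1)
    X, Y = np.meshgrid(ls.c1, ls.c2, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), ls.F.ravel()])
    scale = max(1.0, float(np.ptp(ls.F)))
    eps_gap = 1e-8 * scale

    try:
        hull = ConvexHull(pts)
    except QhullError:
        return PhaseDiagram(
            landscape=ls,
            two_phase=np.zeros((n, n), dtype=bool),
            gap=np.zeros((n, n)),
            tie_lines=[],
            tie_facets=np.zeros((0, 3, 2)),
            degenerate=True,
        )

    lower = hull.equations[:, 2] < -1e-12
    simplices = hull.simplices[lower]
    equations = hull.equations[lower]

    d1 = ls.c1[1] - ls.c1[0]
    d2 = ls.c2[1] - ls.c2[0]
    gap = np.full((n, n), np.inf)
    in_big = np.zeros((n, n), dtype=bool)
    tie_lines = []
    tie_facets = []

    for simplex, eq in zip(simplices, equations):
        tri = pts[simplex]
        proj = tri[:, :2]
        area = 0.5 * abs(
            (proj[1, 0] - proj[0, 0]) * (proj[2, 1] - proj[0, 1])
            - (proj[2, 0] - proj[0, 0]) * (proj[1, 1] - proj[0, 1])
        )
        i0 = max(0, int(np.floor(proj[:, 0].min() / d1)))
        i1 = min(n - 1, int(np.ceil(proj[:, 0].max() / d1)))
        j0 = max(0, int(np.floor(proj[:, 1].min() / d2)))
        j1 = min(n - 1, int(np.ceil(proj[:, 1].max() / d2)))
        xs = ls.c1[i0 : i1 + 1][:, None]
        ys = ls.c2[j0 : j1 + 1][None, :]
        plane = -(eq[0] * xs + eq[1] * ys + eq[3]) / eq[2]
        sub = ls.F[i0 : i1 + 1, j0 : j1 + 1] - plane
        gap[i0 : i1 + 1, j0 : j1 + 1] = np.minimum(
            gap[i0 : i1 + 1, j0 : j1 + 1], sub
        )
        if area > alpha * ls.cell_area:
            tie_lines.append(_longest_edge(proj))
            tie_facets.append(proj)
            # mark nodes covered by this facet
            for ii in range(i0, i1 + 1):
                for jj in range(j0, j1 + 1):
                    if not in_big[ii, jj]:
                        if _barycentric(proj, ls.c1[ii], ls.c2[jj]) is not None:
                            in_big[ii, jj] = True

    gap = np.where(np.isfinite(gap), np.maximum(gap, 0.0), 0.0)
    two_phase = in_big & (gap > eps_gap)
    return PhaseDiagram(
        landscape=ls,
        two_phase=two_phase,
        gap=gap,
        tie_lines=tie_lines,
        tie_facets=np.array(tie_facets) if tie_facets else np.zeros((0, 3, 2)),
        degenerate=False,
    )


def dilute_branch_scan(
    p_list: list[TheoryParams],
    stoichiometries: list[float],
    total_sticker_mM: float = 6.64,
    c_max: float = 25.0,
    n_grid: int = 200,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Dilute/dense branch totals along the tie line through each global
    composition.

    For every parameter set and sticker stoichiometry ``s = c1/c2`` the
    global composition at the given total concentration is located in
    the hull diagram; the containing coexistence facet's tie line gives
    the branch totals.  Compositions in the one-phase region are kept as
    rows with ``coexists = False``.
    """
    if not p_list:
        raise UsageError("parameter list must not be empty")
    rows = []
    for p in p_list:
        ls = build_landscape(p, c_max=c_max, n_grid=n_grid)
        pd_ = binodal_from_hull(ls, alpha=alpha)
        for s in stoichiometries:
            c1 = total_sticker_mM * s / (1.0 + s)
            c2 = total_sticker_mM / (1.0 + s)
            tie = pd_.tie_line_through(c1, c2)
            if tie is None:
                rows.append(
                    dict(
                        L1=p.L1,
                        L2=p.L2,
                        stoichiometry=s,
                        c1=c1,
                        c2=c2,
                        coexists=False,
                        dilute_total=np.nan,
                        dense_total=np.nan,
                    )
                )
            else:
                (d1, d2), (e1, e2) = tie
                rows.append(
                    dict(
                        L1=p.L1,
                        L2=p.L2,
                        stoichiometry=s,
                        c1=c1,
                        c2=c2,
                        coexists=True,
                        dilute_total=d1 + d2,
                        dense_total=e1 + e2,
                    )
                )
    return pd.DataFrame(rows)
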