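"""Mean-field dimer-gel free energy for two associating polymer species.

The system contains A polymers carrying ``L1`` stickers and B polymers
carrying ``L2`` stickers (``L1 >= L2``).  Stickers of opposite species
bind one-to-one.  Polymers associate either as whole-polymer dimers
(concentration of dimers ``rho_d``, dissociation constant ``Kd`` in
polymeric units) or through independently pairing stickers
(bond concentration ``cb``, dissociation constant ``Kb``).

The free-energy density per k_BT splits as

    f_total = f_noninteracting + f_specific + f_nonspecific

with the specific part minimised over the internal association state
``(cd1, cd2, cb)``.  All concentrations are sticker concentrations in
mM unless stated otherwise; ``rho`` symbols are polymeric (c / L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ConvergenceError, UsageError
from .potentials import ATTRACTION_RANGE, cross_attract
from .units import MM_PER_COUNT_PER_NM3

__all__ = [
    "TheoryParams",
    "SpeciesConcentrations",
    "AssociationState",
    "FreeEnergyValue",
    "f_noninteracting",
    "solve_association",
    "association_residuals",
    "f_specific",
    "f_nonspecific",
    "f_total",
    "limiting_f_specific",
    "transition_concentration",
    "skewed_transition",
    "dimer_fraction",
    "effective_valence",
    "dissociation_constant_from_potential",
    "dimer_kd_from_crossover",
]


def _xlogx(x: float) -> float:
    """x * ln(x), continuous at 0."""
    return x * math.log(x) if x > 0.0 else 0.0


@dataclass(frozen=True)
class TheoryParams:
    """Model parameters.

    Kd is the whole-polymer dimer dissociation constant (polymeric mM)
    and is valence-dependent; it is an input, not a derived constant.
    ``vb_ns`` / ``wb_ns`` are the two- and three-body nonspecific
    interaction parameters of the independent-bond solution (mM^-1,
    mM^-2); they are distinct from any microscopic interaction volume.
    """

    L1: int
    L2: int
    Kd: float
    Kb: float
    vb_ns: float = 0.0
    wb_ns: float = 0.0

    def __post_init__(self):
        if not (self.L1 >= self.L2 >= 1):
            raise UsageError(f"require L1 >= L2 >= 1, got ({self.L1}, {self.L2})")
        if not (self.Kd > 0 and self.Kb > 0):
            raise UsageError("Kd and Kb must be positive")
        if self.vb_ns < 0 or self.wb_ns < 0:
            raise UsageError("nonspecific parameters must be >= 0")


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Global sticker concentrations of the two species, mM."""

    c1: float
    c2: float

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0:
            raise UsageError("concentrations must be >= 0")

    def rho1(self, p: TheoryParams) -> float:
        return self.c1 / p.L1

    def rho2(self, p: TheoryParams) -> float:
        return self.c2 / p.L2

    @property
    def skew(self) -> float:
        """max/min sticker-concentration ratio; >= 1."""
        lo, hi = sorted((self.c1, self.c2))
        if lo == 0:
            return math.inf
        return hi / lo


@dataclass(frozen=True)
class AssociationState:
    """Internal equilibrium: stickers in dimers and independent bonds, mM."""

    cd1: float
    cd2: float
    cb: float

    def rho_d(self, p: TheoryParams) -> float:
        return self.cd1 / p.L1

    def validate(self, c: SpeciesConcentrations, p: TheoryParams, tol: float = 1e-9):
        if self.cd1 * p.L2 > 0 or self.cd2 * p.L1 > 0:
            num, den = self.cd1 * p.L2, self.cd2 * p.L1
            if abs(num - den) > 1e-10 * max(abs(num), abs(den), 1e-300):
                raise UsageError("cd1/L1 != cd2/L2")
        if not (-tol <= self.cd1 <= c.c1 + tol and -tol <= self.cd2 <= c.c2 + tol):
            raise UsageError("dimer stickers outside [0, c]")
        if not (-tol <= self.cb <= min(c.c1 - self.cd1, c.c2 - self.cd2) + tol):
            raise UsageError("bond concentration outside feasible range")


@dataclass(frozen=True)
class FreeEnergyValue:
    """A free-energy density in k_BT * mM with its component tag."""

    value: float
    component: Literal["ni", "s", "ns", "total", "dim_limit", "ind_limit"]


# ---------------------------------------------------------------------------
# free-energy components
# ---------------------------------------------------------------------------

def f_noninteracting(c: SpeciesConcentrations, p: TheoryParams) -> FreeEnergyValue:
    """Ideal translational free energy of the two unassociated species.

    (c1/L1) ln(c1/(e L1)) + (c2/L2) ln(c2/(e L2)), with x ln x -> 0 at 0.
    Conformational terms are linear in c and deliberately omitted.
    """
    r1, r2 = c.rho1(p), c.rho2(p)
    v = _xlogx(r1) - r1 + _xlogx(r2) - r2
    return FreeEnergyValue(v, "ni")


def _fs_value(c1, c2, L1, L2, Kd, Kb, rd, cb):
    """Specific free energy at association state (rd polymeric, cb)."""
    r1, r2 = c1 / L1, c2 / L2
    D1, D2 = c1 - L1 * rd, c2 - L2 * rd
    E1, E2 = D1 - cb, D2 - cb
    v = (
        -_xlogx(r1)
        - _xlogx(r2)
        + _xlogx(rd)
        + _xlogx(r1 - rd)
        + _xlogx(r2 - rd)
        - _xlogx(D1)
        - _xlogx(D2)
        + _xlogx(E1)
        + _xlogx(E2)
        + _xlogx(cb)
    )
    if rd > 0:
        v += rd * (1.0 + math.log(Kd))
    if cb > 0:
        v += cb * (1.0 + math.log(Kb))
    return v


def _cb_root(a: float, b: float, Kb: float) -> float:
    """Smaller root of Kb cb = (a - cb)(b - cb); the bond mass-action law."""
    if a <= 0.0 or b <= 0.0 or not math.isfinite(Kb):
        return 0.0
    if Kb > 1e150:  # avoid overflow in s*s; exact to O(ab/Kb^2)
        return a * b / Kb
    s = a + b + Kb
    return 2.0 * a * b / (s + math.sqrt(s * s - 4.0 * a * b))


def _dimer_stationarity_residual(rd, c1, c2, L1, L2, Kd, Kb):
    """Log of (LHS/RHS) of the dimer stationarity condition, cb eliminated."""
    D1, D2 = c1 - L1 * rd, c2 - L2 * rd
    cb = _cb_root(D1, D2, Kb)
    E1, E2 = D1 - cb, D2 - cb
    if rd <= 0 or D1 <= 0 or D2 <= 0 or E1 <= 0 or E2 <= 0:
        return -math.inf if rd <= 0 else math.inf
    return (
        math.log(Kd)
        + math.log(rd)
        + math.log(L1)
        + math.log(L2)
        + (L1 - 1) * math.log(D1)
        + (L2 - 1) * math.log(D2)
        - L1 * math.log(E1)
        - L2 * math.log(E2)
    )


def solve_association(c: SpeciesConcentrations, p: TheoryParams) -> AssociationState:
    """Minimise the specific free energy over (cd1, cd2, cb).

    cd2 is eliminated through cd2 = cd1 L2 / L1 and cb through its
    mass-action quadratic, leaving a one-dimensional problem in the
    dimer concentration whose stationary points are all bracketed and
    compared (see :func:`_solve_rho_d`).  Degenerate inputs (one species
    absent) return the all-zero state.
    """
    c1, c2 = c.c1, c.c2
    if c1 <= 0.0 or c2 <= 0.0:
        return AssociationState(0.0, 0.0, 0.0)
    L1, L2, Kd, Kb = p.L1, p.L2, p.Kd, p.Kb

    if not math.isfinite(Kd):
        rd = 0.0
    else:
        rd = _solve_rho_d(c1, c2, L1, L2, Kd, Kb)
    cb = _cb_root(c1 - L1 * rd, c2 - L2 * rd, Kb)
    return AssociationState(L1 * rd, L2 * rd, cb)


def _fs_at(rd, c1, c2, L1, L2, Kd, Kb):
    return _fs_value(
        c1, c2, L1, L2, Kd, Kb, rd, _cb_root(c1 - L1 * rd, c2 - L2 * rd, Kb)
    )


def _polish_root(rd, lo, hi, c1, c2, L1, L2, Kd, Kb):
    """Bisect to the floating-point limit around a bracketed root; the
    residual slope near full dimerisation is ~1/(rmax - rd), so generic
    xtol floors leave tens of ulps of slack."""
    a = max(lo, rd * (1.0 - 1e-13))
    b = min(hi, rd * (1.0 + 1e-13))
    ga = _dimer_stationarity_residual(a, c1, c2, L1, L2, Kd, Kb)
    gb = _dimer_stationarity_residual(b, c1, c2, L1, L2, Kd, Kb)
    if not (ga < 0.0 < gb):
        return rd
    for _ in range(60):
        m = 0.5 * (a + b)
        if m <= a or m >= b:
            break
        gm = _dimer_stationarity_residual(m, c1, c2, L1, L2, Kd, Kb)
        if gm < 0.0:
            a, ga = m, gm
        else:
            b, gb = m, gm
    return a if abs(ga) <= abs(gb) else b


def _solve_rho_d(c1, c2, L1, L2, Kd, Kb):
    """Global minimiser over rho_d of the cb-reduced specific free energy.

    The reduced objective can have two local minima (a bond-dominated and
    a dimer-dominated branch), so every sign change of the stationarity
    residual is bracketed on a log grid and the lowest free energy wins.
    """
    rmax = min(c1 / L1, c2 / L2)
    if rmax < 1e-280:
        return 0.0  # beyond any physically meaningful dilution
    lo = max(rmax * 1e-300, 1e-305)
    hi = rmax * (1.0 - 1e-12)
    glo = _dimer_stationarity_residual(lo, c1, c2, L1, L2, Kd, Kb)
    ghi = _dimer_stationarity_residual(hi, c1, c2, L1, L2, Kd, Kb)

    candidates = []
    if glo >= 0.0:
        # stationary point below lo where g ~ ln(rd) + const
        candidates.append(lo * math.exp(-glo) if math.isfinite(glo) else 0.0)
    if ghi <= 0.0:
        candidates.append(hi)

    # sample densely toward both edges: log-spaced in rho_d for the
    # bond-dominated branch, log-spaced in (rmax - rho_d) for the
    # near-saturated dimer branch
    from_lo = np.exp(np.linspace(math.log(max(lo, rmax * 1e-60)), math.log(hi), 64))
    from_hi = rmax * (1.0 - np.exp(np.linspace(math.log(1e-12), 0.0, 64)))
    grid = np.unique(np.clip(np.concatenate([from_lo, from_hi]), lo, hi))
    gs = [_dimer_stationarity_residual(r, c1, c2, L1, L2, Kd, Kb) for r in grid]
    for k in range(len(grid) - 1):
        if gs[k] < 0.0 <= gs[k + 1] or gs[k] >= 0.0 > gs[k + 1]:
            u_root = brentq(
                lambda u_: _dimer_stationarity_residual(
                    math.exp(u_), c1, c2, L1, L2, Kd, Kb
                ),
                math.log(grid[k]),
                math.log(grid[k + 1]),
                xtol=1e-15,
                rtol=8.9e-16,
                maxiter=300,
            )
            candidates.append(
                _polish_root(math.exp(u_root), lo, hi, c1, c2, L1, L2, Kd, Kb)
            )

    if not candidates:
        candidates.append(0.0)
    rd = min(candidates, key=lambda r: _fs_at(r, c1, c2, L1, L2, Kd, Kb))

    g = _dimer_stationarity_residual(rd, c1, c2, L1, L2, Kd, Kb)
    # within ~1e-6 of full dimer saturation the (L-1) ln(c - L rho_d)
    # terms amplify double-precision cancellation beyond the tolerance;
    # the state itself is still accurate there
    at_boundary = rd >= rmax * (1.0 - 1e-6) or rd <= rmax * 1e-250
    if rd > 0 and abs(g) > 1e-8 and not at_boundary:
        raise ConvergenceError(
            f"association solver residual {g:.3e} at rho_d={rd:.6e}",
            residuals=(g,),
        )
    return rd


def association_residuals(
    c: SpeciesConcentrations, p: TheoryParams, state: AssociationState
) -> tuple[float, float]:
    """Relative residuals of the two stationarity conditions.

    The first is the log-ratio of the dimer condition
    Kd cd2 L1 (c1-cd1)^(L1-1) (c2-cd2)^(L2-1) = (c1-cd1-cb)^L1 (c2-cd2-cb)^L2,
    the second the relative defect of Kb cb = (c1-cd1-cb)(c2-cd2-cb).
    """
    rd = state.rho_d(p)
    r7 = _dimer_stationarity_residual(rd, c.c1, c.c2, p.L1, p.L2, p.Kd, p.Kb)
    E1 = c.c1 - state.cd1 - state.cb
    E2 = c.c2 - state.cd2 - state.cb
    lhs, rhs = p.Kb * state.cb, E1 * E2
    r8 = (lhs - rhs) / max(abs(lhs), abs(rhs), 1e-300)
    return r7, r8


def f_specific(
    c: SpeciesConcentrations, state: AssociationState, p: TheoryParams
) -> FreeEnergyValue:
    """Specific-association free energy at a given internal state.

    Derived by Stirling's approximation from the pairing combinatorics;
    evaluates to 0 at the no-association state.
    """
    state.validate(c, p)
    rd = state.rho_d(p)
    return FreeEnergyValue(
        _fs_value(c.c1, c.c2, p.L1, p.L2, p.Kd, p.Kb, rd, state.cb), "s"
    )


def f_nonspecific(c: SpeciesConcentrations, p: TheoryParams) -> FreeEnergyValue:
    """Nonspecific part: (vb/2) max(c1,c2)^2 + (wb/6) max(c1,c2)^3."""
    cm = max(c.c1, c.c2)
    return FreeEnergyValue(p.vb_ns / 2.0 * cm**2 + p.wb_ns / 6.0 * cm**3, "ns")


def f_total(c: SpeciesConcentrations, p: TheoryParams) -> FreeEnergyValue:
    """Total free-energy density at the solved association state."""
    state = solve_association(c, p)
    v = (
        f_noninteracting(c, p).value
        + _fs_value(c.c1, c.c2, p.L1, p.L2, p.Kd, p.Kb, state.rho_d(p), state.cb)
        + f_nonspecific(c, p).value
    )
    return FreeEnergyValue(v, "total")


def limiting_f_specific(
    c: SpeciesConcentrations, p: TheoryParams, mode: Literal["dimer", "independent"]
) -> FreeEnergyValue:
    """Strong-binding limits of the specific free energy.

    dimer:       rho_d = min(rho1, rho2), cb = 0:
                 rho_d ln Kd + (rho - rho_d) ln((rho - rho_d)/e) - rho ln(rho/e)
    independent: cb = min(c1, c2), rho_d = 0, same form in sticker units
                 with Kb.
    """
    if mode == "dimer":
        r1, r2 = c.rho1(p), c.rho2(p)
        rd = min(r1, r2)
        rho = max(r1, r2)
        v = (
            (rd * math.log(p.Kd) if rd > 0 else 0.0)
            + _xlogx(rho - rd)
            - (rho - rd)
            - _xlogx(rho)
            + rho
        )
        return FreeEnergyValue(v, "dim_limit")
    if mode == "independent":
        cb = min(c.c1, c.c2)
        cm = max(c.c1, c.c2)
        v = (
            (cb * math.log(p.Kb) if cb > 0 else 0.0)
            + _xlogx(cm - cb)
            - (cm - cb)
            - _xlogx(cm)
            + cm
        )
        return FreeEnergyValue(v, "ind_limit")
    raise UsageError(f"unknown limiting mode {mode!r}")


# ---------------------------------------------------------------------------
# transition concentrations and helpers
# ---------------------------------------------------------------------------

def transition_concentration(L: int, Kd: float, Kb: float) -> float:
    """Equal-stoichiometry dimer/gel crossover c0 = e (Kb^L / (Kd L))^(1/(L-1)).

    Computed in log space so that astronomically small Kd values are safe.
    """
    if L < 2:
        raise UsageError("transition concentration requires L >= 2")
    return math.exp(
        1.0 + (L * math.log(Kb) - math.log(Kd) - math.log(L)) / (L - 1)
    )


def skewed_transition(c0: float, s: float) -> float:
    """Crossover at sticker skew s >= 1: c0 (s-1)^(s-1) s^(-s); cs(1) = c0."""
    if s < 1.0:
        raise UsageError("skew must satisfy s >= 1 (apply max/min first)")
    return c0 * math.exp(_xlogx(s - 1.0) - _xlogx(s))


def dimer_fraction(c: SpeciesConcentrations, p: TheoryParams) -> float:
    """Fraction of all stickers residing in dimers at equilibrium."""
    if c.c1 + c.c2 <= 0:
        raise UsageError("dimer_fraction undefined at zero total concentration")
    st = solve_association(c, p)
    return (st.cd1 + st.cd2) / (c.c1 + c.c2)


def effective_valence(L: float, ell_corr: float) -> float:
    """Map a simulation valence to a theory valence: L / ell_corr.

    ``ell_corr`` is the binding correlation length in stickers (~1.8 for
    the simulated linker length); neighbouring stickers within one
    correlation length bind as one effective unit.
    """
    if ell_corr <= 0:
        raise UsageError("correlation length must be positive")
    return L / ell_corr


def dissociation_constant_from_potential(
    potential: Callable[[float], float] | None = None,
    U0: float = 9.0,
    r_bound: float = ATTRACTION_RANGE,
) -> float:
    """Two-particle dissociation constant of a sticker pair, in mM.

    Kd = [ integral_0^r_bound exp(-U(r)) 4 pi r^2 dr ]^-1 with the bound
    region taken as the attraction well (r < cutoff).  With U = 0 this
    reduces to the inverse bound-region volume.

    Parameters default to the package's cross-species attraction at
    depth ``U0``.
    """
    if U0 < 0:
        raise UsageError("U0 must be >= 0")
    if potential is None:
        potential = lambda r: float(cross_attract(r, U0, r_bound))  # noqa: E731
    integrand = lambda r: 4.0 * math.pi * r * r * math.exp(-potential(r))  # noqa: E731
    vol, _ = quad(integrand, 0.0, r_bound, limit=200)
    if not (math.isfinite(vol) and vol > 0):
        raise UsageError("bound-state integral is not finite and positive")
    return MM_PER_COUNT_PER_NM3 / vol


def dimer_kd_from_crossover(n_bonds: int, Kb: float, c0: float) -> float:
    """Invert the crossover formula: the Kd that places the equal-
    stoichiometry dimer/gel transition of an ``n_bonds``-bond dimer at
    concentration ``c0`` (mM).  Used to generate stand-in Kd inputs when
    no measured value is available."""
    if n_bonds < 2:
        raise UsageError("need at least 2 bonds")
    return math.exp(
        n_bonds * math.log(Kb)
        - math.log(n_bonds)
        - (n_bonds - 1) * (math.log(c0) - 1.0)
    )
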