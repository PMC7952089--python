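import numpy as np
import pytest

from magicratio.theory import SpeciesConcentrations, TheoryParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_theory_draw(rng, strong=False):
    """A random (concentrations, parameters) pair for solver oracles."""
    L2 = int(rng.integers(1, 9))
    L1 = int(rng.integers(L2, 11))
    if strong:
        Kd = 10.0 ** rng.uniform(-20, -4)
        Kb = 10.0 ** rng.uniform(-4, -1)
    else:
        Kd = 10.0 ** rng.uniform(-8, 2)
        Kb = 10.0 ** rng.uniform(-3, 2)
    c = SpeciesConcentrations(
        float(10.0 ** rng.uniform(-2, 1.4)), float(10.0 ** rng.uniform(-2, 1.4))
    )
    p = TheoryParams(L1=L1, L2=L2, Kd=Kd, Kb=Kb)
    return c, p


def grid_minimize_fs(c, p, n=400):
    """Brute-force oracle: minimise the specific free energy on an
    (rho_d, cb) grid with local golden-section refinement.

    Implemented independently of the package internals (vectorised
    numpy evaluation of the Stirling free energy).
    """

    def xlogx(v):
        out = np.zeros_like(v)
        m = v > 0
        out[m] = v[m] * np.log(v[m])
        return out

    L1, L2, Kd, Kb = p.L1, p.L2, p.Kd, p.Kb
    c1, c2 = c.c1, c.c2
    r1, r2 = c1 / L1, c2 / L2

    def fs(rd, cb):
        D1, D2 = c1 - L1 * rd, c2 - L2 * rd
        E1, E2 = D1 - cb, D2 - cb
        bad = (E1 < 0) | (E2 < 0) | (rd < 0) | (cb < 0)
        rd_, cb_ = np.where(bad, 0.0, rd), np.where(bad, 0.0, cb)
        D1, D2 = c1 - L1 * rd_, c2 - L2 * rd_
        E1, E2 = D1 - cb_, D2 - cb_
        val = (
            -xlogx(np.full_like(rd_, r1))
            - xlogx(np.full_like(rd_, r2))
            + xlogx(rd_)
            + xlogx(r1 - rd_)
            + xlogx(r2 - rd_)
            - xlogx(D1)
            - xlogx(D2)
            + xlogx(E1)
            + xlogx(E2)
            + xlogx(cb_)
            + rd_ * (1.0 + np.log(Kd))
            + cb_ * (1.0 + np.log(Kb))
        )
        return np.where(bad, np.inf, val)

    rmax = min(r1, r2)
    rd_axis = np.linspace(0.0, rmax, n)
    cb_axis = np.linspace(0.0, min(c1, c2), n)
    RD, CB = np.meshgrid(rd_axis, cb_axis, indexing="ij")
    F = fs(RD, CB)
    i, j = np.unravel_index(np.argmin(F), F.shape)
    best = F[i, j]
    # two rounds of local grid refinement around the minimum
    for _ in range(3):
        lo_r = rd_axis[max(i - 1, 0)]
        hi_r = rd_axis[min(i + 1, len(rd_axis) - 1)]
        lo_b = cb_axis[max(j - 1, 0)]
        hi_b = cb_axis[min(j + 1, len(cb_axis) - 1)]
        rd_axis = np.linspace(lo_r, hi_r, n)
        cb_axis = np.linspace(lo_b, hi_b, n)
        RD, CB = np.meshgrid(rd_axis, cb_axis, indexing="ij")
        F = fs(RD, CB)
        i, j = np.unravel_index(np.argmin(F), F.shape)
        best = min(best, F[i, j])
    return float(best)
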