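"""Analytic pair interactions shared by the simulator and the theory.

Three interactions define the model:

* ``cross_attract`` -- a smooth, truncated well of depth ``U0`` between
  stickers of different species.  Bound partners sit essentially on top
  of each other (minimum at r = 0), so a bond is a geometric overlap.
* ``same_repel`` -- a soft repulsive dome between stickers of the same
  species.  Its range is at least twice the attraction range, so two A
  stickers can never simultaneously overlap one B sticker: binding is
  one-to-one by construction.
* ``harmonic_bond`` -- the backbone spring between consecutive stickers.

Both non-bonded forms use the C^1 quartic bump (1 - (r/rc)^2)^2, which
vanishes with zero slope at the cutoff (good energy conservation) and
has zero slope at r = 0.

The attraction range ``ATTRACTION_RANGE`` is the one free geometric
parameter of the model.  It is frozen at 1.83 nm, the value at which the
bound-state configurational integral of a 9 kT well gives a two-particle
dissociation constant of 0.40 mM (see
:func:`magicratio.theory.dissociation_constant_from_potential`).
"""

import numpy as np

#: nm; range (and cutoff) of the cross-species attractive well
ATTRACTION_RANGE = 1.83

#: nm; sticker hard-core scale (sets the same-species repulsion range)
STICKER_DIAMETER = 2.5

#: same-species repulsion range = factor * STICKER_DIAMETER >= 2 * ATTRACTION_RANGE
REPULSION_RANGE_FACTOR = 1.5

#: nm; default backbone rest length
MEAN_LINKER_LENGTH = 4.7


def repulsion_range(sticker_diameter: float = STICKER_DIAMETER) -> float:
    return REPULSION_RANGE_FACTOR * sticker_diameter


def repulsion_strength(U0: float) -> float:
    """Default same-species repulsion amplitude in kT.

    Strong enough that the deepest two-on-one arrangement costs more than
    it gains (two overlapping attractions gain < 2 U0, the A-A overlap
    then costs ~4 U0).
    """
    return 4.0 * U0 + 5.0


def cross_attract(r, U0: float, r_cut: float = ATTRACTION_RANGE):
    """Attractive well -U0 * (1 - (r/rc)^2)^2 for r < rc, else 0."""
    r = np.asarray(r, dtype=float)
    x2 = np.clip(r / r_cut, 0.0, 1.0) ** 2
    return -U0 * (1.0 - x2) ** 2


def same_repel(r, strength: float, r_cut: float):
    """Repulsive dome strength * (1 - (r/rc)^2)^2 for r < rc, else 0."""
    r = np.asarray(r, dtype=float)
    x2 = np.clip(r / r_cut, 0.0, 1.0) ** 2
    return strength * (1.0 - x2) ** 2


def harmonic_bond(r, k: float, r0: float = MEAN_LINKER_LENGTH):
    """Backbone spring 0.5 * k * (r - r0)^2."""
    r = np.asarray(r, dtype=float)
    return 0.5 * k * (r - r0) ** 2
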