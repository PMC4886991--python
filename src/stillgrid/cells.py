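"""Unit-cell arithmetic.

Cells are 6-tuples ``(a, b, c, alpha, beta, gamma)`` with lengths in
angstroms and angles in degrees.  All matrix conventions follow the
standard crystallographic orthogonalization: the columns of the real-space
basis matrix are the cell vectors in a Cartesian lab frame, and the
reciprocal basis ``B`` satisfies ``q = B @ (h, k, l)`` with ``|q| = 1/d``.

gemmi does the heavy lifting (metric validity, volume, Niggli reduction);
this module only adapts it to plain numpy types.
"""

from __future__ import annotations

import gemmi
import numpy as np

Cell = tuple[float, float, float, float, float, float]

__all__ = [
    "validate_cell",
    "cell_volume",
    "b_matrix",
    "real_matrix",
    "niggli_reduce",
]


def validate_cell(cell) -> Cell:
    """Check a 6-tuple cell and return it as floats.

    Raises ``ValueError`` naming the offending parameter for non-positive
    lengths, out-of-range angles, or a geometrically impossible combination
    (non-positive metric determinant).
    """
    cell = tuple(float(x) for x in cell)
    if len(cell) != 6:
        raise ValueError(f"cell must have 6 parameters, got {len(cell)}")
    names = ("a", "b", "c", "alpha", "beta", "gamma")
    for name, value in zip(names[:3], cell[:3]):
        if not value > 0:
            raise ValueError(f"cell length {name}={value} must be > 0")
    for name, value in zip(names[3:], cell[3:]):
        if not 0.0 < value < 180.0:
            raise ValueError(f"cell angle {name}={value} must be in (0, 180)")
    ca, cb, cg = (np.cos(np.radians(x)) for x in cell[3:])
    # determinant of the metric tensor divided by (abc)^2
    det = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if det <= 0.0:
        raise ValueError(f"cell angles {cell[3:]} are geometrically invalid")
    return cell


def _gemmi_cell(cell) -> gemmi.UnitCell:
    return gemmi.UnitCell(*validate_cell(cell))


def cell_volume(cell) -> float:
    """Volume of the cell in cubic angstroms (primitive setting as given)."""
    return _gemmi_cell(cell).volume


def real_matrix(cell) -> np.ndarray:
    """Real-space basis matrix; columns are the a, b, c vectors."""
    return np.array(_gemmi_cell(cell).orth.mat.tolist())


def b_matrix(cell) -> np.ndarray:
    """Reciprocal basis matrix ``B`` with columns a*, b*, c* (1/angstrom).

    ``B = (O^-1)^T`` for orthogonalization matrix ``O``, so that
    ``q = B @ h`` is the reciprocal-lattice vector of Miller index ``h``.
    """
    return np.array(_gemmi_cell(cell).frac.mat.tolist()).T


def niggli_reduce(cell) -> Cell:
    """Niggli-reduced setting of a cell.  Idempotent.

    Reduction enables comparison of lattices indexed in different but
    equivalent settings (e.g. permuted or sheared bases).
    """
    gv = gemmi.GruberVector(_gemmi_cell(cell), None)
    gv.niggli_reduce()
    return tuple(float(x) for x in gv.cell_parameters())
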