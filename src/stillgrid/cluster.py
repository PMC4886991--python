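"""Unit-cell clustering and Laue-class selection.

Serial data sets can mix crystal forms (polymorphs, doubled axes).
Grouping integrated images by Niggli-reduced unit cell separates the
forms; the dominant cluster — the one with the most member images — feeds
downstream scaling/merging.  The cell metric is a documented
simplification of the Andrews-Bernstein G6 distance: Euclidean distance on
reduced edge lengths plus angle differences scaled to angstrom-equivalent
units.  Clustering itself is standard agglomerative average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cells import niggli_reduce, validate_cell

__all__ = ["ClusterReport", "cell_distance", "cluster_cells",
           "lowest_laue_class"]

#: Scale converting angle differences (degrees) into distance units (~A).
ANGLE_SCALE = 0.5

#: Default linkage cut: keeps ~0.5% cell-length noise together while a
#: doubled axis (hundreds of angstroms apart) separates cleanly.
DEFAULT_THRESHOLD = 5.0


@dataclass
class ClusterReport:
    """Partition of accepted images by unit-cell similarity."""

    clusters: list            # of dicts: members, centroid_cell, spread
    dominant_index: int
    linkage_threshold: float

    @property
    def dominant(self) -> dict:
        return self.clusters[self.dominant_index]


def cell_distance(cell_a, cell_b) -> float:
    """Distance between two lattices after Niggli reduction.

    Zero iff the reduced cells coincide; symmetric.  Lengths contribute in
    angstroms, angles scaled by ``ANGLE_SCALE`` A/degree.
    """
    ra = np.array(niggli_reduce(validate_cell(cell_a)))
    rb = np.array(niggli_reduce(validate_cell(cell_b)))
    diff = ra - rb
    diff[3:] *= ANGLE_SCALE
    return float(np.linalg.norm(diff))


def cluster_cells(cells, linkage_threshold: float = DEFAULT_THRESHOLD,
                  image_ids=None) -> ClusterReport:
    """Average-linkage agglomerative clustering of unit cells.

    ``cells`` is a sequence of 6-tuples (one per accepted image); the
    linkage tree is cut at ``linkage_threshold`` in cell-distance units.
    Every cluster is reported; the one with the most members is marked
    dominant (ties broken towards the lower cluster index, i.e. first
    appearance order).
    """
    cells = [validate_cell(c) for c in cells]
    if not cells:
        raise ValueError("no cells to cluster")
    if image_ids is None:
        image_ids = [str(i) for i in range(len(cells))]
    reduced = np.array([niggli_reduce(c) for c in cells])
    scaled = reduced.copy()
    scaled[:, 3:] *= ANGLE_SCALE
    if len(cells) == 1:
        labels = np.array([1])
    else:
        dm = squareform(
            np.linalg.norm(scaled[:, None, :] - scaled[None, :, :], axis=2),
            checks=False)
        tree = linkage(dm, method="average")
        labels = fcluster(tree, t=linkage_threshold, criterion="distance")
    clusters = []
    # order clusters by first appearance for a deterministic report
    seen: dict[int, int] = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
    order = np.array([seen[lab] for lab in labels])
    for ci in range(order.max() + 1):
        member_idx = np.nonzero(order == ci)[0]
        members = [image_ids[i] for i in member_idx]
        sub = reduced[member_idx]
        clusters.append({
            "members": members,
            "centroid_cell": tuple(np.mean(sub, axis=0)),
            "spread": tuple(np.std(sub, axis=0)),
        })
    sizes = [len(c["members"]) for c in clusters]
    dominant = int(np.argmax(sizes))
    return ClusterReport(clusters=clusters, dominant_index=dominant,
                         linkage_threshold=float(linkage_threshold))


#: Lowest-symmetry Laue class per Bravais lattice.  Where a lattice allows
#: several Laue classes (tetragonal 4/m vs 4/mmm, trigonal/hexagonal,
#: cubic m-3 vs m-3m) the lower-symmetry class is listed, since downstream
#: scaling can merge upwards but not undo an over-merged symmetry.
_LAUE_TABLE = {
    "aP": "P-1",
    "mP": "P2/m", "mC": "C2/m",
    "oP": "Pmmm", "oC": "Cmmm", "oF": "Fmmm", "oI": "Immm",
    "tP": "P4/m", "tI": "I4/m",
    "hP": "P-3", "hR": "R-3",
    "cP": "Pm-3", "cF": "Fm-3", "cI": "Im-3",
}


def lowest_laue_class(bravais_lattice: str) -> str:
    """Lowest-symmetry Laue class for a Bravais lattice symbol."""
    try:
        return _LAUE_TABLE[bravais_lattice]
    except KeyError:
        raise ValueError(
            f"unknown Bravais lattice symbol {bravais_lattice!r}") from None
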