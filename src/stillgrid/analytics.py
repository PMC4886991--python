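"""Run-level summaries: heat map, beam-centre scatter, counts, stub output.

These tables answer the questions an experimenter asks after a serial run:
how many frames survived each stage, which spot-finding parameters won per
image (and whether any single pair dominates), where the refined beam
centres scatter (mis-indexed frames stand out), and what resolution the
images reach.  A plain key=value parameter stub records the dominant
cluster for whatever downstream merging tool follows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterReport, lowest_laue_class
from .gridsearch import ImageRecord

__all__ = ["heatmap_counts", "summarize_run"]


def heatmap_counts(best_results, grid) -> pd.DataFrame:
    """Matrix of how many images selected each (height, area) grid point.

    Rows are heights, columns areas; the total equals the number of
    integrated images.  A best result whose grid point is not in ``grid``
    is an error.
    """
    heights = sorted({h for h, _ in grid})
    areas = sorted({a for _, a in grid})
    counts = pd.DataFrame(0, index=pd.Index(heights, name="min_height"),
                          columns=pd.Index(areas, name="min_area"))
    for result in best_results:
        h, a = result.grid_point
        if (h, a) not in set(grid):
            raise ValueError(f"grid point {result.grid_point} not in grid")
        counts.loc[h, a] += 1
    return counts


def _limiting_resolution(result) -> float:
    """Highest resolution (smallest d) among integrated reflections."""
    if len(result.reflections) == 0:
        return np.nan
    return float(result.reflections["d"].min())


def summarize_run(records: list[ImageRecord], cluster_report: ClusterReport,
                  grid, out_dir, bravais_lattice: str = "aP",
                  resolution_bins: int = 10) -> dict:
    """Write the summary bundle for one processing run.

    Files written to ``out_dir``: ``summary.tsv`` (stage counts that
    partition the input image set, plus per-cluster rows),
    ``beam_centers.tsv``, ``resolution_hist.tsv``, ``heatmap.tsv``,
    ``downstream_params.txt`` (dominant-cluster image list, centroid cell
    and lowest Laue class for the follow-on merging step).  Returns the
    summary counts as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    integrated = [r for r in records if r.status == "integrated"]
    best = [r.best for r in integrated]

    counts = {
        "total": len(records),
        "no_diffraction": sum(r.status == "no_diffraction" for r in records),
        "not_integrated": sum(r.status == "not_integrated" for r in records),
        "failed_filter": sum(r.status == "failed_filter" for r in records),
        "integrated": len(integrated),
    }
    rows = [{"category": k, "count": v} for k, v in counts.items()]
    for i, cl in enumerate(cluster_report.clusters):
        label = "cluster_%d%s" % (i, " (dominant)"
                                  if i == cluster_report.dominant_index else "")
        rows.append({"category": label, "count": len(cl["members"])})
    pd.DataFrame(rows).to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    bc = pd.DataFrame([{
        "image": r.image_id,
        "slow": r.best.lattice.beam_center_refined[0],
        "fast": r.best.lattice.beam_center_refined[1],
    } for r in integrated])
    bc.to_csv(out_dir / "beam_centers.tsv", sep="\t", index=False)

    res = np.array([_limiting_resolution(b) for b in best])
    res = res[np.isfinite(res)]
    if len(res):
        hist, edges = np.histogram(res, bins=resolution_bins)
        pd.DataFrame({"d_min_lo": edges[:-1], "d_min_hi": edges[1:],
                      "n_images": hist}).to_csv(
            out_dir / "resolution_hist.tsv", sep="\t", index=False)

    heatmap_counts(best, grid).to_csv(out_dir / "heatmap.tsv", sep="\t")

    dom = cluster_report.dominant
    cell = dom["centroid_cell"]
    lines = [
        "# downstream merging parameters (dominant unit-cell cluster)",
        "n_images=%d" % len(dom["members"]),
        "unit_cell=%.3f %.3f %.3f %.3f %.3f %.3f" % tuple(cell),
        "laue_class=%s" % lowest_laue_class(bravais_lattice),
        "image_list=%s" % ",".join(str(m) for m in dom["members"]),
    ]
    (out_dir / "downstream_params.txt").write_text("\n".join(lines) + "\n")
    return counts
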