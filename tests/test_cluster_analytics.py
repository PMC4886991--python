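"""Unit-cell reduction, distance, clustering, Laue table and run summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stillgrid as sg
from stillgrid.analytics import heatmap_counts, summarize_run
from stillgrid.gridsearch import ImageRecord
from stillgrid.integrate import IntegrationResult

SHORT = (69.1, 171.6, 146.9, 90.0, 90.0, 90.0)
LONG = (69.6, 171.1, 291.9, 90.0, 90.0, 90.0)


class TestNiggliReduce:
    def test_reduced_cell_is_fixed_point(self):
        cell = (69.1, 146.9, 171.6, 90, 90, 90)
        assert sg.niggli_reduce(cell) == pytest.approx(cell)

    def test_cubic_unchanged(self):
        assert sg.niggli_reduce((100, 100, 100, 90, 90, 90)) == pytest.approx(
            (100, 100, 100, 90, 90, 90))

    def test_equivalent_settings_reduce_identically(self):
        # the same lattice described on a sheared basis (a, b, a+c)
        a, b, c = 30.0, 40.0, 50.0
        import math
        ac = math.hypot(a, c)
        beta = math.degrees(math.acos(a / ac))
        sheared = (a, b, ac, 90.0, 180.0 - beta, 90.0)
        assert sg.niggli_reduce(sheared) == pytest.approx(
            sg.niggli_reduce((a, b, c, 90, 90, 90)), rel=1e-6)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            sg.niggli_reduce((10, 10, 10, 1, 1, 179))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.tuples(*[st.floats(20.0, 200.0) for _ in range(3)],
                     *[st.floats(70.0, 110.0) for _ in range(3)]))
    def test_reduction_idempotent_and_distance_metric(self, cell):
        reduced = sg.niggli_reduce(cell)
        assert sg.niggli_reduce(reduced) == pytest.approx(reduced, rel=1e-9)
        assert sg.cell_distance(cell, cell) == pytest.approx(0.0, abs=1e-9)
        other = tuple(1.1 * x for x in cell[:3]) + cell[3:]
        assert sg.cell_distance(cell, other) == pytest.approx(
            sg.cell_distance(other, cell))


class TestCellDistance:
    def test_identity(self):
        assert sg.cell_distance(SHORT, SHORT) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = (50 + 50 * rng.random(), 50 + 50 * rng.random(),
                 50 + 50 * rng.random(), 90, 90, 90)
            b = (50 + 50 * rng.random(), 50 + 50 * rng.random(),
                 50 + 50 * rng.random(), 90, 90, 90)
            assert sg.cell_distance(a, b) == pytest.approx(
                sg.cell_distance(b, a))

    def test_two_crystal_forms_separate_cleanly(self):
        rng = np.random.default_rng(1)
        noisy_short = tuple(np.array(SHORT)
                            * (1 + 0.005 * np.r_[rng.standard_normal(3),
                                                 np.zeros(3)]))
        within = sg.cell_distance(SHORT, noisy_short)
        between = sg.cell_distance(SHORT, LONG)
        assert between > 10 * within


class TestClusterCells:
    def test_identical_cells_form_one_cluster(self):
        report = sg.cluster_cells([SHORT] * 8)
        assert len(report.clusters) == 1
        assert report.dominant_index == 0

    def test_two_form_mixture_splits_pure(self):
        rng = np.random.default_rng(2)
        cells, labels = [], []
        for i in range(30):
            base = SHORT if i < 18 else LONG      # 60/40 mixture
            jitter = 1 + 0.003 * rng.standard_normal(3)
            cells.append(tuple(np.r_[np.array(base[:3]) * jitter, base[3:]]))
            labels.append(int(i >= 18))
        report = sg.cluster_cells(cells, linkage_threshold=5.0)
        assert len(report.clusters) == 2
        # purity: each cluster holds exactly one true form
        for cluster in report.clusters:
            members = [int(m) for m in cluster["members"]]
            assert len({labels[m] for m in members}) == 1
        dominant = report.clusters[report.dominant_index]
        assert len(dominant["members"]) == 18
        # Niggli ordering is a <= b <= c, so the 146.9 A axis sorts second
        assert dominant["centroid_cell"][1] == pytest.approx(146.9, rel=0.01)

    def test_huge_threshold_coarsens_to_one_cluster(self):
        report = sg.cluster_cells([SHORT] * 5 + [LONG] * 5,
                                  linkage_threshold=1e6)
        assert len(report.clusters) == 1

    def test_clusters_partition_inputs(self):
        rng = np.random.default_rng(3)
        cells = [tuple(np.r_[np.array(SHORT[:3])
                             * (1 + 0.01 * rng.standard_normal(3)),
                             SHORT[3:]]) for _ in range(20)]
        report = sg.cluster_cells(cells, linkage_threshold=2.0)
        seen = [m for c in report.clusters for m in c["members"]]
        assert sorted(seen) == sorted(str(i) for i in range(20))


class TestLowestLaueClass:
    @pytest.mark.parametrize("lattice,laue", [
        ("tP", "P4/m"),          # lower of P4/m and P4/mmm
        ("oP", "Pmmm"),          # orthorhombic has a single Laue class
        ("cP", "Pm-3"),          # lower of Pm-3 and Pm-3m
        ("aP", "P-1"),
        ("hR", "R-3"),
    ])
    def test_table(self, lattice, laue):
        assert sg.lowest_laue_class(lattice) == laue

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="xQ"):
            sg.lowest_laue_class("xQ")


def make_best(grid_point, cell=SHORT, image_id="img", d_values=(4.0, 5.0)):
    refl = pd.DataFrame({"h": [1, 2], "k": [0, 0], "l": [0, 0],
                         "I": [100.0, 80.0], "sigI": [5.0, 5.0],
                         "d": list(d_values),
                         "partial_flag": [False, False]})
    model = sg.LatticeModel(cell=cell, orientation=np.eye(3),
                            beam_center_refined=(127.3, 128.1))
    return IntegrationResult(reflections=refl, lattice=model,
                             image_id=image_id, grid_point=grid_point,
                             grid_index=0)


class TestHeatmap:
    def test_single_hot_cell(self):
        grid = sg.build_grid(sg.GridSpec(8, 1, 12, 1))
        best = [make_best((8.0, 12)) for _ in range(3)]
        counts = heatmap_counts(best, grid)
        assert counts.loc[8.0, 12] == 3
        assert counts.to_numpy().sum() == 3

    def test_total_equals_image_count(self):
        grid = sg.build_grid(sg.GridSpec(4, 2, 5, 2))
        rng = np.random.default_rng(4)
        best = [make_best(grid[rng.integers(len(grid))]) for _ in range(17)]
        assert heatmap_counts(best, grid).to_numpy().sum() == 17

    def test_foreign_grid_point_rejected(self):
        grid = sg.build_grid(sg.GridSpec(4, 1, 5, 1))
        with pytest.raises(ValueError, match="not in grid"):
            heatmap_counts([make_best((99.0, 99))], grid)


class TestSummarizeRun:
    def test_counts_partition_the_image_set(self, tmp_path):
        grid = sg.build_grid(sg.GridSpec(4, 1, 5, 1))
        records = (
            [ImageRecord(f"i{i}", "integrated",
                         best=make_best(grid[0], image_id=f"i{i}"))
             for i in range(7)]
            + [ImageRecord("b0", "no_diffraction"),
               ImageRecord("b1", "no_diffraction"),
               ImageRecord("u0", "not_integrated")])
        report = sg.cluster_cells([SHORT] * 7,
                                  image_ids=[f"i{i}" for i in range(7)])
        counts = summarize_run(records, report, grid, tmp_path,
                               bravais_lattice="oP")
        assert counts["total"] == 10
        assert (counts["integrated"] + counts["no_diffraction"]
                + counts["not_integrated"] + counts["failed_filter"]) == 10
        summary = pd.read_csv(tmp_path / "summary.tsv", sep="\t")
        assert summary[summary.category == "total"]["count"].iloc[0] == 10

    def test_outputs_written(self, tmp_path):
        grid = sg.build_grid(sg.GridSpec(4, 1, 5, 1))
        records = [ImageRecord(f"i{i}", "integrated",
                               best=make_best(grid[i % len(grid)],
                                              image_id=f"i{i}"))
                   for i in range(5)]
        report = sg.cluster_cells([SHORT] * 5,
                                  image_ids=[f"i{i}" for i in range(5)])
        summarize_run(records, report, grid, tmp_path, bravais_lattice="oP")
        for name in ("summary.tsv", "beam_centers.tsv", "heatmap.tsv",
                     "resolution_hist.tsv", "downstream_params.txt"):
            assert (tmp_path / name).exists()
        bc = pd.read_csv(tmp_path / "beam_centers.tsv", sep="\t")
        assert len(bc) == 5
        stub = (tmp_path / "downstream_params.txt").read_text()
        assert "laue_class=Pmmm" in stub
        assert "n_images=5" in stub
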