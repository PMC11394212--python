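"""Binning core: assignment convention, per-bin and per-quadrant
statistics against a naive per-event oracle, and colour scaling."""

import numpy as np
import pandas as pd
import pytest

from binbat import (
    BinGrid,
    BinStatistic,
    EmptySampleError,
    Quadrant,
    TransformStateError,
    assign_bins,
    bin_color_scale,
    bin_statistics,
    quadrant_statistics,
)
from tests.conftest import make_table


def _table(x, y, z):
    return make_table({"SSC": x, "FCER1A": y, "CD63": z})


GRID = BinGrid("SSC", "FCER1A", bin_width=0.2, x_threshold=1.0, y_threshold=1.0)


def naive_bin_stats(x, y, z, grid: BinGrid, z_thr: float) -> dict:
    """Independent per-event loop oracle for every bin statistic."""
    bins: dict[tuple[int, int], list[float]] = {}
    for xi, yi, zi in zip(x, y, z):
        ix = int(np.floor((xi - grid.origin[0]) / grid.bin_width))
        iy = int(np.floor((yi - grid.origin[1]) / grid.bin_width))
        bins.setdefault((ix, iy), []).append(zi)
    out = {}
    for key, zs in bins.items():
        pos = [v for v in zs if v > z_thr]
        out[key] = {
            "n_events": len(zs),
            "density": len(zs) / len(x),
            "freq_zpos": 100.0 * len(pos) / len(zs),
            "msi_all": float(np.mean(zs)),
            "msi_pos": float(np.mean(pos)) if pos else None,
        }
    return out


class TestAssignBins:
    def test_lower_edge_belongs_to_bin(self):
        t = _table([0.2], [0.4], [0.0])
        idx = assign_bins(t, GRID)
        assert tuple(idx[0]) == (1, 2)

    def test_event_at_origin_in_bin_zero(self):
        t = _table([0.0], [0.0], [0.0])
        assert tuple(assign_bins(t, GRID)[0]) == (0, 0)

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(0, 5, 1000), rng.uniform(0, 5, 1000), np.zeros(1000))
        stats = bin_statistics(t, GRID, "CD63", 0.5, min_cells_per_bin=1)
        assert stats.table["n_events"].sum() == 1000

    def test_untransformed_marker_is_state_error(self):
        t = make_table({"SSC": [1.0], "FCER1A": [1.0]}, transformed=False)
        with pytest.raises(TransformStateError):
            assign_bins(t, BinGrid("SSC", "FCER1A"))


class TestBinStatistics:
    def test_hand_computed_single_bin(self):
        t = _table([0.05, 0.1, 0.15], [0.05, 0.1, 0.15], [1.0, 2.0, 3.0])
        stats = bin_statistics(t, GRID, "CD63", z_threshold=2.0, min_cells_per_bin=1)
        row = stats.table.loc[(0, 0)]
        assert row["freq_zpos"] == pytest.approx(100 / 3)
        assert row["msi_all"] == pytest.approx(2.0)
        assert row["msi_pos"] == pytest.approx(3.0)

    def test_threshold_below_all_values(self):
        t = _table([0.0] * 3, [0.0] * 3, [1.0, 2.0, 3.0])
        stats = bin_statistics(t, GRID, "CD63", z_threshold=0.0, min_cells_per_bin=1)
        row = stats.table.loc[(0, 0)]
        assert row["freq_zpos"] == 100.0
        assert row["msi_pos"] == row["msi_all"]

    def test_threshold_above_all_values_msi_pos_absent(self):
        t = _table([0.0] * 3, [0.0] * 3, [1.0, 2.0, 3.0])
        stats = bin_statistics(t, GRID, "CD63", z_threshold=5.0, min_cells_per_bin=1)
        row = stats.table.loc[(0, 0)]
        assert row["freq_zpos"] == 0.0
        assert pd.isna(row["msi_pos"])  # absent, never zero

    def test_zero_events_is_error(self):
        t = _table([], [], [])
        with pytest.raises(EmptySampleError):
            bin_statistics(t, GRID, "CD63", 0.0)

    def test_matches_naive_oracle_exactly(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 4, 800), rng.uniform(0, 4, 800)
        z = rng.normal(1.5, 1.0, 800)
        t = _table(x, y, z)
        stats = bin_statistics(t, GRID, "CD63", 1.5, min_cells_per_bin=3)
        oracle = naive_bin_stats(x, y, z, GRID, 1.5)
        assert set(stats.table.index) == set(oracle)
        for key, expect in oracle.items():
            row = stats.table.loc[key]
            assert row["n_events"] == expect["n_events"]
            assert row["density"] == pytest.approx(expect["density"], abs=1e-12)
            assert row["freq_zpos"] == pytest.approx(expect["freq_zpos"], abs=1e-9)
            assert row["msi_all"] == pytest.approx(expect["msi_all"], abs=1e-9)
            if expect["msi_pos"] is None:
                assert pd.isna(row["msi_pos"])
            else:
                assert row["msi_pos"] == pytest.approx(expect["msi_pos"], abs=1e-9)

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(9)
        t = _table(rng.uniform(0, 4, 500), rng.uniform(0, 4, 500), rng.normal(size=500))
        stats = bin_statistics(t, GRID, "CD63", 0.0)
        assert stats.table["density"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_freq_monotone_and_msi_pos_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        t = _table(rng.uniform(0, 2, 400), rng.uniform(0, 2, 400), rng.normal(size=400))
        lo = bin_statistics(t, GRID, "CD63", -0.5, min_cells_per_bin=1).table
        hi = bin_statistics(t, GRID, "CD63", 0.5, min_cells_per_bin=1).table
        assert (hi["freq_zpos"] <= lo["freq_zpos"] + 1e-12).all()
        both = hi["msi_pos"].notna()
        assert (hi.loc[both, "msi_pos"] >= lo.loc[both, "msi_pos"] - 1e-12).all()

    def test_event_weighted_msi_equals_global_mean(self):
        rng = np.random.default_rng(17)
        z = rng.normal(2.0, 1.0, 600)
        t = _table(rng.uniform(0, 4, 600), rng.uniform(0, 4, 600), z)
        stats = bin_statistics(t, GRID, "CD63", 0.0).table
        weighted = (stats["msi_all"] * stats["n_events"]).sum() / stats["n_events"].sum()
        assert weighted == pytest.approx(z.mean(), abs=1e-9)


class TestQuadrants:
    def test_all_events_upper_left(self):
        t = _table([0.1] * 5, [2.0] * 5, [0.0] * 5)
        q = quadrant_statistics(t, GRID, "CD63", 0.5, Quadrant.UL)
        assert q.q_freq == {"UL": 100.0, "UR": 0.0, "LL": 0.0, "LR": 0.0}

    def test_eight_hand_placed_events(self):
        # two per quadrant around thresholds (1.0, 1.0); one z-positive in UL
        x = [0.5, 0.5, 1.5, 1.5, 0.5, 0.5, 1.5, 1.5]
        y = [1.5, 1.5, 1.5, 1.5, 0.5, 0.5, 0.5, 0.5]
        z = [9.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        q = quadrant_statistics(_table(x, y, z), GRID, "CD63", 1.0, Quadrant.UL)
        assert q.q_freq == {"UL": 25.0, "UR": 25.0, "LL": 25.0, "LR": 25.0}
        assert q.zpos_pct_target == pytest.approx(50.0)
        assert q.zpos_count == 1

    def test_threshold_beyond_all_events_empties_right(self):
        rng = np.random.default_rng(2)
        t = _table(rng.uniform(0, 2, 50), rng.uniform(0, 2, 50), np.zeros(50))
        grid = BinGrid("SSC", "FCER1A", 0.2, x_threshold=10.0, y_threshold=1.0)
        q = quadrant_statistics(t, grid, "CD63", 0.5, Quadrant.UL)
        assert q.q_freq["UR"] + q.q_freq["LR"] == 0.0

    def test_quadrant_frequencies_sum_to_100(self):
        rng = np.random.default_rng(4)
        t = _table(rng.uniform(0, 3, 333), rng.uniform(0, 3, 333), np.zeros(333))
        q = quadrant_statistics(t, GRID, "CD63", 0.5, Quadrant.UL)
        assert sum(q.q_freq.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_target_quadrant_warns_with_undefined_pct(self):
        t = _table([1.5] * 4, [0.5] * 4, [0.0] * 4)  # everything LR
        q = quadrant_statistics(t, GRID, "CD63", 0.5, Quadrant.UL)
        assert q.zpos_pct_target is None
        assert q.warnings


class TestColorScale:
    def _stats(self, msi_values, below=None):
        n = len(msi_values)
        below = below or [False] * n
        table = pd.DataFrame({
            "n_events": [20] * n,
            "density": [1 / n] * n,
            "freq_zpos": [50.0] * n,
            "msi_all": msi_values,
            "msi_pos": msi_values,
            "below_cutoff": below,
        }, index=pd.MultiIndex.from_tuples([(i, 0) for i in range(n)],
                                           names=["ix", "iy"]))
        from binbat.binning import BinStatsTable

        return BinStatsTable(table, GRID, "CD63", 0.5, 20 * n, 10)

    def test_linear_normalization(self):
        colors = bin_color_scale(self._stats([1.0, 2.0, 3.0]), BinStatistic.MSI)
        np.testing.assert_allclose(colors.to_numpy(), [0.0, 0.5, 1.0])

    def test_flat_statistic_maps_to_half(self):
        colors = bin_color_scale(self._stats([2.0, 2.0]), BinStatistic.MSI)
        np.testing.assert_allclose(colors.to_numpy(), [0.5, 0.5])

    def test_below_cutoff_bin_excluded_from_range_and_grey(self):
        colors = bin_color_scale(
            self._stats([1.0, 2.0, 99.0], below=[False, False, True]), BinStatistic.MSI
        )
        np.testing.assert_allclose(colors.to_numpy()[:2], [0.0, 1.0])
        assert np.isnan(colors.to_numpy()[2])

    def test_all_below_cutoff_is_error(self):
        with pytest.raises(EmptySampleError):
            bin_color_scale(self._stats([1.0], below=[True]), BinStatistic.MSI)
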