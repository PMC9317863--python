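import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import utilsurv as u
from utilsurv.windows import anchor_years


class TestAssignBlocks:
    def test_default_partition_for_june(self, default_config):
        # w=3: window Mar..Sep; leftovers Oct,Nov,Dec,Jan,Feb split 2,2,1
        mapping = u.assign_blocks(6, default_config)
        assert {m for m, b in mapping.items() if b == 0} == {3, 4, 5, 6, 7, 8, 9}
        assert {m for m, b in mapping.items() if b == 1} == {10, 11}
        assert {m for m, b in mapping.items() if b == 2} == {12, 1}
        assert {m for m, b in mapping.items() if b == 3} == {2}

    def test_degenerate_config(self):
        cfg = u.WindowConfig(w=0, n_blocks=1)
        mapping = u.assign_blocks(5, cfg)
        assert mapping[5] == 0
        assert all(b == 1 for m, b in mapping.items() if m != 5)

    @given(
        st.integers(1, 12),
        st.integers(0, 4),
        st.integers(1, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_properties(self, moy, w, n):
        cfg = u.WindowConfig(w=w, n_blocks=n)
        mapping = u.assign_blocks(moy, cfg)
        assert sorted(mapping) == list(range(1, 13))
        sizes = {b: sum(1 for v in mapping.values() if v == b) for b in range(n + 1)}
        assert sizes[0] == 2 * w + 1
        assert sum(sizes.values()) == 12
        # near-equal leftover blocks, larger first
        leftover = [sizes[b] for b in range(1, n + 1)]
        assert max(leftover) - min(leftover) <= 1
        assert leftover == sorted(leftover, reverse=True)
        # window centred on the target month-of-year
        for d in range(-w, w + 1):
            assert mapping[(moy - 1 + d) % 12 + 1] == 0


class TestBuildReferenceDesign:
    def test_post_cutoff_target_has_35_window_points(
        self, study_series, default_config
    ):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        block0 = [p for p in d.points if p.block == 0]
        assert len(block0) == 35  # Mar–Sep of 2015..2019
        assert {p.month.year for p in block0} == {2015, 2016, 2017, 2018, 2019}
        assert {p.month.month for p in block0} == {3, 4, 5, 6, 7, 8, 9}
        # current-year window Mar–May 2020 excluded by the cutoff
        assert all(p.month <= u.MonthStamp(2019, 12) for p in d.points)

    def test_pre_cutoff_target_clamps_to_available_history(
        self, study_series, default_config
    ):
        d = u.build_reference_design(study_series, u.MonthStamp(2019, 6),
                                     default_config)
        block0 = [p for p in d.points if p.block == 0]
        # Mar–Sep of 2015..2018 (2014 predates the series) + Mar–May 2019
        assert len(block0) == 7 * 4 + 3 == 31
        assert u.MonthStamp(2019, 5) in {p.month for p in block0}
        assert all(p.month < u.MonthStamp(2019, 6) for p in d.points)

    def test_pre_cutoff_target_with_full_history_has_38_window_points(
        self, default_config
    ):
        months = tuple(u.MonthStamp(2013, 1).shift(k) for k in range(96))
        s = u.UtilizationSeries(u.Outcome.INPATIENTS_PER_DAY, "total", months,
                                (50,) * 96)
        d = u.build_reference_design(s, u.MonthStamp(2019, 6), default_config)
        block0 = [p for p in d.points if p.block == 0]
        assert len(block0) == 7 * 5 + 3 == 38

    def test_target_before_series_start_errors(self, study_series, default_config):
        with pytest.raises(u.InsufficientHistoryError):
            u.build_reference_design(study_series, u.MonthStamp(2014, 6),
                                     default_config)

    def test_trend_index_is_months_since_series_start(
        self, study_series, default_config
    ):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        for p in d.points:
            assert p.trend_index == study_series.start.months_until(p.month)

    def test_audit_rejects_contaminated_design(self, study_series, default_config):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        d.audit()  # clean design passes
        bad_point = u.ReferencePoint(u.MonthStamp(2020, 3), 60, 0, 100)
        bad = u.ReferenceDesign(
            target=d.target, series_start=d.series_start, config=d.config,
            points=d.points + (bad_point,), block_map=d.block_map,
        )
        with pytest.raises(AssertionError):
            bad.audit()

    def test_anchor_years_regimes(self, default_config):
        assert list(anchor_years(u.MonthStamp(2020, 6), default_config)) == [
            2015, 2016, 2017, 2018, 2019
        ]
        assert list(anchor_years(u.MonthStamp(2019, 6), default_config)) == [
            2014, 2015, 2016, 2017, 2018
        ]


class TestDesignMatrix:
    def test_shape_and_coding(self, study_series, default_config):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        X, y, names, dropped = u.design_matrix(d)
        assert names == ["intercept", "trend", "block_1", "block_2", "block_3"]
        assert X.shape == (len(d.points), 5)
        assert dropped == []
        assert np.all(X[:, 2:].sum(axis=1) <= 1)
        for i, p in enumerate(d.points):
            if p.block == 0:
                assert X[i, 2:].sum() == 0
            assert X[i, 1] == p.trend_index
            assert y[i] == p.value
        assert np.linalg.matrix_rank(X) == 5

    def test_empty_block_column_dropped(self):
        # one anchor year starting in March: February (block 3 for a June
        # target) never occurs, so its dummy column is dropped
        s_months = tuple(u.MonthStamp(2019, 3).shift(k) for k in range(10))
        s = u.UtilizationSeries(u.Outcome.INPATIENTS_PER_DAY, "total", s_months,
                                (100,) * 10)
        cfg = u.WindowConfig(b_years=1)
        d = u.build_reference_design(s, u.MonthStamp(2020, 6), cfg)
        X, y, names, dropped = u.design_matrix(d)
        assert dropped == [3]
        assert "block_3" not in names
        assert X.shape == (10, 4)
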