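import numpy as np
import pandas as pd
import pytest

from lolichemo import (
    GridConfig,
    SpectraSet,
    average_replicates,
    default_study_config,
    enumerate_treatments,
    exclude_zero_reference,
    generate,
    run_grid,
    select_best,
    split_calibration_validation,
)
from lolichemo.errors import EmptyDatasetError, SelectionError
from lolichemo.model_search import GridReport, _selection_key


class TestEnumerateTreatments:
    def test_twenty_codes_in_table_order(self):
        codes = [str(c) for c in enumerate_treatments()]
        assert len(codes) == 20
        assert codes[0] == "n0"
        assert codes[:5] == ["n0", "n1", "n2", "n3", "n4"]
        assert codes[5] == "s0" and codes[10] == "d0" and codes[15] == "m0"

    def test_no_duplicates(self):
        codes = [str(c) for c in enumerate_treatments()]
        assert len(set(codes)) == 20


@pytest.fixture(scope="module")
def averaged():
    spectra, _ = generate(default_study_config(seed=21, n_samples=100))
    return average_replicates(spectra)


@pytest.fixture(scope="module")
def small_grid():
    spectra, _ = generate(default_study_config(seed=23, n_samples=45))
    cal = average_replicates(spectra)
    config = GridConfig(n_factors=5, n_groups=6, seed=23)
    return run_grid(cal, "total_lolines", config)


class TestSplit:
    def test_sizes_75_25(self, averaged):
        cal, val = split_calibration_validation(averaged, 0.75, seed=0)
        assert cal.n_rows == 75 and val.n_rows == 25

    def test_same_seed_same_partition(self, averaged):
        a_cal, a_val = split_calibration_validation(averaged, seed=3)
        b_cal, b_val = split_calibration_validation(averaged, seed=3)
        assert list(a_cal.sample_ids) == list(b_cal.sample_ids)
        assert list(a_val.sample_ids) == list(b_val.sample_ids)

    def test_disjoint_and_exhaustive(self, averaged):
        cal, val = split_calibration_validation(averaged, seed=5)
        cal_ids, val_ids = set(cal.sample_ids), set(val.sample_ids)
        assert cal_ids.isdisjoint(val_ids)
        assert cal_ids | val_ids == set(averaged.sample_ids)


class TestExcludeZeroReference:
    def _set_with_refs(self, refs):
        n = len(refs)
        wl = 1100.0 + 2.0 * np.arange(10)
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "NFL": refs}
        )
        return SpectraSet(wl, 0.5 + 0.01 * rng.standard_normal((n, 10)), meta)

    def test_zero_and_missing_references_are_dropped(self):
        ss = self._set_with_refs([10.0, 0.0, 5.0, np.nan, 0.0, 7.0, 1, 2, 3, 4])
        out = exclude_zero_reference(ss, "NFL")
        assert out.n_rows == 7

    def test_all_positive_is_identity(self):
        ss = self._set_with_refs([1.0, 2.0, 3.0])
        out = exclude_zero_reference(ss, "NFL")
        assert list(out.sample_ids) == list(ss.sample_ids)

    def test_all_zero_is_degenerate(self):
        ss = self._set_with_refs([0.0, 0.0])
        with pytest.raises(EmptyDatasetError):
            exclude_zero_reference(ss, "NFL")


class TestRunGrid:
    def test_grid_has_400_cells(self, small_grid):
        assert len(small_grid.candidates) == 400

    def test_cells_are_populated_or_marked_failed(self, small_grid):
        for c in small_grid.candidates:
            assert c.ok or c.error is not None

    def test_winner_uses_scatter_correction_on_scattered_data(self, small_grid):
        """The generator applies multiplicative scatter, so the winning
        MPLS-stage treatment should not be a bare no-correction code."""
        best = small_grid.best
        assert best is not None
        assert str(best.mpls_code)[0] in "sdm" or best.mpls_code.numerals[0] > 0

    def test_grid_is_deterministic(self):
        spectra, _ = generate(default_study_config(seed=24, n_samples=30))
        cal = average_replicates(spectra)
        config = GridConfig(n_factors=3, n_groups=5, seed=7)
        a = run_grid(cal, "NFL", config)
        b = run_grid(cal, "NFL", config)
        assert [c.secv for c in a.candidates] == [c.secv for c in b.candidates]
        assert str(a.best.pca_code) == str(b.best.pca_code)
        assert str(a.best.mpls_code) == str(b.best.mpls_code)

    def test_toy_grid_with_oversized_factor_count_records_failures(self):
        spectra, _ = generate(default_study_config(seed=25, n_samples=10))
        cal = average_replicates(spectra)
        report = run_grid(cal, "NFL", GridConfig(n_factors=10, n_groups=5, seed=1))
        assert len(report.candidates) == 400
        # 10 samples cannot support 10 factors in any CV fold
        assert all(c.error is not None for c in report.candidates)
        assert report.best is None


class TestSelectBest:
    def test_single_successful_cell_wins(self, ):
        spectra, _ = generate(default_study_config(seed=26, n_samples=30))
        cal = average_replicates(spectra)
        report = run_grid(cal, "NFL", GridConfig(n_factors=4, n_groups=5, seed=2))
        ok = [c for c in report.candidates if c.ok]
        solo = GridReport(
            constituent="NFL", candidates=[ok[0]], config=report.config,
            n_input_samples=report.n_input_samples,
        )
        assert select_best(solo) is ok[0]

    def test_selection_matches_sort_oracle_and_ignores_order(self):
        spectra, _ = generate(default_study_config(seed=27, n_samples=30))
        cal = average_replicates(spectra)
        report = run_grid(cal, "NFL", GridConfig(n_factors=4, n_groups=5, seed=3))
        ok = [c for c in report.candidates if c.ok]
        oracle = sorted(ok, key=_selection_key)[0]
        assert select_best(report) is oracle
        shuffled = GridReport(
            constituent="NFL",
            candidates=list(np.random.default_rng(0).permutation(report.candidates)),
            config=report.config,
            n_input_samples=report.n_input_samples,
        )
        winner = select_best(shuffled)
        assert (str(winner.pca_code), str(winner.mpls_code)) == (
            str(oracle.pca_code), str(oracle.mpls_code)
        )

    def test_no_successful_cell_is_a_selection_error(self):
        report = GridReport(
            constituent="NFL", candidates=[], config=GridConfig(), n_input_samples=0
        )
        with pytest.raises(SelectionError):
            select_best(report)
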