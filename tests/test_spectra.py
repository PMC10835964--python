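"""Spectra containers, CSV round trips, replicate averaging, splice correction."""

import numpy as np
import pandas as pd
import pytest

import nirleaf as nl
from nirleaf.exceptions import (
    ConfigurationError,
    FormatError,
    GridMismatchError,
    SpectraValidationError,
)


def _set(grid, values, **meta_overrides):
    """One-spectrum SpectraSet helper."""
    meta = {"sample_id": "A", "replicate": 1, "state": "dried", "group": None}
    meta.update(meta_overrides)
    return nl.SpectraSet(grid, pd.DataFrame([meta]), np.atleast_2d(values))


class TestSpectralGrid:
    def test_default_grid_has_2151_points(self):
        assert nl.SpectralGrid().n_points == 2151
        assert nl.SpectralGrid().wavelengths()[[0, -1]].tolist() == [350.0, 2500.0]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start_nm=500, end_nm=400),
            dict(step_nm=-1),
            dict(splice_points_nm=(300.0,)),
            dict(splice_points_nm=(1800.0, 1000.0)),
            dict(start_nm=350, end_nm=500.5, step_nm=1.0, splice_points_nm=()),
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            nl.SpectralGrid(**kwargs)

    def test_index_of_off_grid_wavelength(self):
        g = nl.SpectralGrid()
        assert g.index_of(1000.0) == 650
        with pytest.raises(ConfigurationError):
            g.index_of(1000.5)


class TestIO:
    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_identity(self, tmp_path, layout):
        grid = nl.SpectralGrid(350, 360, 1, splice_points_nm=())
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {
                "sample_id": ["A", "A", "B"],
                "replicate": [1, 2, 1],
                "state": ["fresh", "fresh", "dried"],
                "group": [None, None, "control"],
            }
        )
        s = nl.SpectraSet(grid, meta, rng.uniform(0.1, 0.9, size=(3, 11)))
        path = tmp_path / f"s_{layout}.csv"
        nl.write_spectra(s, path, layout=layout)
        back = nl.read_spectra(path, layout=layout, splice_points_nm=())
        assert back.equals(s)

    def test_long_file_grid_arithmetic(self, tmp_path):
        # 2 spectra over the full grid -> 2151 columns
        grid = nl.SpectralGrid()
        vals = np.full((2, grid.n_points), 0.5)
        meta = pd.DataFrame(
            {"sample_id": ["A", "B"], "replicate": [1, 1],
             "state": ["fresh", "fresh"], "group": [None, None]}
        )
        s = nl.SpectraSet(grid, meta, vals)
        path = tmp_path / "s.csv"
        nl.write_spectra(s, path, layout="long")
        back = nl.read_spectra(path, layout="long")
        assert len(back) == 2 and back.grid.n_points == 2151

    def test_out_of_range_reflectance_names_row(self, tmp_path):
        grid = nl.SpectralGrid(350, 352, 1, splice_points_nm=())
        df = pd.DataFrame(
            {"sample_id": ["X"], "replicate": [1], "state": ["fresh"],
             "group": [None], "350": [0.5], "351": [1.7], "352": [0.5]}
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SpectraValidationError, match="X"):
            nl.read_spectra(path, layout="wide", splice_points_nm=())

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"foo": [1]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            nl.read_spectra(path, layout="wide")

    def test_ragged_long_grid_rejected(self, tmp_path):
        rows = [
            {"sample_id": "A", "replicate": 1, "state": "fresh", "group": None,
             "wavelength_nm": w, "reflectance": 0.5}
            for w in (350, 351, 352)
        ] + [
            {"sample_id": "B", "replicate": 1, "state": "fresh", "group": None,
             "wavelength_nm": w, "reflectance": 0.5}
            for w in (350, 352)  # missing 351
        ]
        path = tmp_path / "ragged.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(GridMismatchError):
            nl.read_spectra(path, layout="long", splice_points_nm=())

    def test_duplicate_key_rejected(self):
        grid = nl.SpectralGrid(350, 352, 1, splice_points_nm=())
        meta = pd.DataFrame(
            {"sample_id": ["A", "A"], "replicate": [1, 1],
             "state": ["fresh", "fresh"], "group": [None, None]}
        )
        with pytest.raises(SpectraValidationError):
            nl.SpectraSet(grid, meta, np.full((2, 3), 0.5))


class TestReferenceTable:
    def test_levels_validated(self):
        df = pd.DataFrame(
            {"sample_id": ["A"], "species": ["x"], "leaf_N": [2.0],
             "leaf_P": [1.5], "fert_N_level": [7.0], "fert_P_level": [1.0]}
        )
        with pytest.raises(SpectraValidationError):
            nl.ReferenceTable(df)

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"sample_id": ["A", "B"], "species": ["x", "y"],
             "leaf_N": [2.0, 3.0], "leaf_P": [1.5, 2.5],
             "fert_N_level": [5.0, np.nan], "fert_P_level": [1.0, np.nan]}
        )
        ref = nl.ReferenceTable(df)
        path = tmp_path / "ref.csv"
        nl.write_reference(ref, path)
        assert nl.read_reference(path).equals(ref)


class TestAverageReplicates:
    def test_mean_and_replicate_reset(self):
        grid = nl.SpectralGrid(350, 352, 1, splice_points_nm=())
        meta = pd.DataFrame(
            {"sample_id": ["A"] * 3, "replicate": [1, 2, 3],
             "state": ["fresh"] * 3, "group": [None] * 3}
        )
        vals = np.array([[0.1] * 3, [0.2] * 3, [0.3] * 3])
        out = nl.average_replicates(nl.SpectraSet(grid, meta, vals))
        assert len(out) == 1
        assert out.meta.loc[0, "replicate"] == 1
        np.testing.assert_allclose(out.values, 0.2)

    def test_idempotent_and_bounded(self):
        grid = nl.SpectralGrid(350, 360, 1, splice_points_nm=())
        rng = np.random.default_rng(3)
        meta = pd.DataFrame(
            {"sample_id": ["A", "A", "B"], "replicate": [1, 2, 1],
             "state": ["fresh", "fresh", "fresh"], "group": [None] * 3}
        )
        vals = rng.uniform(0.2, 0.8, size=(3, 11))
        s = nl.SpectraSet(grid, meta, vals)
        once = nl.average_replicates(s)
        twice = nl.average_replicates(once)
        assert twice.equals(once)
        # means stay within the per-wavelength replicate envelope
        assert np.all(once.values[0] <= vals[:2].max(axis=0) + 1e-15)
        assert np.all(once.values[0] >= vals[:2].min(axis=0) - 1e-15)


class TestSpliceCorrect:
    def test_flat_step_removed(self):
        grid = nl.SpectralGrid(998, 1004, 1, splice_points_nm=(1000.0,))
        vals = np.where(grid.wavelengths() <= 1000.0, 0.50, 0.55)
        out = nl.splice_correct(_set(grid, vals))
        np.testing.assert_allclose(out.values, 0.50)

    def test_continuous_spectrum_unchanged(self):
        # no step across the boundary (equal adjacent values) -> zero offset
        grid = nl.SpectralGrid(350, 360, 1, splice_points_nm=(355.0,))
        vals = np.array([0.40, 0.42, 0.44, 0.46, 0.48, 0.50, 0.50, 0.48, 0.46, 0.44, 0.42])
        s = _set(grid, vals)
        assert nl.splice_correct(s).equals(s)

    def test_two_splices_compose(self):
        # offsets +0.05 then -0.02: final segment shifts by -0.03 net
        grid = nl.SpectralGrid(350, 2500, 50, splice_points_nm=(1000.0, 1800.0))
        wl = grid.wavelengths()
        vals = np.full(grid.n_points, 0.50)
        vals[wl > 1000.0] += 0.05
        vals[wl > 1800.0] += -0.02
        out = nl.splice_correct(_set(grid, vals))
        np.testing.assert_allclose(out.values, 0.50)
        raw_final = 0.50 + 0.05 - 0.02
        np.testing.assert_allclose(out.values[0, wl > 1800.0] - raw_final, -0.03)

    def test_within_segment_differences_preserved(self):
        grid = nl.SpectralGrid(350, 2500, 10, splice_points_nm=(1000.0, 1800.0))
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.3, 0.7, size=grid.n_points)
        out = nl.splice_correct(_set(grid, vals))
        wl = grid.wavelengths()
        for lo, hi in ((None, 1000.0), (1000.0, 1800.0), (1800.0, None)):
            m = np.ones_like(wl, dtype=bool)
            if lo is not None:
                m &= wl > lo
            if hi is not None:
                m &= wl <= hi
            np.testing.assert_allclose(
                np.diff(out.values[0, m]), np.diff(vals[m]), atol=1e-12
            )

    def test_off_grid_splice_is_configuration_error(self):
        grid = nl.SpectralGrid(350, 360, 1, splice_points_nm=())
        s = _set(grid, np.full(grid.n_points, 0.5))
        with pytest.raises(ConfigurationError):
            nl.splice_correct(s, splice_points_nm=(355.5,))

    def test_clipping_into_unit_interval(self):
        # offset correction would push the last point to 1.09; it is clipped
        grid = nl.SpectralGrid(350, 354, 1, splice_points_nm=(352.0,))
        vals = np.array([[0.99, 0.99, 0.99, 0.50, 0.60]])
        out = nl.splice_correct(_set(grid, vals))
        assert np.all(out.values <= 1.0) and np.all(out.values > 0.0)
        assert out.values[0, -1] == 1.0
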