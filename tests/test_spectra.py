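"""Absorbance arithmetic, replicate averaging, pigment spectra and I/O."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strawspec import (
    FormatError,
    GridMismatchError,
    RawIntensityRecord,
    SpectralDataset,
    SpectralDomainError,
    WavelengthGrid,
    average_replicates,
    compute_absorbance,
    read_dataset,
    transmittance_absorbance,
    write_dataset,
)


def make_record(grid, sample, white, dark):
    n = len(grid)
    return RawIntensityRecord(
        wavelengths=grid,
        sample=np.full(n, float(sample)),
        white=np.full(n, float(white)),
        dark=np.full(n, float(dark)),
    )


class TestWavelengthGrid:
    def test_rejects_decreasing_and_nonuniform(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0, 498.0, 496.0]))
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0, 502.0, 505.0]))

    def test_step_and_window(self, vis_grid):
        assert vis_grid.step_nm == 2.0
        assert len(vis_grid) == 240  # (978 - 500) / 2 + 1
        idx = vis_grid.window_indices(834.0, 872.0)
        assert idx.size == 20


class TestComputeAbsorbance:
    def test_identity_when_sample_equals_white(self, small_grid):
        rec = make_record(small_grid, 800.0, 800.0, 100.0)
        assert np.allclose(compute_absorbance(rec), 0.0)

    def test_one_decade_attenuation(self, small_grid):
        rec = make_record(small_grid, 200.0, 1100.0, 100.0)  # net 100 vs 1000
        assert np.allclose(compute_absorbance(rec), 1.0)

    def test_hand_worked_value(self, small_grid):
        rec = make_record(small_grid, 250.0, 1200.0, 200.0)
        expected = -math.log10(50.0 / 1000.0)
        assert np.allclose(compute_absorbance(rec), expected, rtol=0, atol=1e-12)

    def test_nonpositive_net_sample_is_domain_error_naming_wavelength(self, small_grid):
        sample = np.full(20, 500.0)
        sample[3] = 90.0  # below dark
        rec = RawIntensityRecord(small_grid, sample, np.full(20, 1000.0),
                                 np.full(20, 100.0))
        with pytest.raises(SpectralDomainError, match=f"{small_grid.values[3]:g}"):
            compute_absorbance(rec)

    def test_nonpositive_net_white_rejected_at_construction(self, small_grid):
        with pytest.raises(SpectralDomainError):
            make_record(small_grid, 500.0, 100.0, 100.0)

    @given(scale=st.floats(min_value=0.01, max_value=1e4),
           offset=st.floats(min_value=0.0, max_value=500.0))
    def test_invariant_to_common_rescaling(self, scale, offset):
        grid = WavelengthGrid(np.linspace(500.0, 538.0, 20))
        rng = np.random.default_rng(7)
        net_s = rng.uniform(50.0, 500.0, 20)
        net_w = rng.uniform(600.0, 1200.0, 20)
        base = RawIntensityRecord(grid, net_s + offset, net_w + offset,
                                  np.full(20, offset))
        scaled = RawIntensityRecord(grid, scale * net_s + offset,
                                    scale * net_w + offset, np.full(20, offset))
        assert np.allclose(compute_absorbance(base), compute_absorbance(scaled),
                           rtol=1e-10, atol=1e-12)


class TestAverageReplicates:
    def test_k_copies_equal_single(self, small_grid):
        rec = make_record(small_grid, 300.0, 1000.0, 50.0)
        for k in (1, 2, 4):
            assert np.allclose(average_replicates([rec] * k),
                               compute_absorbance(rec), rtol=0, atol=0)

    def test_mean_of_constant_absorbances(self, small_grid):
        zero = make_record(small_grid, 1000.0, 1000.0, 0.0)       # A = 0
        one = make_record(small_grid, 100.0, 1000.0, 0.0)         # A = 1
        assert np.allclose(average_replicates([zero, one]), 0.5)

    def test_matches_mean_of_individual_absorbances(self, small_grid):
        rng = np.random.default_rng(3)
        recs = [
            RawIntensityRecord(small_grid, rng.uniform(200, 900, 20),
                               np.full(20, 1000.0), np.full(20, 50.0))
            for _ in range(4)
        ]
        manual = np.mean([compute_absorbance(r) for r in recs], axis=0)
        assert np.allclose(average_replicates(recs), manual, rtol=0, atol=1e-12)

    def test_empty_and_mismatched_grids_error(self, small_grid, vis_grid):
        with pytest.raises(ValueError):
            average_replicates([])
        a = make_record(small_grid, 300.0, 1000.0, 50.0)
        b = make_record(vis_grid, 300.0, 1000.0, 50.0)
        with pytest.raises(GridMismatchError):
            average_replicates([a, b])


class TestTransmittanceAbsorbance:
    """The pigment formula is kept with its printed sign convention:
    -log10(I0/It) is negative for absorbing samples."""

    def test_equal_intensities_give_zero(self, small_grid):
        spec = transmittance_absorbance(small_grid, np.full(20, 500.0),
                                        np.full(20, 500.0))
        assert np.allclose(spec.absorbance, 0.0)

    def test_tenfold_reference_gives_minus_one(self, small_grid):
        spec = transmittance_absorbance(small_grid, np.full(20, 1000.0),
                                        np.full(20, 100.0))
        assert np.allclose(spec.absorbance, -1.0)

    def test_hand_worked_value(self, small_grid):
        spec = transmittance_absorbance(small_grid, np.full(20, 800.0),
                                        np.full(20, 400.0), "anthocyanin")
        assert np.allclose(spec.absorbance, -math.log10(2.0), atol=1e-12)
        assert spec.pigment_name == "anthocyanin"

    def test_nonpositive_intensity_is_domain_error(self, small_grid):
        bad = np.full(20, 500.0)
        bad[0] = 0.0
        with pytest.raises(SpectralDomainError):
            transmittance_absorbance(small_grid, bad, np.full(20, 400.0))


class TestDatasetIO:
    def make_dataset(self, n=5, p=10, seed=0):
        rng = np.random.default_rng(seed)
        return SpectralDataset(
            wavelengths=WavelengthGrid(500.0 + 2.0 * np.arange(p)),
            absorbance=rng.uniform(0.1, 1.5, size=(n, p)),
            ssc=rng.uniform(7.0, 13.0, size=n),
            variety=["white"] * n,
            sample_id=[f"w{i}" for i in range(n)],
        )

    def test_round_trip_is_lossless(self, tmp_path):
        ds = self.make_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.wavelengths == ds.wavelengths
        assert np.array_equal(back.absorbance, ds.absorbance)
        assert np.array_equal(back.ssc, ds.ssc)
        assert back.variety == ds.variety
        assert back.sample_id == ds.sample_id

    def test_full_visnir_grid_round_trip(self, tmp_path, vis_grid):
        ds = SpectralDataset(vis_grid, np.ones((1, 240)), [10.0], ["white"], ["a"])
        path = tmp_path / "one.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.n_samples == 1 and len(back.wavelengths) == 240

    def test_decreasing_wavelength_header_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,variety,ssc,504.0,502.0,500.0\n"
                        "a,white,10.0,1.0,1.0,1.0\n")
        with pytest.raises(FormatError, match="increasing"):
            read_dataset(path)

    def test_missing_ssc_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,variety,500.0,502.0\na,white,1.0,1.0\n")
        with pytest.raises(FormatError, match="ssc"):
            read_dataset(path)

    def test_ragged_row_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,variety,ssc,500.0,502.0\n"
                        "a,white,10.0,1.0,1.0\n"
                        "b,white,10.0,1.0\n")
        with pytest.raises(FormatError):
            read_dataset(path)


class TestSpectralDataset:
    def test_invariants_enforced(self, small_grid):
        with pytest.raises(ValueError, match="unique"):
            SpectralDataset(small_grid, np.ones((2, 20)), [10.0, 9.0],
                            ["w", "w"], ["dup", "dup"])
        with pytest.raises(ValueError, match="positive"):
            SpectralDataset(small_grid, np.ones((1, 20)), [-1.0], ["w"], ["a"])

    def test_concat_and_subset(self, small_grid):
        a = SpectralDataset(small_grid, np.ones((2, 20)), [10.0, 9.0],
                            ["w", "w"], ["a", "b"])
        b = SpectralDataset(small_grid, np.zeros((1, 20)), [8.0], ["r"], ["c"])
        both = SpectralDataset.concat([a, b])
        assert both.n_samples == 3 and both.varieties == ["w", "r"]
        sub = both.subset([2])
        assert sub.sample_id == ["c"] and sub.ssc[0] == 8.0
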