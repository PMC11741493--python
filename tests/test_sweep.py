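"""Sweep engine: region rules, grid accounting, aggregation, exceedance."""

import numpy as np
import pandas as pd
import pytest

from contrastsweep.relaxometry import AcquisitionParams
from contrastsweep.sweep import (ContrastRegion, IOVThresholds, MetricRecord,
                                 SweepGrid, build_grid, classify_region,
                                 iov_exceedance, records_to_frame,
                                 relative_offsets, run_sweep,
                                 summarize_regions)


class TestClassifyRegion:
    @pytest.mark.parametrize("tr,te,region", [
        (5254, 145, ContrastRegion.T2W),   # strongly T2-weighted reference
        (1000, 40, ContrastRegion.PDW),    # boundary: TR >= 1000, TE <= 40
        (900, 60, ContrastRegion.MIXED),
        (999, 40, ContrastRegion.T1W),
        (1000, 41, ContrastRegion.T2W),
        (100, 5, ContrastRegion.T1W),
    ])
    def test_region_rules(self, tr, te, region):
        assert classify_region(tr, te) is region

    def test_total_function_on_grid(self):
        grid = SweepGrid(include_mixed=True)
        regions = {r for _, r in build_grid(grid)}
        assert regions == set(ContrastRegion)


class TestBuildGrid:
    def test_default_grid_has_216_points(self):
        assert len(build_grid(SweepGrid())) == 216

    def test_with_mixed_288_points(self):
        assert len(build_grid(SweepGrid(include_mixed=True))) == 288

    def test_each_used_region_has_72_points(self):
        points = build_grid(SweepGrid())
        counts = {}
        for _, region in points:
            counts[region] = counts.get(region, 0) + 1
        assert counts == {ContrastRegion.T1W: 72, ContrastRegion.T2W: 72,
                          ContrastRegion.PDW: 72}

    def test_ordering_tr_major(self):
        points = build_grid(SweepGrid())
        trs = [p.tr for p, _ in points]
        assert trs == sorted(trs)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError, match="te_values"):
            SweepGrid(te_values=[])

    def test_non_increasing_values_rejected(self):
        with pytest.raises(ValueError, match="tr_values"):
            SweepGrid(tr_values=[100, 100, 200])


def _record(structure="s", tr=1500.0, te=100.0, dsc=1.0, hd=0.0,
            defined=True):
    return MetricRecord(structure=structure, tr_ms=tr, te_ms=te,
                        region=classify_region(tr, te), dsc=dsc,
                        hd95_mm=hd, hd95_defined=defined)


class TestRelativeOffsets:
    @pytest.mark.parametrize("tr,te,expected", [
        (1535.0, 212.0, (0.0, 0.0)),
        (1500.0, 200.0, (-35.0, -12.0)),
        (5000.0, 5.0, (3465.0, -207.0)),
    ])
    def test_offsets(self, tr, te, expected):
        anchor = AcquisitionParams(tr=1535.0, te=212.0)
        (rec,) = relative_offsets([_record(tr=tr, te=te)], anchor)
        assert (rec.delta_tr_ms, rec.delta_te_ms) == expected


class TestSummarize:
    def test_constant_records(self):
        recs = [_record(dsc=0.9, hd=2.0) for _ in range(5)]
        row = summarize_regions(recs).iloc[0]
        assert row.dsc_mean == row.dsc_median == row.dsc_min == row.dsc_max \
            == 0.9
        assert row.hd95_mean == row.hd95_max == 2.0

    def test_two_values(self):
        recs = [_record(dsc=0.8, te=100.0), _record(dsc=0.9, te=120.0)]
        row = summarize_regions(recs).iloc[0]
        assert row.dsc_mean == pytest.approx(0.85)
        assert (row.dsc_min, row.dsc_max) == (0.8, 0.9)

    def test_undefined_hd95_counted_separately(self):
        recs = [_record(hd=1.0, te=100.0), _record(hd=3.0, te=120.0),
                _record(hd=float("nan"), defined=False, te=140.0)]
        row = summarize_regions(recs).iloc[0]
        assert row.n_points == 3
        assert row.n_hd95_undefined == 1
        assert row.hd95_mean == pytest.approx(2.0)  # over defined values only

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            summarize_regions([])


class TestExceedance:
    def thresholds(self):
        return IOVThresholds(dsc={"s": 0.8}, hd95_mm={"s": 3.0})

    def test_all_better_than_cutoff(self):
        recs = [_record(dsc=0.9, hd=1.0) for _ in range(4)]
        df = iov_exceedance(recs, self.thresholds())
        overall = df[df.scope == "overall"].iloc[0]
        assert overall.dsc_exceedance == 1.0
        assert overall.hd95_exceedance == 1.0

    def test_bound_thresholds(self):
        recs = [_record(dsc=0.5, hd=2.0) for _ in range(4)]
        loose = IOVThresholds(dsc={"s": 1e-9}, hd95_mm={"s": 1e9})
        df = iov_exceedance(recs, loose)
        assert (df.dsc_exceedance == 1.0).all()
        assert (df.hd95_exceedance == 1.0).all()
        strict = IOVThresholds(dsc={"s": 1.0}, hd95_mm={"s": 1e-9})
        df = iov_exceedance(recs, strict)
        assert (df.dsc_exceedance == 0.0).all()
        assert (df.hd95_exceedance == 0.0).all()

    def test_counting_fraction(self):
        dscs = [0.9, 0.85, 0.95, 0.81] + [0.5] * 6  # 4 of 10 above 0.8
        recs = [_record(dsc=d, te=100.0 + i) for i, d in enumerate(dscs)]
        df = iov_exceedance(recs, self.thresholds())
        assert df[df.scope == "overall"].iloc[0].dsc_exceedance == 0.4

    def test_inclusive_comparisons(self):
        recs = [_record(dsc=0.8, hd=3.0)]
        df = iov_exceedance(recs, self.thresholds())
        assert (df.dsc_exceedance == 1.0).all()
        assert (df.hd95_exceedance == 1.0).all()

    def test_undefined_hd95_never_exceeds(self):
        recs = [_record(hd=float("nan"), defined=False)]
        df = iov_exceedance(recs, self.thresholds())
        assert (df.hd95_exceedance == 0.0).all()

    def test_missing_structure_named(self):
        recs = [_record(structure="other")]
        with pytest.raises(KeyError, match="other"):
            iov_exceedance(recs, self.thresholds())

    def test_default_thresholds_are_published_iov_levels(self):
        iov = IOVThresholds()
        assert iov.dsc == {"parotid_l": 0.83, "parotid_r": 0.84,
                           "submandibular_l": 0.75, "submandibular_r": 0.78}
        assert iov.hd95_mm == {"parotid_l": 4.9, "parotid_r": 5.1,
                               "submandibular_l": 3.1, "submandibular_r": 3.1}


@pytest.fixture(scope="module")
def tiny_setup():
    """Tiny phantom + truth for fast sweep contract tests."""
    from contrastsweep.phantom import PhantomSpec, Structure, Tissue, \
        build_phantom
    gland = Tissue("g", 1100.0, 120.0, 0.9)
    spec = PhantomSpec(
        shape=(24, 24, 8), spacing=(3.0, 3.0, 5.0),
        head_radii_mm=(32.0, 32.0, 19.0),
        structures=[Structure("s", 1, (0.0, 0.0, 0.0), (12.0, 12.0, 10.0),
                              gland)],
        fat_center_mm=(0.0, 24.0, 0.0), fat_radii_mm=(6.0, 4.0, 6.0),
        noise_sigma=(0.0, 0.0, 0.0))
    maps, labels = build_phantom(spec, seed=0)
    truth = {"s": labels == 1}
    return spec, maps, truth


SMALL_GRID = SweepGrid(tr_values=[500.0, 1000.0, 2000.0],
                       te_values=[20.0, 60.0, 120.0])


class TestRunSweep:
    def test_oracle_segmenter_is_perfect(self, tiny_setup):
        spec, maps, truth = tiny_setup

        def oracle(image, spacing):
            return truth["s"].astype(np.int32)

        records = run_sweep(maps, oracle, SMALL_GRID, truth, {"s": 1})
        assert len(records) == 7  # 3x3 minus the two (500, 60/120) mixed points
        assert all(r.dsc == 1.0 and r.hd95_mm == 0.0 for r in records)

    def test_empty_segmenter_yields_sentinels(self, tiny_setup):
        spec, maps, truth = tiny_setup

        def empty(image, spacing):
            return np.zeros(image.shape, np.int32)

        records = run_sweep(maps, empty, SMALL_GRID, truth, {"s": 1})
        assert all(r.dsc == 0.0 and not r.hd95_defined for r in records)

    def test_raising_segmenter_never_aborts(self, tiny_setup):
        spec, maps, truth = tiny_setup

        def broken(image, spacing):
            raise RuntimeError("model exploded")

        records = run_sweep(maps, broken, SMALL_GRID, truth, {"s": 1})
        assert len(records) == 7
        assert all("model exploded" in r.note for r in records)
        assert all(r.dsc == 0.0 and not r.hd95_defined for r in records)

    def test_misaligned_segmenter_recorded_as_failure(self, tiny_setup):
        spec, maps, truth = tiny_setup

        def misaligned(image, spacing):
            return np.zeros((2, 2, 2), np.int32)

        records = run_sweep(maps, misaligned, SMALL_GRID, truth, {"s": 1})
        assert all("shape" in r.note for r in records)

    def test_grid_accounting_and_delta_fields(self, tiny_setup):
        spec, maps, truth = tiny_setup

        def oracle(image, spacing):
            return truth["s"].astype(np.int32)

        records = run_sweep(maps, oracle, SMALL_GRID, truth, {"s": 1})
        frame = records_to_frame(records)
        assert len(frame) == len(build_grid(SMALL_GRID)) * 1
        anchor = SMALL_GRID.anchor
        np.testing.assert_array_equal(frame.delta_tr_ms,
                                      frame.tr_ms - anchor.tr)

    def test_misaligned_truth_rejected(self, tiny_setup):
        spec, maps, truth = tiny_setup
        with pytest.raises(ValueError, match="ground truth"):
            run_sweep(maps, lambda i, s: None, SMALL_GRID,
                      {"s": np.zeros((2, 2, 2), bool)}, {"s": 1})
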