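"""Unit tests for blank filtering, group comparison, and report export."""

import math

import pandas as pd
import pytest

from airmark.grouping import GroupTable, UnifiedCompound
from airmark.markers import (
    ComparisonReport,
    blank_filter,
    compare_groups,
    export_report,
)
from airmark.spectra import Spectrum

SPEC_A = Spectrum(((43.0180, 1.0), (58.0413, 0.4), (42.0100, 0.2)))
SPEC_B = Spectrum(((57.0699, 1.0), (71.0855, 0.5), (43.0542, 0.3)))


def make_table(group, compounds, n_samples=4, prefix=None):
    prefix = prefix or group
    sample_ids = [f"{prefix}{i + 1}" for i in range(n_samples)]
    table = GroupTable(group=group, sample_ids=sample_ids)
    for name, rt, areas, spectrum in compounds:
        area_map = {sample_ids[i]: a for i, a in enumerate(areas) if a is not None}
        c = UnifiedCompound(
            name=name,
            rt_mean=rt,
            combined_spectrum=spectrum,
            areas=area_map,
            n_merged=len(area_map),
            names={name: len(area_map)},
        )
        c.fraction = len(area_map) / n_samples
        table.compounds.append(c)
    table.compounds.sort(key=lambda c: c.rt_mean)
    table.finalized = True
    return table


class TestBlankFilter:
    def test_low_ratio_flagged(self):
        sample = make_table("L", [("bg", 10.0, [400.0] * 4, SPEC_A)])
        blank = make_table("blank", [("bg", 10.0, [100.0], SPEC_A)], n_samples=1, prefix="B")
        blank_filter(sample, blank, ratio_min=5.0)
        assert sample.compounds[0].blank_disqualified

    def test_high_ratio_kept(self):
        sample = make_table("L", [("real", 10.0, [600.0] * 4, SPEC_A)])
        blank = make_table("blank", [("real", 10.0, [100.0], SPEC_A)], n_samples=1, prefix="B")
        blank_filter(sample, blank, ratio_min=5.0)
        assert not sample.compounds[0].blank_disqualified

    def test_boundary_is_disqualifying(self):
        # exactly 5x the blank does NOT exceed the threshold
        sample = make_table("L", [("edge", 10.0, [500.0] * 4, SPEC_A)])
        blank = make_table("blank", [("edge", 10.0, [100.0], SPEC_A)], n_samples=1, prefix="B")
        blank_filter(sample, blank, ratio_min=5.0)
        assert sample.compounds[0].blank_disqualified

    def test_absent_from_blank_kept(self):
        sample = make_table("L", [("unique", 10.0, [50.0] * 4, SPEC_A)])
        blank = make_table("blank", [("other", 20.0, [1e6], SPEC_B)], n_samples=1, prefix="B")
        blank_filter(sample, blank, ratio_min=5.0)
        assert not sample.compounds[0].blank_disqualified

    def test_spectral_mismatch_not_aligned_to_blank(self):
        sample = make_table("L", [("co_eluting", 10.0, [50.0] * 4, SPEC_A)])
        blank = make_table("blank", [("bg", 10.0, [1e6], SPEC_B)], n_samples=1, prefix="B")
        blank_filter(sample, blank, ratio_min=5.0)
        assert not sample.compounds[0].blank_disqualified

    def test_monotone_in_ratio(self):
        def flagged(ratio):
            sample = make_table("L", [("c", 10.0, [700.0] * 4, SPEC_A)])
            blank = make_table(
                "blank", [("c", 10.0, [100.0], SPEC_A)], n_samples=1, prefix="B"
            )
            blank_filter(sample, blank, ratio_min=ratio)
            return sample.compounds[0].blank_disqualified

        results = [flagged(r) for r in (2.0, 5.0, 7.0, 10.0)]
        assert results == sorted(results)  # once flagged, stays flagged

    def test_requires_finalized_tables(self):
        sample = make_table("L", [])
        sample.finalized = False
        blank = make_table("blank", [], n_samples=1, prefix="B")
        with pytest.raises(ValueError):
            blank_filter(sample, blank)


def two_group_tables(focal_areas, ref_areas, *, focal_frac_areas=None):
    focal = make_table("H", [("c", 10.0, focal_areas, SPEC_A)])
    ref = make_table("L", [("c", 10.0, ref_areas, SPEC_A)]) if ref_areas else make_table("L", [])
    return focal, ref


class TestCompareGroups:
    def test_clear_difference_significant(self):
        focal, ref = two_group_tables([1000.0] * 4, [10.0, 11.0, 9.0, 10.0])
        report = compare_groups(focal, ref)
        (res,) = report.results
        assert res.status == "significant"
        assert res.p_value < 0.05
        assert res.fold > 50

    def test_direction_matters(self):
        focal, ref = two_group_tables([10.0, 11.0, 9.0, 10.0], [1000.0] * 4)
        report = compare_groups(focal, ref)
        assert report.results[0].status == "not_significant"

    def test_self_comparison_not_significant(self):
        focal, _ = two_group_tables([100.0, 110.0, 90.0, 105.0], None)
        ref = make_table("L", [("c", 10.0, [100.0, 110.0, 90.0, 105.0], SPEC_A)])
        report = compare_groups(focal, ref)
        assert report.results[0].status == "not_significant"

    def test_absent_reference_counts_as_zeros(self):
        focal, ref = two_group_tables([1000.0, 900.0, 1100.0, 1000.0], None)
        report = compare_groups(focal, ref)
        (res,) = report.results
        assert res.status == "significant"
        assert math.isinf(res.fold)
        assert res.mean_reference == 0.0

    def test_missing_focal_samples_zero_padded(self):
        # detected in 3 of 4 focal samples: the absent sample enters as 0,
        # not as a shorter vector
        focal = make_table("H", [("c", 10.0, [1000.0, 900.0, 1100.0, None], SPEC_A)])
        ref = make_table("L", [("c", 10.0, [10.0, 11.0, 9.0, 10.0], SPEC_A)])
        report = compare_groups(focal, ref)
        (res,) = report.results
        assert res.fraction_focal == 0.75
        assert res.p_value is not None
        # padded vector {1000, 900, 1100, 0} has much higher variance than
        # the unpadded triple; the test still flags the contrast
        assert res.status in ("significant", "possibly_significant")

    def test_blank_disqualified_focal_reported(self):
        focal, ref = two_group_tables([1000.0] * 4, [10.0] * 4)
        focal.compounds[0].blank_disqualified = True
        report = compare_groups(focal, ref)
        assert report.results[0].status == "disqualified_blank"

    def test_blank_disqualified_reference_treated_as_zero(self):
        focal, ref = two_group_tables([1000.0] * 4, [10.0, 11.0, 9.0, 10.0])
        ref.compounds[0].blank_disqualified = True
        report = compare_groups(focal, ref)
        (res,) = report.results
        assert res.mean_reference == 0.0
        assert res.status == "significant"

    def test_low_focal_fraction_disqualified(self):
        focal = make_table("H", [("c", 10.0, [1000.0, 900.0, None, None], SPEC_A)])
        ref = make_table("L", [])
        report = compare_groups(focal, ref)
        assert report.results[0].status == "disqualified_fraction"

    def test_low_reference_fraction_ignored(self):
        focal, _ = two_group_tables([1000.0] * 4, None)
        ref = make_table("L", [("c", 10.0, [500.0, None, None, None], SPEC_A)])
        report = compare_groups(focal, ref)
        (res,) = report.results
        assert res.fraction_reference == 0.0
        assert res.mean_reference == 0.0

    def test_single_detection_has_no_p_value(self):
        focal = make_table("H", [("c", 10.0, [1000.0, None, None, None], SPEC_A)])
        ref = make_table("L", [])
        report = compare_groups(focal, ref, fraction_focal_min=0.2)
        (res,) = report.results
        assert res.p_value is None
        assert res.status == "not_significant"

    def test_every_focal_compound_reported_once(self):
        focal = make_table(
            "H",
            [
                ("a", 5.0, [100.0] * 4, SPEC_A),
                ("b", 10.0, [100.0] * 4, SPEC_B),
                ("c", 15.0, [100.0] * 4, SPEC_A),
            ],
        )
        ref = make_table("L", [("b", 10.0, [90.0] * 4, SPEC_B)])
        report = compare_groups(focal, ref)
        assert sorted(r.name for r in report.results) == ["a", "b", "c"]

    def test_results_sorted_by_p_value(self):
        focal = make_table(
            "H",
            [
                ("weak", 5.0, [100.0, 120.0, 80.0, 110.0], SPEC_A),
                ("strong", 10.0, [1000.0] * 4, SPEC_B),
            ],
        )
        ref = make_table(
            "L",
            [
                ("weak", 5.0, [90.0, 100.0, 85.0, 95.0], SPEC_A),
                ("strong", 10.0, [10.0, 11.0, 9.0, 10.0], SPEC_B),
            ],
        )
        report = compare_groups(focal, ref)
        ps = [r.p_value for r in report.results]
        assert ps == sorted(ps)
        assert report.results[0].name == "strong"

    def test_welch_variant_runs(self):
        focal, ref = two_group_tables([1000.0, 1100.0, 900.0, 1050.0], [10.0, 11.0, 9.0, 10.0])
        pooled = compare_groups(focal, ref, equal_var=True).results[0].p_value
        focal, ref = two_group_tables([1000.0, 1100.0, 900.0, 1050.0], [10.0, 11.0, 9.0, 10.0])
        welch = compare_groups(focal, ref, equal_var=False).results[0].p_value
        assert pooled != welch

    def test_requires_finalized_tables(self):
        focal, ref = two_group_tables([1.0] * 4, [1.0] * 4)
        focal.finalized = False
        with pytest.raises(ValueError):
            compare_groups(focal, ref)


class TestExport:
    def _report(self):
        focal = make_table(
            "H",
            [
                ("up", 5.0, [1000.0] * 4, SPEC_A),
                ("flat", 10.0, [100.0, 105.0, 95.0, 100.0], SPEC_B),
            ],
        )
        ref = make_table(
            "L",
            [
                ("up", 5.0, [10.0, 11.0, 9.0, 10.0], SPEC_A),
                ("flat", 10.0, [100.0, 104.0, 96.0, 100.0], SPEC_B),
            ],
        )
        return compare_groups(focal, ref)

    def test_tsv_contents(self, tmp_path):
        report = self._report()
        path = tmp_path / "markers.tsv"
        export_report(report, path, "tsv")
        frame = pd.read_csv(path, sep="\t")
        assert list(frame["name"]) == [r.name for r in report.results]
        assert set(frame["status"]) == {r.status for r in report.results}
        # per-sample areas present
        assert "area_H_H1" in frame.columns
        assert frame.loc[frame["name"] == "up", "area_H_H1"].iloc[0] == 1000.0

    def test_xlsx_matches_tsv(self, tmp_path):
        pytest.importorskip("openpyxl")
        report = self._report()
        export_report(report, tmp_path / "m.tsv", "tsv")
        export_report(report, tmp_path / "m.xlsx", "xlsx")
        tsv = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        xlsx = pd.read_excel(tmp_path / "m.xlsx")
        assert list(tsv.columns) == list(xlsx.columns)
        assert list(tsv["name"]) == list(xlsx["name"])
        assert tsv["p_value"].tolist() == pytest.approx(xlsx["p_value"].tolist())

    def test_empty_report_writes_header(self, tmp_path):
        report = ComparisonReport(focal_group="H", reference_group="L", results=[])
        path = tmp_path / "empty.tsv"
        export_report(report, path, "tsv")
        frame = pd.read_csv(path, sep="\t")
        assert "name" in frame.columns and len(frame) == 0

    def test_bh_adjusted_not_below_raw(self, tmp_path):
        report = self._report()
        path = tmp_path / "markers.tsv"
        export_report(report, path, "tsv")
        frame = pd.read_csv(path, sep="\t")
        assert (frame["p_bh"] >= frame["p_value"] - 1e-12).all()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_report(self._report(), tmp_path / "x.csv", "csv")
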