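"""Benchmark statistics: ranking, paired scanner comparison, temporal groups."""
import numpy as np
import pandas as pd
import pytest

from wsiqc.errors import DataError, PairingError
from wsiqc.benchmark import (
    SlideRecord,
    group_stats,
    institute_stats,
    read_records_csv,
    scanner_compare,
    temporal_stats,
    write_records_csv,
    write_report,
)
from wsiqc.pipeline import SlideSummary

CLASSES = ("fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge", "out_of_focus")


def _record(slide_id, any_pct, institute="P1", scanner="S1", date="2020-06-01", rng=None):
    if rng is None:
        per_class = {c: any_pct / len(CLASSES) for c in CLASSES}
    else:
        w = rng.dirichlet(np.ones(len(CLASSES)))
        per_class = {c: any_pct * wi for c, wi in zip(CLASSES, w)}
    summary = SlideSummary(
        slide_id=slide_id,
        tissue_area_mm2=100.0,
        class_pct=per_class,
        artifact_free_pct=100.0 - any_pct,
        any_artifact_pct=any_pct,
    )
    return SlideRecord(slide_id, institute, scanner, date, summary)


def _boxplot_oracle(values):
    """Sort-and-scan quartiles (linear interpolation), whiskers, outliers."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    inside = [x for x in v if q1 - 1.5 * iqr <= x <= q3 + 1.5 * iqr]
    wl, wh = min(inside), max(inside)
    outliers = [x for x in v if x < wl or x > wh]
    return q1, q3, wl, wh, outliers


class TestGroupStats:
    def test_small_group(self):
        recs = [_record(f"s{i}", p) for i, p in enumerate([1.0, 2.0, 3.0])]
        (g,) = institute_stats(recs)
        assert g.mean == pytest.approx(2.0)
        assert g.median == pytest.approx(2.0)
        assert g.n == 3

    def test_random_group_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.gamma(2.0, 3.0, size=50)
        g = group_stats("x", values)
        q1, q3, wl, wh, outliers = _boxplot_oracle(values)
        assert g.q1 == pytest.approx(q1)
        assert g.q3 == pytest.approx(q3)
        assert g.whisker_low == pytest.approx(wl)
        assert g.whisker_high == pytest.approx(wh)
        assert g.outliers == pytest.approx(sorted(outliers))

    def test_outliers_strictly_beyond_whiskers(self):
        rng = np.random.default_rng(8)
        g = group_stats("x", rng.exponential(2.0, 80))
        for o in g.outliers:
            assert o < g.whisker_low or o > g.whisker_high

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            group_stats("x", [])


class TestInstituteRanking:
    def test_ranked_ascending_by_mean(self):
        recs = []
        for inst, mean in [("A", 5.0), ("B", 1.0), ("C", 3.0)]:
            recs += [_record(f"{inst}{i}", mean + d, institute=inst) for i, d in enumerate([-0.5, 0, 0.5])]
        stats = institute_stats(recs)
        assert [g.key for g in stats] == ["B", "C", "A"]

    def test_ranking_stable_under_group_duplication(self):
        rng = np.random.default_rng(9)
        recs = []
        for inst in ("A", "B", "C"):
            base = rng.uniform(1, 10)
            recs += [
                _record(f"{inst}{i}", base + rng.uniform(-1, 1), institute=inst)
                for i in range(5)
            ]
        order = [g.key for g in institute_stats(recs)]
        doubled = recs + [r for r in recs if r.institute_id == "B"]
        assert [g.key for g in institute_stats(doubled)] == order

    def test_per_class_metric(self):
        rng = np.random.default_rng(10)
        recs = [_record(f"s{i}", rng.uniform(0, 10), rng=rng) for i in range(10)]
        stats = institute_stats(recs, metric="fold")
        expected = np.mean([r.summary.class_pct["fold"] for r in recs])
        assert stats[0].mean == pytest.approx(expected)

    def test_group_percentage_conservation(self):
        rng = np.random.default_rng(11)
        recs = [_record(f"s{i}", rng.uniform(0, 30), rng=rng) for i in range(20)]
        per_class_means = [
            institute_stats(recs, metric=c)[0].mean for c in CLASSES
        ]
        free_mean = np.mean([r.summary.artifact_free_pct for r in recs])
        assert sum(per_class_means) + free_mean == pytest.approx(100.0, abs=0.05)


class TestScannerCompare:
    def _paired(self, a_vals, b_vals):
        recs = []
        for i, (a, b) in enumerate(zip(a_vals, b_vals)):
            recs.append(_record(f"s{i}", a, scanner="S1"))
            recs.append(_record(f"s{i}", b, scanner="S2"))
        return recs

    def test_identical_pairs(self):
        cmp = scanner_compare(self._paired([1, 2, 3], [1, 2, 3]))
        assert cmp.mean_diff == 0.0
        assert (cmp.ci_low, cmp.ci_high) == (0.0, 0.0)

    def test_constant_offset(self):
        cmp = scanner_compare(self._paired([1, 2, 3], [3, 4, 5]))
        assert cmp.mean_diff == pytest.approx(2.0)
        assert cmp.ci_low == pytest.approx(2.0)
        assert cmp.ci_high == pytest.approx(2.0)

    def test_closed_form_t_interval(self):
        # diffs 1..5: mean 3, sd sqrt(2.5), t_{0.975,4} = 2.7764451052
        a = [10.0, 10.0, 10.0, 10.0, 10.0]
        b = [11.0, 12.0, 13.0, 14.0, 15.0]
        cmp = scanner_compare(self._paired(a, b))
        half = 2.7764451052 * np.sqrt(2.5) / np.sqrt(5)
        assert cmp.mean_diff == pytest.approx(3.0)
        assert cmp.ci_low == pytest.approx(3.0 - half, rel=1e-6)
        assert cmp.ci_high == pytest.approx(3.0 + half, rel=1e-6)

    def test_antisymmetric_under_scanner_swap(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 10, 8)
        b = rng.uniform(0, 10, 8)
        fwd = scanner_compare(self._paired(a, b))
        # relabel scanners: S1 <-> S2 (sorted order keeps S1 first)
        swapped = scanner_compare(self._paired(b, a))
        assert swapped.mean_diff == pytest.approx(-fwd.mean_diff)
        assert swapped.ci_low == pytest.approx(-fwd.ci_high)
        assert swapped.ci_high == pytest.approx(-fwd.ci_low)

    def test_unpaired_slide_rejected(self):
        recs = self._paired([1, 2], [3, 4])[:-1]
        with pytest.raises(PairingError):
            scanner_compare(recs)


class TestTemporal:
    def test_single_year_single_group(self):
        recs = [_record(f"s{i}", i, date=f"2021-0{i+1}-15") for i in range(4)]
        stats = temporal_stats(recs, "year")
        assert len(stats) == 1
        assert stats[0].key == "2021"
        assert stats[0].n == 4

    def test_group_means_match_groupby_oracle(self):
        rng = np.random.default_rng(13)
        recs, rows = [], []
        for i in range(30):
            year = int(rng.integers(2018, 2022))
            val = float(rng.uniform(0, 20))
            recs.append(_record(f"s{i}", val, date=f"{year}-06-01"))
            rows.append({"year": year, "val": val})
        stats = temporal_stats(recs, "year")
        oracle = pd.DataFrame(rows).groupby("year")["val"].mean()
        assert [g.key for g in stats] == [str(y) for y in oracle.index]
        for g, m in zip(stats, oracle.values):
            assert g.mean == pytest.approx(m)

    def test_groups_partition_records(self):
        rng = np.random.default_rng(14)
        recs = [
            _record(f"s{i}", 1.0, date=f"20{int(rng.integers(18, 23))}-03-01")
            for i in range(25)
        ]
        stats = temporal_stats(recs, "year")
        assert sum(g.n for g in stats) == len(recs)

    def test_bad_dates_rejected_with_log(self, caplog):
        recs = [_record("a", 1.0), _record("b", 2.0, date="not-a-date")]
        stats = temporal_stats(recs, "year")
        assert sum(g.n for g in stats) == 1
        assert any("unparseable" in r.message for r in caplog.records)


class TestReportsAndIO:
    def test_records_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        recs = [_record(f"s{i}", rng.uniform(0, 10), rng=rng) for i in range(5)]
        path = tmp_path / "records.csv"
        write_records_csv(recs, path)
        back = read_records_csv(path)
        for a, b in zip(recs, back):
            assert a.slide_id == b.slide_id
            assert a.summary.any_artifact_pct == pytest.approx(b.summary.any_artifact_pct)
            assert a.summary.class_pct == pytest.approx(b.summary.class_pct)

    def test_write_report_outputs(self, tmp_path):
        rng = np.random.default_rng(16)
        recs = [
            _record(f"s{i}", rng.uniform(0, 10), institute=f"P{i % 3}")
            for i in range(15)
        ]
        stats = institute_stats(recs)
        paths = write_report(stats, tmp_path)
        df = pd.read_csv(paths["csv"])
        for g, (_, row) in zip(stats, df.iterrows()):
            assert row["mean"] == pytest.approx(g.mean, abs=1e-9)
            assert row["q1"] == pytest.approx(g.q1, abs=1e-9)
        assert paths["figure"].exists()
        import json

        stored = json.loads(paths["json"].read_text())
        assert len(stored["groups"]) == len(stats)
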