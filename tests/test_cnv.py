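"""CNV post-processing: stitching, filtering, burden selection."""

import numpy as np
import pandas as pd
import pytest

from cnvomics import cnv
from cnvomics.cnv import Interval


def make_calls(rows, sample="s1"):
    return pd.DataFrame([{"chrom": r.get("chrom", "chr1"),
                          "start": r["start"], "end": r["end"],
                          "cn_type": r.get("cn_type", "DEL"),
                          "n_markers": r.get("n_markers", 10),
                          "confidence": r.get("confidence", 50.0),
                          "sample_id": r.get("sample_id", sample)}
                         for r in rows])


def brute_force_stitch(calls: pd.DataFrame, markers) -> pd.DataFrame:
    """Oracle: exhaustively re-scan all pairs each round until no pair of
    same-chromosome same-type calls can be joined."""
    recs = calls.to_dict("records")
    changed = True
    while changed:
        changed = False
        for i in range(len(recs)):
            for j in range(len(recs)):
                if i == j:
                    continue
                a, b = recs[i], recs[j]
                if (a["sample_id"] != b["sample_id"]
                        or a["chrom"] != b["chrom"]
                        or a["cn_type"] != b["cn_type"]):
                    continue
                lo, hi = sorted([a, b], key=lambda r: r["start"])
                if lo["end"] >= hi["start"]:
                    gap = 0
                else:
                    pos = np.asarray(markers[a["chrom"]])
                    gap = int(((pos > lo["end"]) & (pos < hi["start"])).sum())
                if gap < 0.5 * max(a["n_markers"], b["n_markers"]):
                    merged = {**a,
                              "start": min(a["start"], b["start"]),
                              "end": max(a["end"], b["end"]),
                              "n_markers": a["n_markers"] + b["n_markers"],
                              "confidence": max(a["confidence"], b["confidence"])}
                    recs = [r for k, r in enumerate(recs) if k not in (i, j)]
                    recs.append(merged)
                    changed = True
                    break
            if changed:
                break
    return (pd.DataFrame(recs)
            .sort_values(["sample_id", "chrom", "start"])
            .reset_index(drop=True))


class TestStitch:
    def test_hand_traced_merge(self):
        """Two deletions (20 and 10 markers) with 4 markers in the gap:
        4 < 0.5 * 20, so they join into one 100-300 kb call."""
        calls = make_calls([
            {"start": 100_000, "end": 200_000, "n_markers": 20, "confidence": 30},
            {"start": 210_000, "end": 300_000, "n_markers": 10, "confidence": 40},
        ])
        markers = {"chr1": np.array([150_000, 202_000, 204_000, 206_000,
                                     208_000, 250_000])}
        out = cnv.stitch_cnvs(calls, markers)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (100_000, 300_000)
        assert row["n_markers"] == 30
        assert row["confidence"] == 40.0

    def test_wide_gap_not_merged(self):
        calls = make_calls([
            {"start": 100_000, "end": 200_000, "n_markers": 10},
            {"start": 210_000, "end": 300_000, "n_markers": 10},
        ])
        # 5 gap markers >= 0.5 * 10
        markers = {"chr1": np.arange(201_000, 210_000, 1800)}
        assert len(cnv.stitch_cnvs(calls, markers)) == 2

    def test_single_call_unchanged(self):
        calls = make_calls([{"start": 1000, "end": 2000}])
        out = cnv.stitch_cnvs(calls, {"chr1": np.array([1500])})
        pd.testing.assert_frame_equal(
            out[calls.columns].reset_index(drop=True), calls)

    def test_types_never_merge(self):
        calls = make_calls([
            {"start": 1000, "end": 2000, "cn_type": "DEL"},
            {"start": 2001, "end": 3000, "cn_type": "DUP"},
        ])
        assert len(cnv.stitch_cnvs(calls, {"chr1": np.array([])})) == 2

    def test_missing_marker_map_errors(self):
        calls = make_calls([{"start": 1, "end": 2, "chrom": "chrX"}])
        with pytest.raises(ValueError, match="chrX"):
            cnv.stitch_cnvs(calls, {"chr1": np.array([])})

    def test_fixed_point_and_oracle_equivalence(self):
        """Random instances match a brute-force pairwise re-scanner and
        re-stitching is a no-op; coverage never decreases."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = rng.integers(1, 21)
            chroms = rng.choice(["chr1", "chr2"], n)
            starts = rng.integers(1, 5_000_000, n)
            sizes = rng.integers(10_000, 500_000, n)
            calls = pd.DataFrame({
                "chrom": chroms, "start": starts, "end": starts + sizes,
                "cn_type": rng.choice(["DEL", "DUP"], n),
                "n_markers": rng.integers(1, 40, n),
                "confidence": rng.uniform(10, 100, n),
                "sample_id": "s1"})
            markers = {c: np.unique(rng.integers(1, 6_000_000, 300))
                       for c in ("chr1", "chr2")}
            out = cnv.stitch_cnvs(calls, markers)
            oracle = brute_force_stitch(calls, markers)
            cols = ["chrom", "start", "end", "cn_type", "n_markers"]
            pd.testing.assert_frame_equal(
                out[cols].reset_index(drop=True), oracle[cols],
                check_dtype=False)
            again = cnv.stitch_cnvs(out, markers)
            pd.testing.assert_frame_equal(
                out.reset_index(drop=True), again.reset_index(drop=True))
            assert ((out["end"] - out["start"] + 1).sum()
                    >= _covered_bp(calls))


def _covered_bp(calls):
    total = 0
    for (c, t), grp in calls.groupby(["chrom", "cn_type"]):
        ivs = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


class TestFilter:
    def test_size_marker_confidence_thresholds(self):
        calls = make_calls([
            {"start": 1, "end": 90_000},                          # too small
            {"start": 1, "end": 150_000, "n_markers": 7},         # few markers
            {"start": 1, "end": 150_000, "confidence": 19.9},     # low conf
            {"start": 1, "end": 150_001, "n_markers": 8, "confidence": 20.0},
        ])
        out = cnv.filter_cnvs(calls)
        assert len(out) == 1
        assert out.iloc[0]["end"] == 150_001

    def test_exactly_100kb_removed(self):
        # size = end - start + 1 = exactly 100,000 -> not "over 100 kbp"
        calls = make_calls([{"start": 1, "end": 100_000}])
        assert len(cnv.filter_cnvs(calls)) == 0

    def test_confound_overlap_boundary(self):
        calls = make_calls([{"start": 1, "end": 200_000},
                            {"start": 1, "end": 200_000}])
        regions = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "start": [1, 1],
                                "end": [120_000, 100_000]})
        # 60% overlap removed; exactly 50% retained
        out = cnv.filter_cnvs(calls.iloc[[0]], regions.iloc[[0]])
        assert len(out) == 0
        out = cnv.filter_cnvs(calls.iloc[[1]], regions.iloc[[1]])
        assert len(out) == 1

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(1, 1_000_000, 12)
        calls = make_calls([{"start": int(s), "end": int(s + sz),
                             "n_markers": int(m), "confidence": float(c)}
                            for s, sz, m, c in zip(
                                starts, rng.integers(50_000, 300_000, 12),
                                rng.integers(1, 30, 12),
                                rng.uniform(5, 60, 12))])
        once = cnv.filter_cnvs(calls)
        twice = cnv.filter_cnvs(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = cnv.filter_cnvs(calls.sample(frac=1, random_state=1))
        assert set(map(tuple, shuffled[["start", "end"]].to_numpy())) \
            == set(map(tuple, once[["start", "end"]].to_numpy()))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            cnv.filter_cnvs(make_calls([{"start": 1, "end": 2}]),
                            min_size_bp=-1)


class TestBurden:
    locus = Interval("chr16", 29_500_000, 30_100_000)

    def _calls_of_size(self, bp, sample):
        return make_calls([{"chrom": "chr2", "start": 1, "end": bp}],
                          sample=sample)

    def test_worked_z_score_example(self):
        """Fibroblast burden 1.0 Mb, clones {1.0, 1.2, 0.8, 3.0} Mb:
        SD 1.026 Mb, the 3.0 Mb clone has Z 1.95 > 1.5 and is discarded."""
        fibro = self._calls_of_size(1_000_000, "fibro")
        clones = {f"c{i}": self._calls_of_size(bp, f"c{i}")
                  for i, bp in enumerate([1_000_000, 1_200_000,
                                          800_000, 3_000_000])}
        report, retained = cnv.clone_burden_selection(fibro, clones,
                                                      self.locus)
        z = report.set_index("subject_id")["z_score"]
        # 2.0 Mb above the fibroblast mean over a 1.013 Mb clone SD
        assert z["c3"] == pytest.approx(2.0 / np.std([1.0, 1.2, 0.8, 3.0],
                                                     ddof=1), abs=1e-9)
        assert z["c3"] > 1.5
        assert retained == ["c0", "c1", "c2"]

    def test_zero_sd_retains_all_with_warning(self):
        fibro = self._calls_of_size(500_000, "fibro")
        clones = {c: self._calls_of_size(500_000, c) for c in ("a", "b")}
        with pytest.warns(UserWarning, match="SD is 0"):
            report, retained = cnv.clone_burden_selection(fibro, clones,
                                                          self.locus)
        assert (report["z_score"] == 0).all()
        assert set(retained) == {"a", "b"}

    def test_z_exactly_at_threshold_retained(self):
        fibro = self._calls_of_size(1_000_000, "fibro")
        # clones at 1.0 and 1.0 + 1.5*sd: sd = diff/sqrt(2), so construct
        clones = {"a": self._calls_of_size(1_000_000, "a"),
                  "b": self._calls_of_size(2_000_000, "b")}
        sd = np.std([1_000_000, 2_000_000], ddof=1)
        report, retained = cnv.clone_burden_selection(
            fibro, clones, self.locus, z_max=(1_000_000 / sd))
        assert "b" in retained  # Z == z_max is kept (rule is strictly >)

    def test_focal_locus_excluded_from_burden(self):
        fibro = self._calls_of_size(1_000_000, "fibro")
        with_focal = pd.concat([
            self._calls_of_size(1_000_000, "a"),
            make_calls([{"chrom": "chr16", "start": 29_500_000,
                         "end": 30_100_000}], sample="a")])
        clones = {"a": with_focal, "b": self._calls_of_size(1_200_000, "b")}
        report, _ = cnv.clone_burden_selection(fibro, clones, self.locus)
        b = report.set_index("subject_id")["burden_bp"]
        assert b["a"] == 1_000_000

    def test_single_clone_rejected(self):
        fibro = self._calls_of_size(1, "f")
        with pytest.raises(ValueError):
            cnv.clone_burden_selection(fibro, {"a": fibro}, self.locus)


class TestConfirmFocal:
    locus = Interval("chr16", 29_500_000, 30_100_000)

    def test_full_span_confirms(self):
        calls = make_calls([{"chrom": "chr16", "start": 29_400_000,
                             "end": 30_200_000}])
        assert cnv.confirm_focal_cnv(calls, self.locus, "DEL")

    def test_wrong_type_fails(self):
        calls = make_calls([{"chrom": "chr16", "start": 29_400_000,
                             "end": 30_200_000, "cn_type": "DUP"}])
        assert not cnv.confirm_focal_cnv(calls, self.locus, "DEL")

    def test_partial_overlap_below_half_fails(self):
        # covers 40% of the locus only
        end = 29_500_000 + int(0.4 * self.locus.size) - 1
        calls = make_calls([{"chrom": "chr16", "start": 29_500_000,
                             "end": end}])
        assert not cnv.confirm_focal_cnv(calls, self.locus, "DEL")


class TestReaders:
    def test_penncnv_rawcnv_line(self):
        line = ("chr1:1000-2000  numsnp=25  length=1001  state2,cn=1  "
                "sample.txt  startsnp=rs1 endsnp=rs2  conf=30.0")
        out = cnv.read_penncnv([line])
        row = out.iloc[0]
        assert (row["chrom"], row["start"], row["end"]) == ("chr1", 1000, 2000)
        assert row["cn_type"] == "DEL"
        assert row["n_markers"] == 25
        assert row["confidence"] == 30.0

    def test_duplication_state(self):
        line = ("chr2:5-9  numsnp=3  length=5  state5,cn=3  s.txt  "
                "startsnp=a endsnp=b  conf=12.5")
        assert cnv.read_penncnv([line]).iloc[0]["cn_type"] == "DUP"

    def test_bed_conversion(self, tmp_path):
        p = tmp_path / "regions.bed"
        p.write_text("chr1\t0\t100\nchr2\t50\t60\n")
        bed = cnv.read_bed_regions(p)
        # 0-based half-open -> 1-based inclusive
        assert bed.iloc[0]["start"] == 1 and bed.iloc[0]["end"] == 100
        assert bed.iloc[1]["start"] == 51
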