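"""Post-processing of array-based CNV calls.

Calls arrive from an HMM caller (PennCNV-style) as per-sample interval
records with a supporting-marker count and a confidence score.  Fragmented
calls are re-joined by recursive stitching, low-quality calls are filtered,
and iPSC clones whose genome-wide CNV burden exceeds the parental
fibroblast line are discarded by a burden z-score rule.

Coordinates are 1-based inclusive (size = end - start + 1), the array
caller's convention; BED input is converted on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "start", "end", "cn_type", "n_markers",
                "confidence", "sample_id"]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if (calls["start"] > calls["end"]).any():
        raise ValueError("call with start > end")
    if (calls["n_markers"] < 1).any():
        raise ValueError("call with n_markers < 1")
    return calls


def _markers_between(markers: np.ndarray, left_end: int, right_start: int) -> int:
    """Markers strictly inside the gap (left_end, right_start)."""
    lo = np.searchsorted(markers, left_end, side="right")
    hi = np.searchsorted(markers, right_start, side="left")
    return int(hi - lo)


def stitch_cnvs(calls: pd.DataFrame, markers: dict[str, np.ndarray]) -> pd.DataFrame:
    """Recursively join same-type neighbouring calls separated by a small
    marker gap.

    Two same-chromosome, same-type calls are merged when the number of
    array markers strictly between them is less than half the marker count
    of the larger call.  The merged call spans both, its marker count is
    the sum of the pair (gap markers did not support either call) and its
    confidence the maximum of the pair.  Applied until a fixed point.
    """
    calls = _validate_calls(calls.copy())
    for chrom in calls["chrom"].unique():
        if chrom not in markers:
            raise ValueError(f"no marker map for chromosome {chrom}")
    out = []
    for (sample, chrom, cn_type), grp in calls.groupby(
            ["sample_id", "chrom", "cn_type"], sort=False):
        pos = np.asarray(markers[chrom])
        recs = grp.sort_values("start").to_dict("records")
        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(recs) - 1:
                a, b = recs[i], recs[i + 1]
                gap = _markers_between(pos, a["end"], b["start"])
                if gap < 0.5 * max(a["n_markers"], b["n_markers"]):
                    recs[i] = {**a,
                               "start": min(a["start"], b["start"]),
                               "end": max(a["end"], b["end"]),
                               "n_markers": a["n_markers"] + b["n_markers"],
                               "confidence": max(a["confidence"], b["confidence"])}
                    del recs[i + 1]
                    changed = True
                else:
                    i += 1
        out.extend(recs)
    result = pd.DataFrame(out, columns=calls.columns if out else CALL_COLUMNS)
    return result.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


def filter_cnvs(calls: pd.DataFrame,
                confound_regions: pd.DataFrame | None = None,
                min_size_bp: int = 100_000, min_markers: int = 8,
                min_conf: float = 20.0,
                max_confound_frac: float = 0.5) -> pd.DataFrame:
    """Quality filter: keep calls strictly larger than ``min_size_bp``,
    with at least ``min_markers`` supporting markers, confidence at least
    ``min_conf``, and at most ``max_confound_frac`` of their span inside
    confounding regions (assembly gaps, segmental duplications,
    centromeres/telomeres)."""
    if min(min_size_bp, min_markers) < 0 or min_conf < 0 or max_confound_frac < 0:
        raise ValueError("thresholds must be non-negative")
    calls = _validate_calls(calls)
    size = calls["end"] - calls["start"] + 1
    keep = ((size > min_size_bp)
            & (calls["n_markers"] >= min_markers)
            & (calls["confidence"] >= min_conf))
    if confound_regions is not None and len(confound_regions):
        fracs = np.zeros(len(calls))
        by_chrom = {c: g for c, g in confound_regions.groupby("chrom")}
        for i, row in enumerate(calls.itertuples(index=False)):
            regions = by_chrom.get(row.chrom)
            if regions is None:
                continue
            ov = sum(_overlap_bp(row.start, row.end, r.start, r.end)
                     for r in regions.itertuples(index=False))
            fracs[i] = min(ov, row.end - row.start + 1) / (row.end - row.start + 1)
        keep &= pd.Series(fracs, index=calls.index) <= max_confound_frac
    return calls[keep].reset_index(drop=True)


def _burden_bp(calls: pd.DataFrame, focal_locus: Interval) -> int:
    """Total CNV bp excluding calls that overlap the focal locus."""
    total = 0
    for row in calls.itertuples(index=False):
        if (row.chrom == focal_locus.chrom
                and _overlap_bp(row.start, row.end, focal_locus.start,
                                focal_locus.end) > 0):
            continue
        total += row.end - row.start + 1
    return total


def clone_burden_selection(fibroblast_calls: pd.DataFrame,
                           clone_calls: dict[str, pd.DataFrame],
                           focal_locus: Interval,
                           z_max: float = 1.5) -> tuple[pd.DataFrame, list[str]]:
    """Screen reprogrammed clones against the parental fibroblast burden.

    Burden B = summed bp of (filtered, non-focal) calls.  The fibroblast
    burden is the reference mean; the SD is taken across the clone burdens
    of the same patient; clones with Z = (B_clone - B_fibro)/SD strictly
    above ``z_max`` are discarded.  A zero SD (all clones identical)
    retains every clone with a warning.
    """
    if len(clone_calls) < 2:
        raise ValueError("need >= 2 clones for a defined burden SD")
    b_fibro = _burden_bp(fibroblast_calls, focal_locus)
    burdens = {c: _burden_bp(df, focal_locus) for c, df in clone_calls.items()}
    sd = float(np.std(list(burdens.values()), ddof=1))
    rows = []
    for clone, b in burdens.items():
        if sd == 0:
            z = 0.0
        else:
            z = (b - b_fibro) / sd
        rows.append({"subject_id": clone, "burden_bp": b, "z_score": z})
    if sd == 0:
        warnings.warn("clone burden SD is 0; all clones retained")
    report = pd.DataFrame(rows)
    retained = report.loc[report["z_score"] <= z_max, "subject_id"].tolist()
    return report, retained


def confirm_focal_cnv(calls: pd.DataFrame, focal_locus: Interval,
                      expected_type: str,
                      min_reciprocal_overlap: float = 0.5) -> bool:
    """True iff some call of ``expected_type`` reciprocally overlaps the
    focal locus by at least ``min_reciprocal_overlap`` of both intervals."""
    for row in calls.itertuples(index=False):
        if row.cn_type != expected_type or row.chrom != focal_locus.chrom:
            continue
        ov = _overlap_bp(row.start, row.end, focal_locus.start, focal_locus.end)
        call_size = row.end - row.start + 1
        if (ov / call_size >= min_reciprocal_overlap
                and ov / focal_locus.size >= min_reciprocal_overlap):
            return True
    return False


_RAWCNV_RE = re.compile(
    r"(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r".*?conf=(?P<conf>[-\d.]+)")


def read_penncnv(path_or_lines) -> pd.DataFrame:
    """Parse PennCNV ``rawcnv`` text lines into a call table.

    Copy number <2 becomes DEL, >2 DUP; cn=2 lines are rejected.
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = path_or_lines
    else:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    rows = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        m = _RAWCNV_RE.match(line)
        if not m:
            raise ValueError(f"unparseable rawcnv line: {line!r}")
        cn = int(m.group("cn"))
        if cn == 2:
            raise ValueError(f"copy-neutral line is not a CNV call: {line!r}")
        rows.append({
            "chrom": m.group("chrom"), "start": int(m.group("start")),
            "end": int(m.group("end")),
            "cn_type": "DEL" if cn < 2 else "DUP",
            "n_markers": int(m.group("numsnp")),
            "confidence": float(m.group("conf")),
            "sample_id": m.group("sample"),
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def read_bed_regions(path) -> pd.DataFrame:
    """Read BED (0-based half-open) confound regions into the 1-based
    inclusive convention used throughout this module."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    bed["start"] = bed["start"] + 1
    return bed
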