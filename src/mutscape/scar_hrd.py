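"""Genomic-scar HRD scoring from allele-specific copy-number segments.

The three scar components follow the published score definitions: LOH
(loss-of-heterozygosity segments longer than 15 Mb not spanning a whole
chromosome), TAI (allelic-imbalance segments reaching a telomere without
crossing the centromere) and LST (arm-wise large-scale state transitions
between adjacent >=10 Mb segments after removing <3 Mb segments and
merging equal-CN neighbors).  The summed score classifies tumors as
HRD-high at >= 42, with an automatic override for BRCA1/2 carriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalogs import MB, GenomeAnnotation

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]


@dataclass(frozen=True)
class ScarParams:
    loh_min_len: int = 15 * MB
    lst_min_seg: int = 10 * MB
    lst_max_gap: int = 3 * MB
    lst_filter_len: int = 3 * MB
    hrd_cutoff: int = 42


@dataclass
class HrdResult:
    sample_id: str
    loh: int
    tai: int
    lst: int
    status: str | None = None
    brca_override: bool = False

    @property
    def score(self) -> int:
        return self.loh + self.tai + self.lst


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def _validate(segments: pd.DataFrame) -> pd.DataFrame:
    if segments["minor_cn"].isna().any():
        raise ValueError("minor_cn is required for scar scoring")
    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segments must have end > start")
    return segments.sort_values(["chrom", "start"], kind="mergesort")


def _merged_rows(segments: pd.DataFrame, max_gap: int = 0):
    """Chromosome-sorted segment dicts with equal-CN neighbors merged.

    Neighbors are merged when they share total and minor copy number and
    are separated by at most ``max_gap`` bp, so that splitting a segment
    into equal-CN pieces never changes any scar component.
    """
    out = []
    for chrom, chrom_segs in _validate(segments).groupby("chrom", sort=True):
        rows = [
            {
                "chrom": chrom,
                "start": int(r.start),
                "end": int(r.end),
                "total_cn": int(r.total_cn),
                "minor_cn": int(r.minor_cn),
            }
            for r in chrom_segs.itertuples()
        ]
        out.extend(_merge_equal_cn(rows, max_gap=max_gap))
    return out


def _is_loh(row: dict) -> bool:
    return row["minor_cn"] == 0 and row["total_cn"] != 0


def _is_ai(row: dict) -> bool:
    return row["minor_cn"] != row["total_cn"] - row["minor_cn"]


def loh_score(
    segments: pd.DataFrame,
    annotation: GenomeAnnotation,
    params: ScarParams | None = None,
) -> int:
    """Count LOH segments > 15 Mb that do not span their whole chromosome."""
    params = params or ScarParams()
    count = 0
    for row in _merged_rows(segments):
        if not _is_loh(row):
            continue
        length = row["end"] - row["start"] + 1
        whole = row["start"] <= 1 and row["end"] >= annotation.length(row["chrom"])
        if length > params.loh_min_len and not whole:
            count += 1
    return count


def tai_score(
    segments: pd.DataFrame,
    annotation: GenomeAnnotation,
    params: ScarParams | None = None,
) -> int:
    """Count allelic-imbalance segments touching a telomere but not the centromere."""
    params = params or ScarParams()
    count = 0
    for row in _merged_rows(segments):
        if row["chrom"] not in annotation:
            raise ValueError(f"annotation missing chromosome {row['chrom']}")
        if not _is_ai(row):
            continue
        cen_start, cen_end = annotation.centromere(row["chrom"])
        chrom_len = annotation.length(row["chrom"])
        at_telomere = row["start"] <= 1 or row["end"] >= chrom_len
        crosses_cen = row["start"] <= cen_end and row["end"] >= cen_start
        if at_telomere and not crosses_cen:
            count += 1
    return count


def _merge_equal_cn(rows: list, max_gap: int = 0) -> list:
    merged: list = []
    for row in rows:
        if (
            merged
            and merged[-1]["total_cn"] == row["total_cn"]
            and merged[-1]["minor_cn"] == row["minor_cn"]
            and row["start"] - merged[-1]["end"] - 1 <= max_gap
        ):
            merged[-1]["end"] = row["end"]
        else:
            merged.append(dict(row))
    return merged


def lst_score(
    segments: pd.DataFrame,
    annotation: GenomeAnnotation,
    params: ScarParams | None = None,
) -> int:
    """Arm-wise count of large-scale state transitions.

    Segments crossing the centromere midpoint are split for arm-wise
    counting; segments shorter than 3 Mb are discarded, equal-CN
    neighbors merged, and a transition is counted for each adjacent pair
    of >= 10 Mb segments separated by < 3 Mb.
    """
    params = params or ScarParams()
    rows = _merged_rows(segments)
    by_chrom: dict[str, list] = {}
    for rec in rows:
        by_chrom.setdefault(rec["chrom"], []).append(rec)
    count = 0
    for chrom, chrom_segs in sorted(by_chrom.items()):
        cen_start, cen_end = annotation.centromere(chrom)
        mid = (cen_start + cen_end) // 2
        arms: dict[str, list] = {"p": [], "q": []}
        for rec in chrom_segs:
            if rec["end"] <= mid:
                arms["p"].append(rec)
            elif rec["start"] > mid:
                arms["q"].append(rec)
            else:
                left = {**rec, "end": mid}
                right = {**rec, "start": mid + 1}
                if left["end"] > left["start"]:
                    arms["p"].append(left)
                if right["end"] > right["start"]:
                    arms["q"].append(right)
        for arm_segs in arms.values():
            kept = [
                s for s in arm_segs if s["end"] - s["start"] + 1 >= params.lst_filter_len
            ]
            merged = _merge_equal_cn(kept, max_gap=params.lst_max_gap - 1)
            for left, right in zip(merged, merged[1:]):
                gap = right["start"] - left["end"] - 1
                big = (
                    left["end"] - left["start"] + 1 >= params.lst_min_seg
                    and right["end"] - right["start"] + 1 >= params.lst_min_seg
                )
                if big and gap < params.lst_max_gap:
                    count += 1
    return count


def hrd_score(
    segments: pd.DataFrame,
    annotation: GenomeAnnotation,
    sample_id: str = "",
    params: ScarParams | None = None,
) -> HrdResult:
    """LOH + TAI + LST for one sample's segments."""
    params = params or ScarParams()
    return HrdResult(
        sample_id=sample_id,
        loh=loh_score(segments, annotation, params),
        tai=tai_score(segments, annotation, params),
        lst=lst_score(segments, annotation, params),
    )


def classify_hrd_status(
    result: HrdResult,
    brca_flags: bool | dict = False,
    params: ScarParams | None = None,
) -> HrdResult:
    """HRD-high iff score >= 42 (inclusive) or any pathogenic BRCA1/2 flag.

    ``brca_flags`` may be a bool or a mapping like
    ``{"BRCA1_germline": True, "BRCA2_somatic": False}``.
    """
    params = params or ScarParams()
    any_brca = (
        any(bool(v) for v in brca_flags.values())
        if isinstance(brca_flags, dict)
        else bool(brca_flags)
    )
    result.brca_override = any_brca and result.score < params.hrd_cutoff
    high = result.score >= params.hrd_cutoff or any_brca
    result.status = "HRD-high" if high else "HRD-low"
    return result


def score_cohort(
    segments: pd.DataFrame,
    annotation: GenomeAnnotation,
    brca_flags: dict | None = None,
    params: ScarParams | None = None,
) -> pd.DataFrame:
    """Per-sample HRD components, score and status for a segment table."""
    params = params or ScarParams()
    brca_flags = brca_flags or {}
    rows = []
    for sample, sub in segments.groupby("sample_id", sort=True):
        res = hrd_score(sub, annotation, sample_id=sample, params=params)
        res = classify_hrd_status(res, brca_flags.get(sample, False), params)
        rows.append(
            {
                "sample_id": sample,
                "loh": res.loh,
                "tai": res.tai,
                "lst": res.lst,
                "hrd_score": res.score,
                "status": res.status,
                "brca_override": res.brca_override,
            }
        )
    return pd.DataFrame(rows)
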