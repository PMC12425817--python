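"""Somatic mutation data model, I/O, caller integration, filters and burden.

Mutation tables are MAF-like :class:`pandas.DataFrame` objects with one row
per (sample, locus, allele) call.  Coordinates are 1-based inclusive; MNVs
are kept as single records.  Per-caller evidence is merged on integration
and the four post-calling SNV filters (normal-sample contingency, strand
bias, base-quality drop, poor mapping quality) are applied afterwards,
accumulating every violated criterion rather than short-circuiting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2

CALLERS = ("strelka", "muse", "vardict", "mutect")

#: identity of a call; integration merges on these
KEY_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]

#: full MAF-like schema; evidence columns may be NaN when unknown
MAF_COLUMNS = KEY_COLUMNS + [
    "variant_class",   # SNV / insertion / deletion / MNV
    "gene",
    "consequence",
    "nonsilent",       # bool
    "callers",         # comma-joined subset of CALLERS
    "t_alt", "t_ref", "n_alt", "n_ref",
    "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
    "site_bq", "flank_bq", "alt_mq",
    "context",         # trinucleotide around SNVs (pyrimidine or purine strand)
    "hp_run",          # homopolymer run length at indel sites
]

FILTER_REASONS = ("normal_evidence", "strand_bias", "base_quality_drop", "poor_mapping")


class DataError(ValueError):
    """Inconsistent variant data (e.g. conflicting ref alleles at a locus)."""


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the post-calling filters.

    The significance levels are two-sided Fisher levels; ``bq_drop`` is the
    tolerated Phred drop of site base quality below the flanking average;
    ``mq_min`` the minimum mean mapping quality of mutant reads; ``hp_max``
    the homopolymer run length at which 1-bp indels are rejected.
    """

    alpha_normal: float = 0.05
    alpha_strand: float = 0.05
    bq_drop: float = 10.0
    mq_min: float = 20.0
    hp_max: int = 6


@dataclass
class BurdenSummary:
    sample_id: str
    snv_count: int
    indel_count: int
    target_size_mb: float = 73.499
    snvs_per_mb: float = field(init=False)
    hypermutated: bool = field(init=False)

    def __post_init__(self):
        if self.target_size_mb <= 0:
            raise ValueError("target_size_mb must be positive")
        self.snvs_per_mb = self.snv_count / self.target_size_mb
        self.hypermutated = False  # set by mutation_burden


def empty_maf() -> pd.DataFrame:
    return pd.DataFrame(columns=MAF_COLUMNS)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "callers": str})
    missing = set(KEY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"MAF-like table missing required columns: {sorted(missing)}")
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path, tumor_sample: str, normal_sample: str, sample_id: str | None = None) -> pd.DataFrame:
    """Read a minimal somatic VCF (AD/DP per sample, optional SB) into MAF form.

    ``SB`` is expected as ref-fwd, ref-rev, alt-fwd, alt-rev on the tumor
    sample.  Multi-allelic records are split by ALT allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)
    except ValueError as exc:
        raise DataError(f"samples {tumor_sample}/{normal_sample} not in VCF: {samples}") from exc
    rows = []
    for var in vcf:
        ad = var.format("AD")
        sb = var.format("SB")
        for alt_i, alt in enumerate(var.ALT):
            ref = var.REF
            if len(ref) == len(alt) == 1:
                vclass = "SNV"
            elif len(ref) == len(alt):
                vclass = "MNV"
            elif len(ref) < len(alt):
                vclass = "insertion"
            else:
                vclass = "deletion"
            row = {
                "sample_id": sample_id or tumor_sample,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": ref,
                "alt": alt,
                "variant_class": vclass,
                "t_ref": int(ad[t_idx][0]) if ad is not None else np.nan,
                "t_alt": int(ad[t_idx][alt_i + 1]) if ad is not None else np.nan,
                "n_ref": int(ad[n_idx][0]) if ad is not None else np.nan,
                "n_alt": int(ad[n_idx][alt_i + 1]) if ad is not None else np.nan,
            }
            if sb is not None:
                row.update(
                    ref_fwd=int(sb[t_idx][0]), ref_rev=int(sb[t_idx][1]),
                    alt_fwd=int(sb[t_idx][2]), alt_rev=int(sb[t_idx][3]),
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    for col in MAF_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[MAF_COLUMNS] if len(out) else empty_maf()


def _caller_set(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {c for c in str(value).split(",") if c}


def _join_callers(callers: set[str]) -> str:
    return ",".join(c for c in CALLERS if c in callers) or ",".join(sorted(callers))


# ---------------------------------------------------------------------------
# multi-caller integration
# ---------------------------------------------------------------------------


def integrate_callers(
    call_sets: dict[str, pd.DataFrame], min_support: int = 1
) -> pd.DataFrame:
    """Merge per-caller call sets into a unified mutation table.

    Records are merged on (sample, chrom, pos, ref, alt); the ``callers``
    field becomes the union of supporting callers and evidence fields are
    taken from the supporting record with the greatest tumor depth.
    Records supported by fewer than ``min_support`` callers are dropped.
    Conflicting ref alleles at one (sample, chrom, pos, alt) raise
    :class:`DataError`.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    frames = []
    for caller, df in call_sets.items():
        if df is None or len(df) == 0:
            continue
        sub = df.copy()
        sub["_caller"] = caller
        frames.append(sub)
    if not frames:
        return empty_maf()
    allcalls = pd.concat(frames, ignore_index=True)

    conflict = (
        allcalls.groupby(["sample_id", "chrom", "pos", "alt"])["ref"].nunique()
    )
    if (conflict > 1).any():
        bad = conflict[conflict > 1].index[0]
        raise DataError(f"conflicting ref alleles at {bad}")

    depth = allcalls.get("t_alt", pd.Series(0, index=allcalls.index)).fillna(0) + allcalls.get(
        "t_ref", pd.Series(0, index=allcalls.index)
    ).fillna(0)
    allcalls["_depth"] = depth

    merged_rows = []
    for _, grp in allcalls.groupby(KEY_COLUMNS, sort=False):
        callers = set(grp["_caller"])
        if len(callers) < min_support:
            continue
        best = grp.loc[grp["_depth"].idxmax()].drop(labels=["_caller", "_depth"])
        row = best.to_dict()
        row["callers"] = _join_callers(callers)
        merged_rows.append(row)
    if not merged_rows:
        return empty_maf()
    out = pd.DataFrame(merged_rows)
    return out.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _has(value) -> bool:
    return value is not None and not pd.isna(value)


def filter_snvs(records: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Apply the four SNV filter criteria; returns a decision table.

    A record fails

    - ``normal_evidence`` iff the normal sample carries the alternative
      allele and the tumor/normal contingency (two-sided Fisher on
      [[alt_t, ref_t], [alt_n, ref_n]]) is NOT significant at
      ``alpha_normal`` — i.e. the evidence is compatible with a germline
      or contaminating event;
    - ``strand_bias`` iff all mutant reads lie on one strand and the
      alt-vs-ref strand contingency is significant at ``alpha_strand``;
    - ``base_quality_drop`` iff the site mean base quality falls more
      than ``bq_drop`` below the flanking mean;
    - ``poor_mapping`` iff mutant-read mapping quality < ``mq_min``.

    Records lacking strand counts are flagged unevaluable
    (``evaluable=False``, ``passed=<NA>``) and reported separately.
    """
    params = params or FilterParams()
    decisions = []
    for _, row in records.iterrows():
        reasons: list[str] = []
        evaluable = all(_has(row.get(c)) for c in ("alt_fwd", "alt_rev", "ref_fwd", "ref_rev"))
        if evaluable:
            t_alt, t_ref = int(row["t_alt"]), int(row["t_ref"])
            n_alt, n_ref = int(row["n_alt"]), int(row["n_ref"])
            if n_alt > 0:
                p = fisher_exact_2x2([[t_alt, t_ref], [n_alt, n_ref]])
                if p >= params.alpha_normal:
                    reasons.append("normal_evidence")
            af, ar = int(row["alt_fwd"]), int(row["alt_rev"])
            rf, rr = int(row["ref_fwd"]), int(row["ref_rev"])
            if (af + ar) > 0 and (af == 0 or ar == 0):
                p = fisher_exact_2x2([[af, ar], [rf, rr]])
                if p < params.alpha_strand:
                    reasons.append("strand_bias")
            if _has(row.get("site_bq")) and _has(row.get("flank_bq")):
                if row["site_bq"] < row["flank_bq"] - params.bq_drop:
                    reasons.append("base_quality_drop")
            if _has(row.get("alt_mq")) and row["alt_mq"] < params.mq_min:
                reasons.append("poor_mapping")
        decisions.append(
            {
                **{k: row[k] for k in KEY_COLUMNS if k in row},
                "evaluable": evaluable,
                "passed": (len(reasons) == 0) if evaluable else pd.NA,
                "reasons": ",".join(reasons),
            }
        )
    out = pd.DataFrame(
        decisions, columns=KEY_COLUMNS + ["evaluable", "passed", "reasons"]
    )
    out["passed"] = out["passed"].astype("boolean")
    return out


def filter_indels(records: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Indel filtering: homopolymer context, germline evidence, mapping quality.

    1-bp indels inside homopolymer runs of length >= ``hp_max`` are
    rejected as likely slippage artifacts; the normal-contingency and
    mapping-quality criteria mirror the SNV filters.
    """
    params = params or FilterParams()
    decisions = []
    for _, row in records.iterrows():
        reasons: list[str] = []
        indel_len = abs(len(str(row["ref"]).replace("-", "")) - len(str(row["alt"]).replace("-", "")))
        if indel_len <= 1 and _has(row.get("hp_run")) and row["hp_run"] >= params.hp_max:
            reasons.append("homopolymer")
        if _has(row.get("n_alt")) and int(row["n_alt"]) > 0:
            p = fisher_exact_2x2(
                [[int(row["t_alt"]), int(row["t_ref"])], [int(row["n_alt"]), int(row["n_ref"])]]
            )
            if p >= params.alpha_normal:
                reasons.append("normal_evidence")
        if _has(row.get("alt_mq")) and row["alt_mq"] < params.mq_min:
            reasons.append("poor_mapping")
        decisions.append(
            {
                **{k: row[k] for k in KEY_COLUMNS if k in row},
                "evaluable": True,
                "passed": len(reasons) == 0,
                "reasons": ",".join(reasons),
            }
        )
    out = pd.DataFrame(
        decisions, columns=KEY_COLUMNS + ["evaluable", "passed", "reasons"]
    )
    out["passed"] = out["passed"].astype("boolean")
    return out


def apply_filters(
    records: pd.DataFrame, params: FilterParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a mixed SNV/indel table; returns (passed records, decisions)."""
    params = params or FilterParams()
    is_snv = records["variant_class"].isin(["SNV", "MNV"])
    dec_snv = filter_snvs(records[is_snv], params)
    dec_ind = filter_indels(records[~is_snv], params)
    decisions = pd.concat([dec_snv, dec_ind], ignore_index=True)
    keep_keys = decisions.loc[decisions["passed"] == True, KEY_COLUMNS]  # noqa: E712
    passed = records.merge(keep_keys, on=KEY_COLUMNS, how="inner")
    return passed.reset_index(drop=True), decisions


def rejection_counts(decisions: pd.DataFrame) -> dict[str, int]:
    """Per-criterion rejection counts for logging/reporting."""
    counts = {reason: 0 for reason in FILTER_REASONS + ("homopolymer",)}
    for reasons in decisions["reasons"]:
        for r in str(reasons).split(","):
            if r:
                counts[r] = counts.get(r, 0) + 1
    counts["unevaluable"] = int((~decisions["evaluable"]).sum())
    return counts


# ---------------------------------------------------------------------------
# burden and summaries
# ---------------------------------------------------------------------------


def mutation_burden(
    records: pd.DataFrame,
    target_size_mb: float = 73.499,
    cutoff: float = 10.0,
    strict: bool = True,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample SNV burden (SNVs/Mb) and hypermutation flag.

    ``strict=True`` flags hypermutation at burden strictly greater than
    ``cutoff`` SNVs/Mb; ``strict=False`` uses >=.
    """
    if target_size_mb <= 0:
        raise ValueError("target_size_mb must be positive")
    if samples is None:
        samples = sorted(records["sample_id"].unique()) if len(records) else []
    rows = []
    for sample in samples:
        sub = records[records["sample_id"] == sample]
        snv = int((sub["variant_class"] == "SNV").sum()) if len(sub) else 0
        indel = int(sub["variant_class"].isin(["insertion", "deletion"]).sum()) if len(sub) else 0
        per_mb = snv / target_size_mb
        hyper = per_mb > cutoff if strict else per_mb >= cutoff
        rows.append(
            {
                "sample_id": sample,
                "snv_count": snv,
                "indel_count": indel,
                "target_size_mb": target_size_mb,
                "snvs_per_mb": per_mb,
                "hypermutated": hyper,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "snv_count", "indel_count",
            "target_size_mb", "snvs_per_mb", "hypermutated",
        ],
    )


def gene_frequency(
    records: pd.DataFrame, n_samples: int, min_frequency: float | None = None
) -> pd.DataFrame:
    """Per-gene nonsilent mutation frequency; each sample counts once per gene."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    nonsilent = records[records["nonsilent"].astype(bool)] if len(records) else records
    if len(nonsilent) == 0:
        return pd.DataFrame(columns=["gene", "mutated_samples", "frequency"])
    counts = (
        nonsilent.drop_duplicates(["gene", "sample_id"])
        .groupby("gene")["sample_id"]
        .size()
        .rename("mutated_samples")
        .reset_index()
    )
    counts["frequency"] = counts["mutated_samples"] / n_samples
    counts = counts.sort_values(
        ["mutated_samples", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if min_frequency is not None:
        counts = counts[counts["frequency"] >= min_frequency].reset_index(drop=True)
    return counts


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_classes(records_or_counts) -> dict:
    """Mutation class summary with integer-rounded percentages.

    Accepts a mutation table or a mapping ``{"snv": n, "indel": n, ...}``
    (optionally with an explicit ``"total"``).
    """
    if isinstance(records_or_counts, pd.DataFrame):
        df = records_or_counts
        snv = int((df["variant_class"] == "SNV").sum())
        indel = int(df["variant_class"].isin(["insertion", "deletion"]).sum())
        total = int(len(df))
    else:
        counts = dict(records_or_counts)
        snv = int(counts.get("snv", 0))
        indel = int(counts.get("indel", 0))
        total = int(counts.get("total", snv + indel + int(counts.get("other", 0))))
    if total == 0:
        return {"total": 0, "snv_count": 0, "indel_count": 0, "pct_snv": 0, "pct_indel": 0}
    return {
        "total": total,
        "snv_count": snv,
        "indel_count": indel,
        "pct_snv": _round_half_up(100.0 * snv / total),
        "pct_indel": _round_half_up(100.0 * indel / total),
    }
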