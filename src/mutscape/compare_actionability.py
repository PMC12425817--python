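"""Cross-cohort comparisons and therapeutic-actionability classification.

Per-gene mutation frequencies are compared between cohorts with two-sided
Fisher exact tests under Benjamini-Hochberg FDR control; germline allele
frequencies against population references use chi-square or Fisher,
whichever the expected counts allow.  Copy-number amplitudes are reduced
to the five-level threshold scale (-2..2); actionability combines the
HRD-based chemotherapy-response call, the best evidence level from a
packaged OncoKB-style lookup snapshot, the CD274 (PD-L1) copy-number
class, and the expressed-neoantigen count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, chi2_or_fisher, fisher_exact_2x2

ONCOKB_LEVEL_ORDER = ["1", "2", "3a", "3b", "4", "none"]


@dataclass
class CohortFrequency:
    """Per-gene mutated-sample counts for one cohort."""

    name: str
    n: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        bad = {g: c for g, c in self.counts.items() if c < 0 or c > self.n}
        if bad:
            raise ValueError(f"counts out of range for cohort {self.name}: {bad}")


@dataclass
class ActionabilityCall:
    sample_id: str
    chemo_responsive: bool
    oncokb_level: str
    cd274_class: str
    neoantigen_count: int


def compare_frequencies(
    a: CohortFrequency, b: CohortFrequency, q_threshold: float = 0.10
) -> pd.DataFrame:
    """Two-sided Fisher per gene across two cohorts, BH-adjusted.

    Genes are tested over the union of both gene universes (absent genes
    count zero mutated samples); ``flagged`` marks q < ``q_threshold``.
    """
    genes = sorted(set(a.counts) | set(b.counts))
    rows = []
    for gene in genes:
        ma, mb = a.counts.get(gene, 0), b.counts.get(gene, 0)
        p = fisher_exact_2x2([[ma, a.n - ma], [mb, b.n - mb]])
        rows.append({"gene": gene, "count_a": ma, "count_b": mb, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = benjamini_hochberg(df["p"])
        df["flagged"] = df["q"] < q_threshold
    else:
        df["q"] = []
        df["flagged"] = []
    return df


def germline_vs_reference(
    case_alt: int,
    case_total: int,
    ref_alt: int,
    ref_total: int,
    alternative: str = "two-sided",
) -> dict:
    """Allele-frequency test of cases against a population reference.

    Chi-square when all expected cells are >= 5, otherwise Fisher exact;
    ``alternative='greater'`` gives the one-sided enrichment test (always
    Fisher).  Returns ``{"p": float, "method": str}``.
    """
    if case_total <= 0 or ref_total <= 0:
        raise ValueError("allele totals must be positive")
    table = [[case_alt, case_total - case_alt], [ref_alt, ref_total - ref_alt]]
    p, method = chi2_or_fisher(table, alternative=alternative)
    return {"p": p, "method": method}


DEFAULT_CN_CUTS = {0: -2, 1: -1, 2: 0, 3: 1, 4: 1}  # >=5 maps to 2


def threshold_cn(total_cn: int, cuts: dict[int, int] | None = None) -> int:
    """Discretize an integer total copy number to the five-level scale.

    Defaults: 0 -> -2 (homozygous deletion), 1 -> -1, 2 -> 0 (diploid),
    3-4 -> 1 (low-level gain), >= 5 -> 2 (high-level amplification).
    """
    if total_cn < 0:
        raise ValueError("total copy number must be non-negative")
    cuts = DEFAULT_CN_CUTS if cuts is None else cuts
    return cuts.get(int(total_cn), 2)


def cd274_class(threshold_value: int) -> str:
    """CD274 (PD-L1) copy-number class from a threshold value."""
    if threshold_value not in (-2, -1, 0, 1, 2):
        raise ValueError("threshold value must be in {-2..2}")
    if threshold_value == 1:
        return "gain"
    if threshold_value == 2:
        return "high_amp"
    return "neutral"


def count_neoantigens(
    peptides: pd.DataFrame,
    expression: pd.DataFrame,
    ic50_max: float = 500.0,
    min_reads: int = 1,
) -> tuple[int, list]:
    """Expressed neoantigen count for one sample.

    ``peptides`` has columns ``mutation`` and ``ic50_nM`` (one row per
    candidate peptide), ``expression`` columns ``mutation`` and
    ``read_count``.  A mutation is counted when at least one of its
    peptides binds (IC50 < 500 nM) and its transcript is expressed
    (read count >= 1).  Mutations lacking expression data are excluded
    and returned for logging.
    """
    expr = expression.set_index("mutation")["read_count"]
    binders = peptides[peptides["ic50_nM"] < ic50_max]["mutation"].unique()
    missing = [m for m in binders if m not in expr.index]
    count = sum(1 for m in binders if m in expr.index and expr[m] >= min_reads)
    return count, missing


def load_oncokb_snapshot(path=None) -> pd.DataFrame:
    """Load an OncoKB-style lookup table (gene, alteration_type, alteration, level).

    Without a path, the packaged synthetic snapshot is used.
    """
    if path is None:
        res = resources.files("mutscape.data") / "oncokb_snapshot_synthetic.tsv"
        with resources.as_file(res) as p:
            table = pd.read_csv(p, sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "alteration_type", "alteration", "level"}
    if not required.issubset(table.columns):
        raise ValueError(f"snapshot must have columns {sorted(required)}")
    bad = set(table["level"]) - set(ONCOKB_LEVEL_ORDER[:-1])
    if bad:
        raise ValueError(f"unknown OncoKB levels: {sorted(bad)}")
    return table


def best_oncokb_level(
    alterations: pd.DataFrame, snapshot: pd.DataFrame
) -> tuple[str, list]:
    """Best (lowest-numbered) evidence level among a sample's alterations.

    ``alterations`` has columns ``gene``, ``alteration_type`` (mutation /
    amplification / deletion / fusion) and ``alteration`` (e.g. the amino
    acid change, or 'any').  Unmatched alterations are returned for
    logging.
    """
    levels = []
    unmatched = []
    for row in alterations.itertuples():
        hits = snapshot[
            (snapshot["gene"] == row.gene)
            & (snapshot["alteration_type"] == row.alteration_type)
            & (
                (snapshot["alteration"] == "any")
                | (snapshot["alteration"] == str(row.alteration))
            )
        ]
        if len(hits):
            levels.extend(hits["level"].tolist())
        else:
            unmatched.append((row.gene, row.alteration_type, str(row.alteration)))
    if not levels:
        return "none", unmatched
    best = min(levels, key=ONCOKB_LEVEL_ORDER.index)
    return best, unmatched


def classify_actionability(
    sample_id: str,
    alterations: pd.DataFrame,
    hrd_status: str,
    snapshot: pd.DataFrame | None = None,
    cd274_threshold_value: int = 0,
    neoantigen_count: int = 0,
) -> ActionabilityCall:
    """Combine chemo-response, OncoKB level, CD274 class and neoantigens."""
    if snapshot is None:
        snapshot = load_oncokb_snapshot()
    level, _ = best_oncokb_level(alterations, snapshot)
    return ActionabilityCall(
        sample_id=sample_id,
        chemo_responsive=(hrd_status == "HRD-high"),
        oncokb_level=level,
        cd274_class=cd274_class(cd274_threshold_value),
        neoantigen_count=int(neoantigen_count),
    )


def donut_proportions(calls: list[ActionabilityCall]) -> dict:
    """Percentage breakdowns for the actionability report (sum to ~100)."""
    n = len(calls)
    if n == 0:
        return {"chemo": {}, "oncokb": {}, "cd274": {}}
    chemo = {
        "responsive": round(100 * sum(c.chemo_responsive for c in calls) / n),
        "non_responsive": round(100 * sum(not c.chemo_responsive for c in calls) / n),
    }
    oncokb = {
        lvl: round(100 * sum(c.oncokb_level == lvl for c in calls) / n)
        for lvl in ONCOKB_LEVEL_ORDER
        if any(c.oncokb_level == lvl for c in calls)
    }
    cd274 = {
        cls: round(100 * sum(c.cd274_class == cls for c in calls) / n)
        for cls in ("neutral", "gain", "high_amp")
        if any(c.cd274_class == cls for c in calls)
    }
    return {"chemo": chemo, "oncokb": oncokb, "cd274": cd274}
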