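"""Orthogonal confirmation of WES mutation calls.

Two independent lines of evidence are modeled: deep targeted amplicon
sequencing (TAS) of a gene panel, where a call is confirmed when the tumor
variant allele fraction exceeds the matched control by a highly stringent
one-sided Fisher criterion, and RNA-level detection, where concordance is
reported within strata of increasing RNA coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2

#: default confirmation level, reading the stringent criterion 10x10^-10 as 1e-9
DEFAULT_TAS_ALPHA = 1e-9


@dataclass(frozen=True)
class TasObservation:
    """Read counts at one mutation site in tumor TAS and matched control."""

    key: str
    alt_t: int
    ref_t: int
    alt_c: int
    ref_c: int

    def __post_init__(self):
        if min(self.alt_t, self.ref_t, self.alt_c, self.ref_c) < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_t + self.ref_t == 0:
            raise ValueError("tumor depth must be positive")


@dataclass
class ConfirmationReport:
    stratum: str
    n_input: int
    n_confirmed: int
    pvalues: dict | None = None

    @property
    def rate_pct(self):
        """Integer-rounded confirmation percentage; None for empty strata."""
        if self.n_input == 0:
            return None
        return int(np.floor(100.0 * self.n_confirmed / self.n_input + 0.5))


def confirm_tas(obs: TasObservation, alpha: float = DEFAULT_TAS_ALPHA) -> dict:
    """Confirm one mutation from TAS counts.

    One-sided Fisher exact test for tumor VAF greater than control VAF on
    [[alt_t, ref_t], [alt_c, ref_c]]; confirmed iff p < ``alpha``.
    """
    if obs.alt_c + obs.ref_c == 0:
        raise ValueError("control depth must be positive")
    p = fisher_exact_2x2(
        [[obs.alt_t, obs.ref_t], [obs.alt_c, obs.ref_c]], alternative="greater"
    )
    return {"key": obs.key, "confirmed": p < alpha, "p": p}


def confirm_tas_batch(
    observations: list[TasObservation], alpha: float = DEFAULT_TAS_ALPHA
) -> ConfirmationReport:
    results = [confirm_tas(o, alpha=alpha) for o in observations]
    return ConfirmationReport(
        stratum="tas",
        n_input=len(results),
        n_confirmed=sum(r["confirmed"] for r in results),
        pvalues={r["key"]: r["p"] for r in results},
    )


def rna_detection(
    wes_mutations: pd.DataFrame,
    rna_counts: pd.DataFrame,
    min_depths: list[int] = (0, 10, 30),
) -> tuple[list[ConfirmationReport], list]:
    """RNA-level detection of WES calls, stratified by RNA coverage.

    ``rna_counts`` must carry columns ``key``, ``alt`` and ``total``; WES
    mutations without an RNA row are excluded and returned separately.
    Within each stratum, only mutations with RNA total depth >= the
    stratum minimum are considered and a mutation counts as detected when
    at least one mutant read is seen.
    """
    keys = set(wes_mutations["key"])
    rna = rna_counts[rna_counts["key"].isin(keys)]
    unmatched = sorted(keys - set(rna["key"]))
    reports = []
    for min_depth in sorted(min_depths):
        sub = rna[rna["total"] >= min_depth]
        label = "all" if min_depth <= 0 else f">={min_depth}x"
        reports.append(
            ConfirmationReport(
                stratum=label,
                n_input=int(len(sub)),
                n_confirmed=int((sub["alt"] >= 1).sum()),
            )
        )
    return reports, unmatched


def denovo_tas_scan(
    tumor_counts: pd.DataFrame,
    pool_counts: pd.DataFrame,
    alpha: float = DEFAULT_TAS_ALPHA,
    vaf_min: float = 0.0,
    low_vaf_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Scan TAS panel sites for mutations absent from the WES calls.

    Each tumor site (columns ``site``, ``alt``, ``ref``) is compared with
    the pooled normal counts at the same site by a one-sided Fisher test;
    a site is called when p < ``alpha`` and its VAF >= ``vaf_min``.
    Called variants under ``low_vaf_cutoff`` are flagged low-VAF.
    """
    pool = pool_counts.set_index("site")
    rows = []
    for row in tumor_counts.itertuples():
        if row.site not in pool.index:
            continue
        palt, pref = int(pool.loc[row.site, "alt"]), int(pool.loc[row.site, "ref"])
        if palt + pref == 0:
            raise ValueError(f"pooled normal depth is zero at {row.site}")
        depth = row.alt + row.ref
        vaf = row.alt / depth if depth else 0.0
        p = fisher_exact_2x2([[row.alt, row.ref], [palt, pref]], alternative="greater")
        if p < alpha and vaf >= vaf_min:
            rows.append(
                {
                    "site": row.site,
                    "alt": int(row.alt),
                    "ref": int(row.ref),
                    "vaf": vaf,
                    "p": p,
                    "low_vaf": vaf < low_vaf_cutoff,
                }
            )
    return pd.DataFrame(rows, columns=["site", "alt", "ref", "vaf", "p", "low_vaf"])
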