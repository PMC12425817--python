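"""Channel orderings, reference-signature catalogs and genome annotations.

The SBS96 and ID83 channel orderings follow the COSMIC convention used by
the signature-extraction tools in this field.  The packaged reference
catalogs are SYNTHETIC stand-ins: deterministic, well-separated profiles
carrying the qualitative features of the named signatures (CpG C>T for
SBS1, TpC APOBEC motifs for SBS2/SBS13, broad featureless spectra for the
HRD and clock-like flat signatures), suitable for simulation and
round-trip testing.  Real COSMIC catalogs can be loaded from TSV with
:func:`load_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def sbs96_labels() -> list[str]:
    """The 96 trinucleotide substitution channels in COSMIC order."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


def id83_labels() -> list[str]:
    """The 83 indel channels in COSMIC order.

    Layout: 1-bp deletions (C/T homopolymer), 1-bp insertions, longer
    deletions/insertions at repeats, then microhomology deletions.
    """
    labels: list[str] = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{r}" for r in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{r}" for r in range(6)]
    for length in (2, 3, 4, 5):
        labels += [f"{length}:Del:R:{r}" for r in range(6)]
    for length in (2, 3, 4, 5):
        labels += [f"{length}:Ins:R:{r}" for r in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels += [f"{length}:Del:M:{m}" for m in range(1, max_mh + 1)]
    assert len(labels) == 83
    return labels


def _structured_profile(
    n_channels: int,
    peak_idx: np.ndarray,
    peak_weight: float,
    seed: int,
) -> np.ndarray:
    """Peaked motif mass plus a signature-specific broad background."""
    rng = np.random.default_rng(seed)
    background = rng.gamma(shape=1.0, scale=1.0, size=n_channels)
    background /= background.sum()
    profile = (1.0 - peak_weight) * background
    if peak_idx.size:
        peaks = rng.gamma(shape=4.0, scale=1.0, size=peak_idx.size)
        peaks /= peaks.sum()
        profile[peak_idx] += peak_weight * peaks
    return profile / profile.sum()


def synthetic_sbs_catalog() -> pd.DataFrame:
    """Synthetic five-signature SBS96 catalog (SBS1, SBS2, SBS3, SBS5, SBS13).

    Deterministic construction; columns sum to one.  The profiles are
    stand-ins shaped after the biology of the named signatures, not the
    COSMIC estimates.
    """
    labels = sbs96_labels()
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    def channels(sub: str, five: str | None = None, three: str | None = None):
        sel = [
            idx[f"{f}[{sub}]{t}"]
            for f in BASES
            for t in BASES
            if (five is None or f == five) and (three is None or t == three)
        ]
        return np.array(sel, dtype=int)

    cols = {
        # deamination of methylated CpG: C>T with 3' G
        "SBS1": _structured_profile(n, channels("C>T", three="G"), 0.85, seed=101),
        # APOBEC: C>T in TpC context
        "SBS2": _structured_profile(n, channels("C>T", five="T"), 0.85, seed=102),
        # HRD-associated: broad, relatively featureless
        "SBS3": _structured_profile(n, np.array([], dtype=int), 0.0, seed=103),
        # clock-like: broad with a T>C tilt
        "SBS5": _structured_profile(n, channels("T>C"), 0.6, seed=105),
        # APOBEC: C>G in TpC context
        "SBS13": _structured_profile(n, channels("C>G", five="T"), 0.85, seed=113),
    }
    return pd.DataFrame(cols, index=pd.Index(labels, name="channel"))


def synthetic_id_catalog() -> pd.DataFrame:
    """Synthetic five-signature ID83 catalog (ID2, ID4, ID6, ID7, ID8)."""
    labels = id83_labels()
    n = len(labels)
    arr = np.array(labels)

    def where(predicate) -> np.ndarray:
        return np.array([i for i, lab in enumerate(arr) if predicate(lab)], int)

    cols = {
        # 1-bp T deletions in long T homopolymers (slippage)
        "ID2": _structured_profile(
            n, where(lambda s: s.startswith("1:Del:T:") and int(s[-1]) >= 4), 0.9, 202
        ),
        # >=2 bp deletions at repeats
        "ID4": _structured_profile(
            n,
            where(lambda s: ":Del:R:" in s and not s.startswith("1")),
            0.85,
            204,
        ),
        # microhomology-mediated deletions (HRD)
        "ID6": _structured_profile(n, where(lambda s: ":Del:M:" in s), 0.9, 206),
        # short insertions at repeats
        "ID7": _structured_profile(
            n, where(lambda s: ":Ins:R:" in s), 0.85, 207
        ),
        # longer deletions with little/no microhomology (NHEJ)
        "ID8": _structured_profile(
            n,
            where(lambda s: s.startswith("5:Del:R:") and int(s[-1]) <= 1),
            0.85,
            208,
        ),
    }
    return pd.DataFrame(cols, index=pd.Index(labels, name="channel"))


def load_catalog(path) -> pd.DataFrame:
    """Read a channel x signature catalog TSV (first column = channel)."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    if (cat < 0).any().any():
        raise ValueError("catalog entries must be non-negative")
    return cat / cat.sum(axis=0)


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromAnnotation:
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self):
        if not (0 < self.cen_start < self.cen_end <= self.length):
            raise ValueError("centromere must lie within chromosome bounds")


@dataclass(frozen=True)
class GenomeAnnotation:
    """Chromosome lengths and centromere intervals (1-based, bp)."""

    chroms: dict[str, ChromAnnotation]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return self.chroms[chrom].length

    def centromere(self, chrom: str) -> tuple[int, int]:
        ann = self.chroms[chrom]
        return ann.cen_start, ann.cen_end

    def arm(self, chrom: str, pos: int) -> str:
        """Arm by centromere midpoint: 'p' left of it, 'q' right."""
        ann = self.chroms[chrom]
        mid = (ann.cen_start + ann.cen_end) // 2
        return "p" if pos <= mid else "q"


MB = 1_000_000


def toy_genome(n_chroms: int = 3) -> GenomeAnnotation:
    """Small test genome: each chromosome 88 Mb with a 4 Mb centromere."""
    chroms = {
        f"chr{i + 1}": ChromAnnotation(88 * MB, 42 * MB, 46 * MB)
        for i in range(n_chroms)
    }
    return GenomeAnnotation(chroms)


def load_genome_annotation(path) -> GenomeAnnotation:
    """Read annotation TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    return GenomeAnnotation(
        {
            row.chrom: ChromAnnotation(int(row.length), int(row.cen_start), int(row.cen_end))
            for row in df.itertuples()
        }
    )


def grch37_annotation() -> GenomeAnnotation:
    """GRCh37 chromosome sizes and approximate centromere intervals."""
    path = resources.files("mutscape.data") / "grch37_annotation.tsv"
    with resources.as_file(path) as p:
        return load_genome_annotation(p)
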