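"""Synthetic TNBC-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-tumor SBS96 context counts drawn multinomially from known
signature mixtures, a log-normal SNV burden, four pseudo-caller call sets
with injected artifact calls that each violate exactly one post-calling
filter criterion, allele-specific copy-number segments with engineered
LOH/TAI/LST events on a toy genome, deep amplicon (TAS) and RNA read
counts for a gene panel, and exponential survival times whose hazard is
scaled by the tumor's SBS subtype.  Every quantity is reproducible from
the seed and reported in a truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import MB, GenomeAnnotation, sbs96_labels, synthetic_sbs_catalog, toy_genome
from .mutation_core import CALLERS, MAF_COLUMNS
from .subtype_survival import assign_sbs_subtype

ARTIFACT_TYPES = (
    "strand_bias",
    "normal_contamination",
    "base_quality",
    "low_mapping_quality",
)

#: filter criterion each artifact type is designed to violate
ARTIFACT_REASON = {
    "strand_bias": "strand_bias",
    "normal_contamination": "normal_evidence",
    "base_quality": "base_quality_drop",
    "low_mapping_quality": "poor_mapping",
}

DEFAULT_GENE_FREQ = {
    "TP53": 0.95,
    "PIK3CA": 0.23,
    "PTEN": 0.12,
    "RB1": 0.08,
    "NOTCH2": 0.05,
}

PANEL_GENE = "TP53"


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``burden_distribution`` gives (mu, sigma) of log SNVs/Mb; the default
    centers the burden at 1.29 SNVs/Mb.  ``signature_profiles`` may fix
    per-tumor mixing weights (rows re-normalized to sum 1); otherwise
    weights are drawn from coupled latent aging/HRD axes so that SBS3
    activity and the planted HRD scar score rise together.
    ``hazard_ratios`` multiply the baseline all-cause hazard per subtype.
    """

    n_patients: int = 100
    signature_profiles: pd.DataFrame | None = None
    burden_distribution: tuple[float, float] = (float(np.log(1.29)), 1.0)
    min_mutations: int = 1
    subtype_truth: list | None = None
    hazard_ratios: dict = field(
        default_factory=lambda: {1: 1.0, 2: 1.3, 3: 2.6, 4: 1.3}
    )
    artifact_rates: dict = field(
        default_factory=lambda: {t: 0.05 for t in ARTIFACT_TYPES}
    )
    caller_dropout: float = 0.10
    target_size_mb: float = 73.499
    indel_fraction: float = 0.08
    gene_freq_truth: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQ))
    with_mutations: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for name, rate in self.artifact_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"artifact rate {name} must be in [0,1]")
        if not 0 <= self.caller_dropout <= 1:
            raise ConfigurationError("caller_dropout must be in [0,1]")
        if self.signature_profiles is not None:
            w = self.signature_profiles.to_numpy(float)
            if (w < 0).any() or (w.sum(axis=1) <= 0).any():
                raise ConfigurationError("signature profiles must be non-negative with positive row sums")


@dataclass
class CohortBundle:
    patients: pd.DataFrame
    truth_mutations: pd.DataFrame
    caller_calls: dict
    call_labels: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    rna_counts: pd.DataFrame
    tas_reads: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def _draw_weights(cfg: CohortConfig, catalog: pd.DataFrame, rng) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-tumor mixing weights over the catalog, plus latent axes (u=HRD, v=aging)."""
    n = cfg.n_patients
    u = rng.uniform(0, 1, n)
    v = rng.uniform(0, 1, n)
    if cfg.subtype_truth is not None:
        # forced levels pin the latent axes into the low/high bands
        for i, (aging_level, hrd_level) in enumerate(cfg.subtype_truth):
            v[i] = rng.uniform(0.70, 1.0) if aging_level == "high" else rng.uniform(0.0, 0.62)
            u[i] = rng.uniform(0.70, 1.0) if hrd_level == "high" else rng.uniform(0.0, 0.62)
    if cfg.signature_profiles is not None:
        w = cfg.signature_profiles.to_numpy(float)
        w = w / w.sum(axis=1, keepdims=True)
        return (
            pd.DataFrame(w, columns=cfg.signature_profiles.columns),
            u,
            v,
        )
    cols = list(catalog.columns)
    w = np.zeros((n, len(cols)))
    w3 = 0.08 + 0.50 * u + rng.normal(0, 0.03, n)
    aging = 0.10 + 0.55 * v + rng.normal(0, 0.03, n)
    w3 = np.clip(w3, 0.02, 0.75)
    aging = np.clip(aging, 0.05, 0.80)
    split = rng.uniform(0.3, 0.5, n)  # SBS1 share of the aging activity
    apobec = np.clip(1.0 - w3 - aging, 0.02, None)
    apobec_split = rng.uniform(0.4, 0.6, n)
    w[:, cols.index("SBS3")] = w3
    w[:, cols.index("SBS1")] = aging * split
    w[:, cols.index("SBS5")] = aging * (1 - split)
    w[:, cols.index("SBS2")] = apobec * apobec_split
    w[:, cols.index("SBS13")] = apobec * (1 - apobec_split)
    w = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, columns=cols), u, v


_LABELS = sbs96_labels()
_FIVE = np.array([lab[0] for lab in _LABELS])
_REF = np.array([lab[2] for lab in _LABELS])
_ALT = np.array([lab[4] for lab in _LABELS])
_THREE = np.array([lab[6] for lab in _LABELS])


def _mutation_rows(
    sample_id: str,
    channel_idx: np.ndarray,
    genes: np.ndarray,
    nonsilent: np.ndarray,
    genome: GenomeAnnotation,
    rng,
) -> pd.DataFrame:
    m = channel_idx.size
    chroms = rng.choice(list(genome.chroms), size=m)
    pos = np.array([rng.integers(1, genome.length(c)) for c in chroms])
    depth_t = 60 + rng.poisson(60, m)
    vaf = rng.beta(8, 16, m)
    alt_t = np.maximum(rng.binomial(depth_t, vaf), 4)
    ref_t = depth_t - alt_t
    # keep at least one mutant read per strand so true calls are not
    # rejected as strand artifacts
    alt_fwd = np.clip(rng.binomial(alt_t, 0.5), 1, alt_t - 1)
    alt_rev = alt_t - alt_fwd
    ref_fwd = rng.binomial(ref_t, 0.5)
    depth_n = 40 + rng.poisson(60, m)
    flank_bq = rng.normal(34, 1.5, m)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chroms,
            "pos": pos,
            "ref": _REF[channel_idx],
            "alt": _ALT[channel_idx],
            "variant_class": "SNV",
            "gene": genes,
            "consequence": np.where(nonsilent, "missense", "silent"),
            "nonsilent": nonsilent,
            "callers": "",
            "t_alt": alt_t,
            "t_ref": ref_t,
            "n_alt": 0,
            "n_ref": depth_n,
            "alt_fwd": alt_fwd,
            "alt_rev": alt_rev,
            "ref_fwd": ref_fwd,
            "ref_rev": ref_t - ref_fwd,
            "site_bq": flank_bq + rng.normal(0, 0.5, m),
            "flank_bq": flank_bq,
            "alt_mq": 60.0,
            "context": [
                f"{_FIVE[c]}{_REF[c]}{_THREE[c]}" for c in channel_idx
            ],
            "hp_run": np.nan,
        }
    )


def _indel_rows(sample_id: str, n: int, genome: GenomeAnnotation, rng) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(columns=MAF_COLUMNS)
    chroms = rng.choice(list(genome.chroms), size=n)
    pos = np.array([rng.integers(1, genome.length(c)) for c in chroms])
    is_del = rng.random(n) < 0.6
    seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(1, 5))) for _ in range(n)]
    depth_t = 60 + rng.poisson(60, n)
    alt_t = np.maximum(rng.binomial(depth_t, rng.beta(8, 16, n)), 4)
    ref_t = depth_t - alt_t
    alt_fwd = np.clip(rng.binomial(alt_t, 0.5), 1, alt_t - 1)
    flank_bq = rng.normal(34, 1.5, n)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chroms,
            "pos": pos,
            "ref": [s if d else "-" for s, d in zip(seqs, is_del)],
            "alt": ["-" if d else s for s, d in zip(seqs, is_del)],
            "variant_class": np.where(is_del, "deletion", "insertion"),
            "gene": [f"G{rng.integers(0, 300):04d}" for _ in range(n)],
            "consequence": "frameshift",
            "nonsilent": True,
            "callers": "",
            "t_alt": alt_t,
            "t_ref": ref_t,
            "n_alt": 0,
            "n_ref": 40 + rng.poisson(60, n),
            "alt_fwd": alt_fwd,
            "alt_rev": alt_t - alt_fwd,
            "ref_fwd": ref_t // 2,
            "ref_rev": ref_t - ref_t // 2,
            "site_bq": flank_bq,
            "flank_bq": flank_bq,
            "alt_mq": 60.0,
            "context": "",
            "hp_run": rng.integers(0, 4, n),
        }
    )


def _artifact_row(sample_id: str, kind: str, genome: GenomeAnnotation, rng) -> dict:
    chrom = str(rng.choice(list(genome.chroms)))
    base = {
        "sample_id": sample_id,
        "chrom": chrom,
        "pos": int(rng.integers(1, genome.length(chrom))),
        "variant_class": "SNV",
        "gene": f"G{rng.integers(0, 300):04d}",
        "consequence": "missense",
        "nonsilent": True,
        "callers": "",
        "context": "ACA",
        "ref": "C",
        "alt": "T",
        "hp_run": np.nan,
        "site_bq": 34.0,
        "flank_bq": 34.0,
        "alt_mq": 60.0,
        "n_alt": 0,
        "n_ref": 100,
    }
    if kind == "strand_bias":
        alt = int(rng.integers(12, 20))
        base.update(
            t_alt=alt, t_ref=80, alt_fwd=alt, alt_rev=0, ref_fwd=40, ref_rev=40
        )
    elif kind == "normal_contamination":
        vaf = float(rng.uniform(0.15, 0.25))
        alt_t = max(int(rng.binomial(90, vaf)), 2)
        alt_n = max(int(rng.binomial(90, vaf)), 2)
        fwd = max(1, min(alt_t - 1, int(rng.binomial(alt_t, 0.5))))
        base.update(
            t_alt=alt_t, t_ref=90 - alt_t, n_alt=alt_n, n_ref=90 - alt_n,
            alt_fwd=fwd, alt_rev=alt_t - fwd, ref_fwd=45, ref_rev=45,
        )
    elif kind == "base_quality":
        base.update(
            t_alt=20, t_ref=80, alt_fwd=10, alt_rev=10, ref_fwd=40, ref_rev=40,
            site_bq=19.0, flank_bq=34.0,
        )
    elif kind == "low_mapping_quality":
        base.update(
            t_alt=20, t_ref=80, alt_fwd=10, alt_rev=10, ref_fwd=40, ref_rev=40,
            alt_mq=10.0,
        )
    else:
        raise ValueError(f"unknown artifact type {kind}")
    return base


def inject_artifacts(
    truth: pd.DataFrame,
    rates: dict,
    seed_or_rng,
    genome: GenomeAnnotation | None = None,
    caller_dropout: float = 0.10,
) -> tuple[dict, pd.DataFrame]:
    """Build per-caller call sets: truth calls with dropout plus artifacts.

    Each artifact call carries evidence violating exactly one filter
    criterion, at a severity the filters are designed to reject, and is
    labeled with its intended rejection reason in the returned label
    table (``label='real'`` for truth calls).
    """
    for name, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ConfigurationError(f"artifact rate {name} must be in [0,1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    genome = genome or toy_genome(24)
    n = len(truth)
    artifact_frames = []
    labels = [
        truth[["sample_id", "chrom", "pos", "ref", "alt"]].assign(label="real")
    ]
    samples = truth["sample_id"].unique() if n else []
    for kind in ARTIFACT_TYPES:
        rate = rates.get(kind, 0.0)
        if rate == 0 or n == 0:
            continue
        for sample in samples:
            n_sample = int((truth["sample_id"] == sample).sum())
            k = rng.binomial(n_sample, rate)
            rows = [_artifact_row(sample, kind, genome, rng) for _ in range(k)]
            if rows:
                df = pd.DataFrame(rows)
                artifact_frames.append(df)
                labels.append(
                    df[["sample_id", "chrom", "pos", "ref", "alt"]].assign(
                        label=f"artifact:{ARTIFACT_REASON[kind]}"
                    )
                )
    allcalls = pd.concat([truth] + artifact_frames, ignore_index=True) if artifact_frames else truth.copy()
    m = len(allcalls)
    call_sets = {}
    detected = rng.random((m, len(CALLERS))) >= caller_dropout
    none_detected = ~detected.any(axis=1)
    if none_detected.any():
        forced = rng.integers(0, len(CALLERS), none_detected.sum())
        detected[np.where(none_detected)[0], forced] = True
    for j, caller in enumerate(CALLERS):
        call_sets[caller] = allcalls[detected[:, j]].reset_index(drop=True)
    label_df = pd.concat(labels, ignore_index=True) if n else pd.DataFrame(
        columns=["sample_id", "chrom", "pos", "ref", "alt", "label"]
    )
    return call_sets, label_df


def simulate_tas_reads(
    vaf: float, depth: int, seed_or_rng, error_rate: float = 1e-3, control_depth: int | None = None
) -> dict:
    """Binomial tumor/control read counts for one amplicon site."""
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must be in [0,1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    control_depth = control_depth or depth
    alt_t = int(rng.binomial(depth, vaf))
    alt_c = int(rng.binomial(control_depth, error_rate))
    return {
        "alt_t": alt_t,
        "ref_t": depth - alt_t,
        "alt_c": alt_c,
        "ref_c": control_depth - alt_c,
    }


def simulate_subtype_labels(
    age: np.ndarray,
    bmi: np.ndarray,
    beta_age: float,
    beta_bmi: float,
    intercept: float,
    seed_or_rng,
) -> np.ndarray:
    """Draw subtype-1-vs-3 labels from an exactly planted logistic model.

    Returns an array over {1, 3}; the log-odds of subtype 1 are
    ``intercept + beta_age * age + beta_bmi * bmi``, so the true odds
    ratio per +10 years is ``exp(10 * beta_age)`` by construction.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    age = np.asarray(age, float)
    bmi = np.asarray(bmi, float)
    logit = intercept + beta_age * age + beta_bmi * bmi
    p1 = 1.0 / (1.0 + np.exp(-logit))
    return np.where(rng.random(age.size) < p1, 1, 3)


# --- copy-number arm templates ---------------------------------------------

_FILL_A = (2, 1)   # balanced diploid
_FILL_B = (4, 2)   # balanced tetraploid


def _arm_blocks(event: str, arm: str) -> list[tuple[int, tuple[int, int]]]:
    """(length, (total, minor)) blocks tiling one 42 Mb arm.

    Each template contributes exactly one scar event (or none); fills are
    balanced, sub-10 Mb and alternate copy state so no extra LOH, TAI or
    LST arises.
    """
    if event == "none":
        return [(9 * MB, _FILL_A), (9 * MB, _FILL_B), (9 * MB, _FILL_A), (9 * MB, _FILL_B), (6 * MB, _FILL_A)]
    if event == "loh":
        return [(9 * MB, _FILL_A), (16 * MB, (1, 0)), (9 * MB, _FILL_B), (8 * MB, _FILL_A)]
    if event == "tai":
        blocks = [(20 * MB, (3, 1)), (9 * MB, _FILL_A), (9 * MB, _FILL_B), (4 * MB, _FILL_A)]
        return blocks if arm == "p" else blocks[::-1]
    if event == "lst":
        return [(9 * MB, _FILL_B), (12 * MB, _FILL_A), (12 * MB, (3, 1)), (9 * MB, _FILL_B)]
    raise ValueError(event)


def _sample_segments(
    sample_id: str, genome: GenomeAnnotation, events: dict, rng
) -> pd.DataFrame:
    arms = [(chrom, arm) for chrom in genome.chroms for arm in ("p", "q")]
    wanted = (
        ["loh"] * events["loh"] + ["tai"] * events["tai"] + ["lst"] * events["lst"]
    )
    if len(wanted) > len(arms):
        raise ConfigurationError(
            f"planted events ({len(wanted)}) exceed arm capacity ({len(arms)})"
        )
    wanted += ["none"] * (len(arms) - len(wanted))
    order = rng.permutation(len(arms))
    rows = []
    for idx, event in zip(order, wanted):
        chrom, arm = arms[idx]
        cen_start, cen_end = genome.centromere(chrom)
        start = 1 if arm == "p" else cen_end + 1
        for length, (total, minor) in _arm_blocks(event, arm):
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": start,
                    "end": start + length - 1,
                    "total_cn": total,
                    "minor_cn": minor,
                }
            )
            start += length
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def _empty_bundle() -> CohortBundle:
    return CohortBundle(
        patients=pd.DataFrame(
            columns=["sample_id", "age", "bmi", "stage", "study", "time", "event",
                     "brca1_germline", "brca2_germline", "brca_somatic"]
        ),
        truth_mutations=pd.DataFrame(columns=MAF_COLUMNS),
        caller_calls={c: pd.DataFrame(columns=MAF_COLUMNS) for c in CALLERS},
        call_labels=pd.DataFrame(columns=["sample_id", "chrom", "pos", "ref", "alt", "label"]),
        segments=pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]),
        expression=pd.DataFrame(),
        rna_counts=pd.DataFrame(columns=["key", "alt", "total"]),
        tas_reads=pd.DataFrame(columns=["key", "alt_t", "ref_t", "alt_c", "ref_c"]),
        truth={
            "exposures": pd.DataFrame(),
            "weights": pd.DataFrame(),
            "subtypes": pd.DataFrame(),
            "hrd": pd.DataFrame(columns=["sample_id", "loh", "tai", "lst", "hrd_score"]),
        },
    )


def generate_cohort(config: CohortConfig, catalog: pd.DataFrame | None = None) -> CohortBundle:
    """Generate a full synthetic cohort from the study conditions.

    Deterministic under a fixed seed.  ``catalog`` defaults to the
    packaged synthetic five-signature SBS96 catalog; it must be
    column-stochastic over the 96 channels.
    """
    config.validate()
    catalog = catalog if catalog is not None else synthetic_sbs_catalog()
    if catalog.shape[0] == 0 or catalog.shape[1] == 0:
        raise ConfigurationError("reference catalog is empty")
    if config.n_patients == 0:
        return _empty_bundle()
    rng = np.random.default_rng(config.seed)
    genome = toy_genome(24)
    n = config.n_patients
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- signature structure ------------------------------------------------
    weights, u, v = _draw_weights(config, catalog, rng)

    # --- patients (age/BMI rise with the latent aging axis) -----------------
    age = np.clip(rng.normal(56, 11, n) + 8 * (v - 0.5), 25, 90)
    bmi = np.clip(rng.normal(31, 6.5, n) + 4 * (v - 0.5), 17, 55)
    stage = rng.choice(["I", "II", "III"], size=n, p=[0.25, 0.45, 0.30])
    study = rng.choice(["A", "B", "C"], size=n, p=[0.5, 0.3, 0.2])
    if set(weights.columns) != set(catalog.columns):
        raise ConfigurationError("signature profile columns must match the catalog")
    weights = weights[list(catalog.columns)]
    if config.subtype_truth is None and not {"SBS1", "SBS5", "SBS3"}.issubset(catalog.columns):
        raise ConfigurationError(
            "catalog must contain SBS1, SBS5 and SBS3 unless subtype_truth is forced"
        )
    mu, sigma = config.burden_distribution
    floor = max(config.min_mutations, 1)
    if config.min_mutations > 1 and sigma > 0:
        # left-truncated log-normal: keeps the burden continuous above the
        # floor instead of piling samples onto a single atom
        from scipy.stats import norm

        z_lo = (np.log(floor / config.target_size_mb) - mu) / sigma
        u = rng.uniform(norm.cdf(z_lo), 1.0, n)
        burden = np.exp(mu + sigma * norm.ppf(u))
    else:
        burden = np.exp(rng.normal(mu, sigma, n))
    n_snv = np.maximum(np.round(burden * config.target_size_mb).astype(int), floor)
    profiles = weights.to_numpy() @ catalog.to_numpy().T  # n x 96
    channel_counts = np.vstack(
        [rng.multinomial(n_snv[i], profiles[i]) for i in range(n)]
    )
    true_exposures = pd.DataFrame(
        weights.to_numpy() * n_snv[:, None],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=weights.columns,
    )
    context_matrix = pd.DataFrame(
        channel_counts, index=pd.Index(sample_ids, name="sample_id"), columns=_LABELS
    )

    # --- subtype truth and survival ----------------------------------------
    if config.subtype_truth is not None:
        from .subtype_survival import SUBTYPE_MAP

        subtype = np.array(
            [SUBTYPE_MAP[(a, h)] for a, h in config.subtype_truth], dtype=int
        )
        subtypes = pd.DataFrame(
            {"sample_id": sample_ids, "subtype": subtype}
        ).set_index("sample_id")
    else:
        try:
            subtypes = assign_sbs_subtype(true_exposures)[["subtype"]]
        except ValueError:
            # cohorts too small (or too tied) for tertiles: neutral subtype
            subtypes = pd.DataFrame(
                {"subtype": [2] * n}, index=pd.Index(sample_ids, name="sample_id")
            )
        subtype = subtypes["subtype"].to_numpy()
    lam0 = 0.008  # baseline monthly hazard
    hr = np.array([config.hazard_ratios.get(int(s), 1.0) for s in subtype])
    t_event = rng.exponential(1.0 / (lam0 * hr))
    censor = rng.uniform(12, 120, n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    # --- BRCA flags, coupled to the HRD axis --------------------------------
    brca1 = rng.random(n) < (0.02 + 0.10 * u)
    brca2 = rng.random(n) < (0.01 + 0.05 * u)
    brca_som = rng.random(n) < 0.03

    patients = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "bmi": bmi,
            "stage": stage,
            "study": study,
            "time": time,
            "event": event,
            "brca1_germline": brca1,
            "brca2_germline": brca2,
            "brca_somatic": brca_som,
        }
    )

    # --- HRD scar events ----------------------------------------------------
    score_target = np.round(8 + 40 * u + rng.normal(0, 2, n)).astype(int)
    score_target = np.clip(score_target, 0, 46)
    loh_n = np.round(0.4 * score_target).astype(int)
    tai_n = np.round(0.3 * score_target).astype(int)
    lst_n = score_target - loh_n - tai_n
    seg_frames = []
    for i, sample in enumerate(sample_ids):
        seg_frames.append(
            _sample_segments(
                sample,
                genome,
                {"loh": int(loh_n[i]), "tai": int(tai_n[i]), "lst": int(lst_n[i])},
                rng,
            )
        )
    segments = pd.concat(seg_frames, ignore_index=True)
    hrd_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "loh": loh_n,
            "tai": tai_n,
            "lst": lst_n,
            "hrd_score": loh_n + tai_n + lst_n,
        }
    )

    # --- mutation records ---------------------------------------------------
    truth_mutations = pd.DataFrame(columns=MAF_COLUMNS)
    caller_calls = {c: pd.DataFrame(columns=MAF_COLUMNS) for c in CALLERS}
    call_labels = pd.DataFrame(columns=["sample_id", "chrom", "pos", "ref", "alt", "label"])
    planted_freq = {}
    if config.with_mutations:
        frames = []
        # planted per-gene sample frequencies (one nonsilent record each)
        gene_samples: dict[str, np.ndarray] = {}
        for gene, freq in config.gene_freq_truth.items():
            k = int(round(freq * n))
            gene_samples[gene] = rng.choice(n, size=k, replace=False)
            planted_freq[gene] = k
        for i, sample in enumerate(sample_ids):
            channel_idx = np.repeat(np.arange(96), channel_counts[i])
            rng.shuffle(channel_idx)
            m = channel_idx.size
            genes = np.array([f"G{g:04d}" for g in rng.integers(0, 300, m)])
            nonsilent = rng.random(m) < 0.75
            df = _mutation_rows(sample, channel_idx, genes, nonsilent, genome, rng)
            extra_genes = [g for g, chosen in gene_samples.items() if i in chosen]
            if extra_genes:
                extra_idx = rng.choice(96, size=len(extra_genes), p=profiles[i])
                extra = _mutation_rows(
                    sample,
                    np.atleast_1d(extra_idx),
                    np.array(extra_genes),
                    np.ones(len(extra_genes), bool),
                    genome,
                    rng,
                )
                df = pd.concat([df, extra], ignore_index=True)
            n_indel = rng.poisson(config.indel_fraction * m)
            if n_indel:
                df = pd.concat(
                    [df, _indel_rows(sample, n_indel, genome, rng)], ignore_index=True
                )
            frames.append(df)
        truth_mutations = pd.concat(frames, ignore_index=True)
        truth_mutations = truth_mutations.drop_duplicates(
            ["sample_id", "chrom", "pos", "ref", "alt"]
        ).reset_index(drop=True)
        caller_calls, call_labels = inject_artifacts(
            truth_mutations,
            config.artifact_rates,
            rng,
            genome=genome,
            caller_dropout=config.caller_dropout,
        )

    # --- panel confirmation data (TAS + RNA) --------------------------------
    tas_rows, rna_rows = [], []
    if config.with_mutations and len(truth_mutations):
        panel = truth_mutations[truth_mutations["gene"] == PANEL_GENE]
        for row in panel.itertuples():
            key = f"{row.sample_id}:{row.chrom}:{row.pos}:{row.ref}>{row.alt}"
            vaf = row.t_alt / max(row.t_alt + row.t_ref, 1)
            tas = simulate_tas_reads(vaf, depth=2000, seed_or_rng=rng)
            tas_rows.append({"key": key, **tas})
            rna_total = int(np.round(np.exp(rng.normal(3.0, 1.1))))
            rna_alt = int(rng.binomial(rna_total, min(vaf * 1.2, 0.95))) if rna_total else 0
            rna_rows.append({"key": key, "alt": rna_alt, "total": rna_total})
    tas_reads = pd.DataFrame(tas_rows, columns=["key", "alt_t", "ref_t", "alt_c", "ref_c"])
    rna_counts = pd.DataFrame(rna_rows, columns=["key", "alt", "total"])

    # --- expression (gene x sample read counts) -----------------------------
    genes_expr = list(config.gene_freq_truth) + [f"G{g:04d}" for g in range(50)]
    expression = pd.DataFrame(
        rng.poisson(30, size=(len(genes_expr), n)),
        index=pd.Index(genes_expr, name="gene"),
        columns=sample_ids,
    )

    return CohortBundle(
        patients=patients,
        truth_mutations=truth_mutations,
        caller_calls=caller_calls,
        call_labels=call_labels,
        segments=segments,
        expression=expression,
        rna_counts=rna_counts,
        tas_reads=tas_reads,
        truth={
            "exposures": true_exposures,
            "weights": weights,
            "subtypes": subtypes,
            "hrd": hrd_truth,
            "context_matrix": context_matrix,
            "burden": pd.Series(burden, index=sample_ids, name="snvs_per_mb"),
            "planted_gene_counts": planted_freq,
            "latent": pd.DataFrame({"sample_id": sample_ids, "hrd_axis": u, "aging_axis": v}),
            "genome": genome,
        },
    )


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    """Write MAF-like TSV, SEG TSV, clinical CSV and a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.truth_mutations.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
    for caller, df in bundle.caller_calls.items():
        df.to_csv(out / f"calls_{caller}.maf.tsv", sep="\t", index=False)
    bundle.call_labels.to_csv(out / "call_labels.tsv", sep="\t", index=False)
    bundle.segments.to_csv(out / "segments.seg.tsv", sep="\t", index=False)
    bundle.patients.to_csv(out / "clinical.csv", index=False)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    bundle.rna_counts.to_csv(out / "rna_counts.tsv", sep="\t", index=False)
    bundle.tas_reads.to_csv(out / "tas_reads.tsv", sep="\t", index=False)
    truth = {
        "exposures": bundle.truth["exposures"].reset_index().to_dict(orient="list"),
        "subtypes": bundle.truth["subtypes"].reset_index().to_dict(orient="list"),
        "hrd": bundle.truth["hrd"].to_dict(orient="list"),
        "planted_gene_counts": bundle.truth["planted_gene_counts"],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
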