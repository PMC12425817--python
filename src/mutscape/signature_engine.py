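"""Mutational-signature analysis: context matrices, NMF extraction, refitting.

A tumor's catalog of single-base substitutions is summarized as counts over
the 96 trinucleotide channels (pyrimidine strand), indels over the 83
COSMIC indel channels.  De novo signatures are extracted by KL-divergence
NMF (the Poisson-consistent objective) with multiplicative updates, run as
many random restarts on bootstrap-resampled matrices; replicate solutions
are clustered by cosine distance and per-signature stability is reported
as the cluster silhouette.  Samples are refit against a reference catalog
by non-negative least squares with a backward-elimination sparsity step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_samples

from .catalogs import COMPLEMENT, id83_labels, sbs96_labels

_EPS = 1e-12


def cosine(u, v) -> float:
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# context matrices
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs_channel(ref: str, alt: str, context: str) -> str | None:
    """SBS96 channel for one substitution given its trinucleotide context.

    ``context`` is the 3-mer centered on the variant on the reported
    strand.  Purine-reference calls are reverse-complemented onto the
    pyrimidine strand.  Returns None for ambiguous (N-containing) input.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref or "N" in context or ref == alt:
        return None
    if ref in "AG":
        context = _revcomp(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_sbs_matrix(mutations: pd.DataFrame, samples=None) -> tuple[pd.DataFrame, int]:
    """Samples x 96 channel count matrix from an SNV table with ``context``.

    Returns ``(matrix, n_excluded)`` where excluded records had ambiguous
    contexts.  Row sums equal per-sample SNV counts minus exclusions.
    """
    labels = sbs96_labels()
    snvs = mutations[mutations["variant_class"] == "SNV"]
    if samples is None:
        samples = sorted(snvs["sample_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=labels)
    excluded = 0
    for row in snvs.itertuples():
        ch = sbs_channel(str(row.ref), str(row.alt), str(row.context))
        if ch is None:
            excluded += 1
            continue
        mat.loc[row.sample_id, ch] += 1
    return mat, excluded


def classify_indel(
    indel_type: str, seq: str, flank5: str, flank3: str, min_flank: int = 25
) -> str | None:
    """COSMIC ID83 channel for one insertion or deletion.

    ``seq`` is the inserted/deleted sequence, ``flank5``/``flank3`` the
    reference sequence immediately before/after the event.  Channels are
    assigned by indel length (1..5+), repeat-unit count of the indel motif
    in the adjacent sequence, and for non-repeat deletions >= 2 bp, the
    flanking microhomology length.  Returns None when flanks are too short
    to classify.
    """
    seq = seq.upper()
    flank5, flank3 = flank5.upper(), flank3.upper()
    if indel_type not in ("ins", "del"):
        raise ValueError("indel_type must be 'ins' or 'del'")
    if len(seq) == 0:
        raise ValueError("empty indel sequence")
    if min(len(flank5), len(flank3)) < min_flank:
        return None
    L = len(seq)
    size = min(L, 5)
    kind = "Del" if indel_type == "del" else "Ins"

    # adjacent copies of the motif on either side (alignment-invariant)
    repeats = 0
    i = 0
    while flank3[i : i + L] == seq:
        repeats += 1
        i += L
    i = len(flank5)
    while i - L >= 0 and flank5[i - L : i] == seq:
        repeats += 1
        i -= L

    if L == 1:
        base = seq if seq in "CT" else COMPLEMENT[seq]
        return f"1:{kind}:{base}:{min(repeats, 5)}"
    if repeats >= 1:
        return f"{size}:{kind}:R:{min(repeats, 5)}"
    if indel_type == "ins":
        return f"{size}:Ins:R:0"
    # deletion, not in a repeat: look for flanking microhomology
    mh3 = 0
    while mh3 < L - 1 and seq[mh3] == flank3[mh3]:
        mh3 += 1
    mh5 = 0
    while mh5 < L - 1 and seq[L - 1 - mh5] == flank5[len(flank5) - 1 - mh5]:
        mh5 += 1
    mh = max(mh3, mh5)
    if mh == 0:
        return f"{size}:Del:R:0"
    max_mh = 5 if size == 5 else size - 1
    return f"{size}:Del:M:{min(mh, max_mh)}"


def build_id_matrix(indels: pd.DataFrame, samples=None) -> tuple[pd.DataFrame, int]:
    """Samples x 83 channel matrix from an indel table.

    Expects columns ``sample_id``, ``indel_type``, ``seq``, ``flank5``,
    ``flank3``.  Unclassifiable records are excluded and counted.
    """
    labels = id83_labels()
    if samples is None:
        samples = sorted(indels["sample_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=labels)
    excluded = 0
    for row in indels.itertuples():
        ch = classify_indel(row.indel_type, row.seq, row.flank5, row.flank3)
        if ch is None:
            excluded += 1
            continue
        mat.loc[row.sample_id, ch] += 1
    return mat, excluded


# ---------------------------------------------------------------------------
# KL-divergence NMF
# ---------------------------------------------------------------------------


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    mask = V > 0
    term = np.zeros_like(V, dtype=float)
    term[mask] = V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))
    return float(term.sum() - V.sum() + WH.sum())


def klnmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Multiplicative-update NMF under the KL objective.

    ``V`` is channels x samples.  Returns column-stochastic ``W``
    (channels x k), ``H`` (k x samples), the objective trace (non-
    increasing), and a convergence flag.  Non-convergence returns the
    best iterate reached.
    """
    n_ch, n_s = V.shape
    if not (1 <= k <= min(n_ch, n_s)):
        raise ValueError("k out of range")
    W = rng.random((n_ch, k)) + 0.1
    H = rng.random((k, n_s)) + 0.1
    history = [kl_divergence(V, W @ H)]
    converged = False
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        history.append(kl_divergence(V, W @ H))
        if abs(history[-2] - history[-1]) <= tol * max(abs(history[-2]), 1.0):
            converged = True
            break
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return W, H, history, converged


@dataclass
class SignatureModel:
    """De novo signatures with per-signature stability and exposures."""

    signatures: pd.DataFrame          # channels x k, column-stochastic
    exposures: pd.DataFrame           # samples x k, mutation-count units
    stability: pd.Series              # mean silhouette per signature
    reconstruction_error: float       # 1 - mean per-sample cosine
    mean_stability: float = field(init=False)
    degenerate: bool = False
    converged: bool = True

    def __post_init__(self):
        self.mean_stability = float(self.stability.mean()) if len(self.stability) else np.nan

    @property
    def k(self) -> int:
        return self.signatures.shape[1]


def _nnls_exposures(matrix: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    W = signatures.to_numpy(float)
    expo = np.zeros((matrix.shape[0], W.shape[1]))
    for i, (_, row) in enumerate(matrix.iterrows()):
        expo[i], _ = nnls(W, row.to_numpy(float))
    return pd.DataFrame(expo, index=matrix.index, columns=signatures.columns)


def extract_denovo(
    matrix: pd.DataFrame,
    k_range=range(1, 7),
    n_replicates: int = 8,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    silhouette_min: float = 0.8,
) -> dict:
    """Stability-selected de novo signature extraction.

    For each candidate rank, NMF is re-run on ``n_replicates`` bootstrap-
    resampled matrices; the pooled replicate signatures are clustered by
    cosine distance and each consensus signature's silhouette measures its
    stability.  The selected rank is the largest one whose mean silhouette
    reaches ``silhouette_min`` with non-degenerate clusters (every cluster
    populated by at least half the replicates, no negative-silhouette
    signature).  Deterministic under a fixed seed.

    Returns ``{"models": {k: SignatureModel}, "selected_k": int,
    "selected": SignatureModel}``.
    """
    if matrix.shape[0] == 0 or float(matrix.to_numpy().sum()) == 0:
        raise ValueError("empty context matrix")
    rng = np.random.default_rng(seed)
    V0 = matrix.to_numpy(float).T  # channels x samples
    n_ch, n_s = V0.shape
    totals = V0.sum(axis=0)
    models: dict[int, SignatureModel] = {}
    for k in k_range:
        if k > min(n_ch, n_s):
            continue
        reps = []
        all_converged = True
        for _ in range(n_replicates):
            Vb = np.empty_like(V0)
            for j in range(n_s):
                tot = int(totals[j])
                if tot == 0:
                    Vb[:, j] = 0
                    continue
                Vb[:, j] = rng.multinomial(tot, V0[:, j] / totals[j])
            W, _, _, conv = klnmf(Vb, k, rng, max_iter=max_iter, tol=tol)
            all_converged &= conv
            reps.append(W)
        pooled = np.hstack(reps)  # channels x (k * n_replicates)
        X = pooled.T
        if k == 1:
            labels = np.zeros(X.shape[0], dtype=int)
            sil = np.ones(X.shape[0])
        else:
            clusterer = AgglomerativeClustering(
                n_clusters=k, metric="cosine", linkage="average"
            )
            labels = clusterer.fit_predict(X)
            sil = silhouette_samples(X, labels, metric="cosine")
        consensus = np.zeros((n_ch, k))
        per_sig_sil = np.zeros(k)
        sizes = np.zeros(k, dtype=int)
        for c in range(k):
            members = labels == c
            sizes[c] = members.sum()
            mean_vec = X[members].mean(axis=0)
            consensus[:, c] = mean_vec / max(mean_vec.sum(), _EPS)
            per_sig_sil[c] = float(sil[members].mean())
        order = np.argsort(-consensus.max(axis=0), kind="mergesort")
        consensus = consensus[:, order]
        per_sig_sil = per_sig_sil[order]
        sizes = sizes[order]
        names = [f"DN{chr(ord('A') + i)}" for i in range(k)]
        sig_df = pd.DataFrame(consensus, index=matrix.columns, columns=names)
        expo = _nnls_exposures(matrix, sig_df)
        recon = expo.to_numpy() @ sig_df.to_numpy().T
        cosines = [
            cosine(recon[i], V0[:, i]) for i in range(n_s) if totals[i] > 0
        ]
        degenerate = bool(
            (sizes < max(2, n_replicates // 2)).any() or (per_sig_sil < 0).any()
        )
        models[k] = SignatureModel(
            signatures=sig_df,
            exposures=expo,
            stability=pd.Series(per_sig_sil, index=names),
            reconstruction_error=1.0 - float(np.mean(cosines)) if cosines else np.nan,
            degenerate=degenerate,
            converged=all_converged,
        )
    eligible = [
        k
        for k, m in models.items()
        if m.mean_stability >= silhouette_min and not m.degenerate
    ]
    selected_k = max(eligible) if eligible else min(models)
    return {"models": models, "selected_k": selected_k, "selected": models[selected_k]}


# ---------------------------------------------------------------------------
# reference decomposition
# ---------------------------------------------------------------------------


def _fit_subset(v: np.ndarray, W: np.ndarray, active: list[int]) -> tuple[np.ndarray, float]:
    coef, _ = nnls(W[:, active], v)
    recon = W[:, active] @ coef
    return coef, cosine(recon, v)


def decompose_to_reference(
    samples: pd.DataFrame, catalog: pd.DataFrame, cosine_tol: float = 0.01
) -> pd.DataFrame:
    """Sparse NNLS refit of count vectors against a reference catalog.

    ``samples`` is samples x channels (counts; a signature matrix can be
    passed transposed), ``catalog`` channels x signatures with columns
    summing to one.  Each sample is fit by NNLS, then reference signatures
    are removed by backward elimination while the reconstruction cosine
    drops by less than ``cosine_tol`` per removal.  Exposures are in
    mutation-count units.
    """
    if list(samples.columns) != list(catalog.index):
        raise ValueError("channel ordering of samples and catalog must match")
    W = catalog.to_numpy(float)
    n_sig = W.shape[1]
    out = np.zeros((samples.shape[0], n_sig))
    for i, (_, row) in enumerate(samples.iterrows()):
        v = row.to_numpy(float)
        if v.sum() == 0:
            continue
        active = list(range(n_sig))
        coef, cos_full = _fit_subset(v, W, active)
        while len(active) > 1:
            best = None
            for j in range(len(active)):
                trial = active[:j] + active[j + 1 :]
                c_trial, cos_trial = _fit_subset(v, W, trial)
                if best is None or cos_trial > best[2]:
                    best = (j, c_trial, cos_trial)
            j, c_best, cos_best = best
            if cos_full - cos_best < cosine_tol:
                active.pop(j)
                coef, cos_full = c_best, cos_best
            else:
                break
        out[i, active] = coef
    return pd.DataFrame(out, index=samples.index, columns=catalog.columns)


def refit_exposures(
    samples: pd.DataFrame, catalog: pd.DataFrame, max_iter: int = 2000, tol: float = 0.0
) -> pd.DataFrame:
    """Maximum-likelihood exposure refit under the Poisson/KL model.

    With the signature matrix fixed, multiplicative KL updates on the
    exposures give the Poisson MLE for count data; compared with least
    squares this weights low-count channels correctly and has lower
    variance on multinomial counts.  Used for subtype-grade activity
    estimates; :func:`decompose_to_reference` remains the sparse refit.
    """
    if list(samples.columns) != list(catalog.index):
        raise ValueError("channel ordering of samples and catalog must match")
    W = catalog.to_numpy(float)
    V = samples.to_numpy(float).T  # channels x samples
    k, n = W.shape[1], V.shape[1]
    H = np.full((k, n), V.sum(axis=0) / k + _EPS)
    Wsum = np.maximum(W.sum(axis=0)[:, None], _EPS)
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / Wsum
        if tol > 0:
            obj = kl_divergence(V, np.maximum(W @ H, _EPS))
            if abs(prev - obj) <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    return pd.DataFrame(H.T, index=samples.index, columns=catalog.columns)


def exposure_correlations(
    exposures: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations between signature exposures and covariates.

    Pairs with fewer than 3 complete observations or zero variance yield
    NaN r and p.
    """
    rows = []
    for sig in exposures.columns:
        for cov in covariates.columns:
            paired = pd.concat(
                [exposures[sig], covariates[cov]], axis=1, join="inner"
            ).dropna()
            n = len(paired)
            x, y = paired.iloc[:, 0], paired.iloc[:, 1]
            if n < 3 or x.std() == 0 or y.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
            rows.append({"signature": sig, "covariate": cov, "n": n, "r": r, "p": p})
    return pd.DataFrame(rows)
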