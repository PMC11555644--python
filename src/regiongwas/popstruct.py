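"""Relatedness (IBD), principal components, and ancestry-outlier flagging.

Relatedness is the classical method-of-moments estimator: observed
identity-by-state (IBS) counts are compared with their expectations under
IBD states 0/1/2 given sample allele frequencies, and
pi_hat = P(IBD=1)/2 + P(IBD=2). Pairs sharing more than the threshold
(default 0.1875, halfway between second- and third-degree relatives) are
broken greedily.

PCA standardizes each SNP by sqrt(2 f (1-f)) after mean-imputing missing
calls (the imputation is for PCA only; association stages never see it) and
takes the top-k singular structure. Ancestry outliers are flagged by a
robust z-score (median/MAD) on PC1/PC2 relative to a reference subset — a
deterministic surrogate for the visual reference-cluster inspection usually
done by eye.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, StudyGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "RelatednessPair", "PcaResult", "pihat", "pihat_matrix",
    "relatedness_filter", "compute_pcs", "ancestry_outliers",
]


@dataclass(frozen=True)
class RelatednessPair:
    sid_a: str
    sid_b: str
    pi_hat: float

    def __post_init__(self):
        if not (0.0 <= self.pi_hat <= 1.02):
            raise ValueError(f"pi_hat {self.pi_hat} outside [0, 1.02]")


@dataclass
class PcaResult:
    """Top-k principal components of the standardized genotype matrix."""

    loadings: np.ndarray      # SNP x k
    scores: np.ndarray        # sample x k
    eigenvalues: np.ndarray   # k, non-increasing

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------

def _ibs_expectations(freq: np.ndarray) -> tuple[float, float, float, float]:
    """Sums over SNPs of P(IBS=s | IBD=z) needed by the moments estimator."""
    p = freq
    q = 1.0 - p
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p * q))
    return e0_ibd0, e1_ibd0, e1_ibd1, float(len(p))


def _pihat_from_ibs(n0: float, n1: float, n_obs: float,
                    e0_ibd0: float, e1_ibd0: float, e1_ibd1: float,
                    n_snps: float) -> float:
    """Solve the moments equations for P(IBD=0,1,2) and return pi_hat."""
    scale = n_obs / n_snps  # rescale expectations to the observed SNP count
    p0 = n0 / max(e0_ibd0 * scale, 1e-12)
    p1 = (n1 - p0 * e1_ibd0 * scale) / max(e1_ibd1 * scale, 1e-12)
    p0 = min(max(p0, 0.0), 1.0)
    p1 = min(max(p1, 0.0), 1.0 - p0)
    p2 = 1.0 - p0 - p1
    return p1 / 2.0 + p2


def pihat(study: StudyGenotypes, pair: tuple[str, str],
          min_overlap: int = 100) -> RelatednessPair:
    """Method-of-moments IBD sharing estimate for one sample pair."""
    sid_a, sid_b = pair
    sids = study.samples["sid"]
    ia = int(sids[sids == sid_a].index[0])
    ib = int(sids[sids == sid_b].index[0])
    da, db = study.dosage[ia], study.dosage[ib]
    both = (da != MISSING) & (db != MISSING)
    if both.sum() < min_overlap:
        raise RuntimeError(
            f"only {int(both.sum())} overlapping SNPs for ({sid_a}, {sid_b})")
    freq = study.allele_freq()[both]
    diff = np.abs(da[both].astype(np.int16) - db[both].astype(np.int16))
    n0 = float((diff == 2).sum())
    n1 = float((diff == 1).sum())
    e0, e10, e11, m = _ibs_expectations(freq)
    ph = _pihat_from_ibs(n0, n1, float(both.sum()), e0, e10, e11, float(both.sum()))
    return RelatednessPair(sid_a, sid_b, float(np.clip(ph, 0.0, 1.02)))


def pihat_matrix(study: StudyGenotypes) -> np.ndarray:
    """pi_hat for all sample pairs (vectorized; missing treated pairwise).

    For speed the expectations use all SNPs rather than the pairwise-complete
    subset; with missingness completely at random this is unbiased.
    """
    d = study.dosage.astype(np.float32)
    obs = (study.dosage != MISSING)
    d = np.where(obs, d, np.nan)
    n = study.n_samples
    freq = study.allele_freq()
    e0, e10, e11, m = _ibs_expectations(freq)

    # pair counts of |dose_i - dose_j| == 2 and == 1 via indicator products
    is0 = np.where(obs, (study.dosage == 0), 0).astype(np.float32)
    is1 = np.where(obs, (study.dosage == 1), 0).astype(np.float32)
    is2 = np.where(obs, (study.dosage == 2), 0).astype(np.float32)
    n_obs = obs.astype(np.float32) @ obs.astype(np.float32).T
    n_ibs0 = is0 @ is2.T + is2 @ is0.T
    n_ibs1 = is0 @ is1.T + is1 @ is0.T + is1 @ is2.T + is2 @ is1.T

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if n_obs[i, j] <= 0:
                continue
            ph = _pihat_from_ibs(float(n_ibs0[i, j]), float(n_ibs1[i, j]),
                                 float(n_obs[i, j]), e0, e10, e11, m)
            out[i, j] = out[j, i] = np.clip(ph, 0.0, 1.02)
    return out


def relatedness_filter(study: StudyGenotypes, threshold: float = 0.1875,
                       ) -> tuple[StudyGenotypes, list[RelatednessPair]]:
    """Drop samples until no pair shares IBD above the threshold (strict >).

    Greedy: repeatedly remove the sample in the most flagged pairs; within a
    tie, the member with the lower call rate goes (so for an isolated pair
    the lower-call-rate member is dropped); remaining tie, the
    lexicographically larger sid. Output is re-scanned to assert the
    invariant.
    """
    pm = pihat_matrix(study)
    sids = study.samples["sid"].to_numpy()
    call = study.call_rate_samples()
    flagged = [RelatednessPair(sids[i], sids[j], float(pm[i, j]))
               for i, j in zip(*np.where(np.triu(pm, 1) > threshold))]
    adj = pm > threshold
    np.fill_diagonal(adj, False)
    removed: set[int] = set()
    active = adj.copy()
    while active.any():
        deg = active.sum(axis=1)
        cand = np.flatnonzero(deg == deg.max())
        cand = cand[call[cand] == call[cand].min()]
        drop = cand[np.argmax(sids[cand])] if cand.size > 1 else cand[0]
        removed.add(int(drop))
        active[drop, :] = False
        active[:, drop] = False
    keep = np.array([i not in removed for i in range(study.n_samples)])
    filtered = study.subset_samples(keep)
    # invariant: no retained pair above threshold
    assert not (np.triu(pm[np.ix_(keep, keep)], 1) > threshold).any()
    return filtered, flagged


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def compute_pcs(study: StudyGenotypes, k: int = 7, seed: int = 0) -> PcaResult:
    """Top-k PCA of the standardized dosage matrix.

    Missing entries are mean-imputed (for PCA only); each SNP is centred at
    2f and scaled by sqrt(2 f (1-f)); monomorphic SNPs are dropped. The sign
    convention fixes each score column's largest-magnitude entry positive.
    """
    d = study.dosage.astype(np.float64)
    obs = study.dosage != MISSING
    freq = study.allele_freq()
    poly = (freq > 0) & (freq < 1) & np.isfinite(freq)
    d = np.where(obs, d, 2.0 * freq)[:, poly]
    f = freq[poly]
    Z = (d - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))

    max_k = min(Z.shape) - 1
    if k > max_k:
        warnings.warn(f"k={k} exceeds available rank; reduced to {max_k}")
        k = max_k
    n = Z.shape[0]
    if min(Z.shape) > 800:
        # iterative SVD for large matrices; deterministic via seeded start
        from scipy.sparse.linalg import svds
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(Z.shape))
        U, sv, Vt = svds(Z, k=k, v0=v0)
        order = np.argsort(sv)[::-1]
        U, sv, V = U[:, order], sv[order], Vt[order].T
    elif Z.shape[0] <= Z.shape[1]:
        G = Z @ Z.T
        w, U = np.linalg.eigh(G)
        idx = np.argsort(w)[::-1][:k]
        sv = np.sqrt(np.clip(w[idx], 0.0, None))
        U = U[:, idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            V = Z.T @ (U / np.where(sv > 0, sv, 1.0))
    else:
        C = Z.T @ Z
        w, V = np.linalg.eigh(C)
        idx = np.argsort(w)[::-1][:k]
        sv = np.sqrt(np.clip(w[idx], 0.0, None))
        V = V[:, idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            U = Z @ (V / np.where(sv > 0, sv, 1.0))
    scores = U * sv
    flip = np.sign(scores[np.abs(scores).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    V = V * flip
    eig = sv**2 / max(n - 1, 1)
    return PcaResult(loadings=V, scores=scores, eigenvalues=eig)


def ancestry_outliers(pcs: PcaResult, reference_mask: np.ndarray,
                      n_sd: float = 6.0) -> np.ndarray:
    """Flag samples far from the reference cluster on PC1/PC2.

    Robust z = (x - median_ref) / (1.4826 * MAD_ref); flagged when |z| > n_sd
    on either of the first two PCs. Degenerate MAD falls back to the SD with
    a warning. Sign flips of the PCs do not change the flag set.
    """
    ref = np.asarray(reference_mask, dtype=bool)
    if ref.sum() < 20:
        raise ValueError("reference subset must have >= 20 samples")
    flags = np.zeros(pcs.scores.shape[0], dtype=bool)
    for dim in range(min(2, pcs.scores.shape[1])):
        x = pcs.scores[:, dim]
        med = np.median(x[ref])
        mad = np.median(np.abs(x[ref] - med))
        scale = 1.4826 * mad
        if scale <= 0:
            warnings.warn(f"MAD degenerate on PC{dim + 1}; falling back to SD")
            scale = x[ref].std()
            if scale <= 0:
                continue
        flags |= np.abs(x - med) / scale > n_sd
    return flags
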