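"""Synthetic multi-study case-control genotype data with block LD structure.

The generator emulates the study design every downstream stage expects:
several parallel case-control studies drawn from one shared haplotype pool,
sparse causal regions of weak per-SNP effects (odds ratios around 1.1-1.5),
optional sex-restricted effects, age and sex covariates, genotype
missingness, and a held-out study that exists only as summary statistics.

Haplotypes come from a Li-Stephens-style copying process: each new haplotype
copies stretches of previously generated ones, switching template with a
small probability between adjacent SNPs (giving distance-decaying LD within a
block) and with a larger probability at block boundaries, plus a per-SNP
copying-error (mutation) rate. Only the second-moment structure matters to
the statistics under test, so this is deliberately simpler than a coalescent
simulation.

Disease status follows the same logistic model the analysis fits,
logit P(case) = logit(base_prev) + sum_j ln(OR_j) * g_j, with the effect term
applied only in the permitted sex for sex-restricted effects, so parameter
recovery is an exact oracle. All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit as logit_fn

from .io import MISSING, Region, StudyGenotypes, variant_frame
from ._glm import design_matrix, fit_logistic, SeparationError

__all__ = [
    "HaplotypePool", "EffectSpec", "AgeModel", "GenerationError",
    "SimulationError", "build_haplotype_pool", "simulate_study",
    "emit_summary_study", "null_z_sampler",
]


class GenerationError(RuntimeError):
    """Haplotype pool could not satisfy the requested allele-frequency range."""


class SimulationError(RuntimeError):
    """Case/control quotas unattainable within the retry budget."""


@dataclass
class HaplotypePool:
    """Shared pool of phased haplotypes with LD-block structure.

    haplotypes : uint8 array, n_haplotypes x n_snps (allele 1 = effect allele)
    block_bounds : list of (start, end) SNP-index intervals (half-open)
    maf : realized allele-1 frequency per SNP
    variants : variant metadata (chrom, pos, vid, a1, a2)
    """

    haplotypes: np.ndarray
    block_bounds: list[tuple[int, int]]
    maf: np.ndarray
    variants: pd.DataFrame

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class EffectSpec:
    """A causal region: which SNPs carry risk and for whom.

    or_per_allele is the odds ratio per copy of the effect allele, applied to
    each causal SNP; sex_restriction limits the effect to one sex
    ('male_only' / 'female_only') or applies it to 'both'.
    """

    region: Region
    causal_ids: tuple[str, ...]
    or_per_allele: float
    sex_restriction: str = "both"

    def __post_init__(self):
        if self.or_per_allele <= 0:
            raise ValueError("or_per_allele must be > 0")
        if self.sex_restriction not in ("both", "male_only", "female_only"):
            raise ValueError(f"bad sex_restriction {self.sex_restriction!r}")
        object.__setattr__(self, "causal_ids", tuple(self.causal_ids))


@dataclass(frozen=True)
class AgeModel:
    """Gaussian age distributions by phenotype (years).

    Defaults echo the adult-glioma age structure of typical case-control
    studies: cases around 55 (sd 15), controls around 56 (sd 15).
    """

    case_mean: float = 55.0
    case_sd: float = 15.0
    ctrl_mean: float = 56.0
    ctrl_sd: float = 15.0

    def draw(self, rng: np.random.Generator, is_case: np.ndarray) -> np.ndarray:
        mean = np.where(is_case, self.case_mean, self.ctrl_mean)
        sd = np.where(is_case, self.case_sd, self.ctrl_sd)
        return np.clip(rng.normal(mean, sd), 18.0, 95.0).round(1)


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------

def build_haplotype_pool(
    n_hap: int,
    n_snp: int,
    block_len: int = 25,
    recomb_between_blocks: float = 0.3,
    maf_range: tuple[float, float] = (0.05, 0.5),
    mutation: float = 0.005,
    recomb_within: float = 0.003,
    n_seed_haplotypes: int = 10,
    spacing_bp: int = 4000,
    chrom: str = "1",
    start_bp: int = 1,
    seed: int = 0,
    max_retries: int = 30,
) -> HaplotypePool:
    """Generate a haplotype pool by template copying.

    block_len is in SNPs; spacing_bp sets a regular physical grid (about one
    array SNP per 4 kb at the default). Columns whose realized frequency
    falls outside maf_range are regenerated along the same template chains
    with a fresh base frequency; persistent failures raise GenerationError.
    """
    if n_hap < 100:
        raise ValueError("n_hap must be >= 100")
    if not (0 < recomb_between_blocks <= 0.5):
        raise ValueError("recomb_between_blocks must be in (0, 0.5]")
    lo, hi = maf_range
    if not (0.01 <= lo < hi <= 0.99):
        raise ValueError("maf_range must satisfy 0.01 <= lo < hi <= 0.99")
    rng = np.random.default_rng(seed)

    block_bounds = [(s, min(s + block_len, n_snp)) for s in range(0, n_snp, block_len)]
    # per-SNP template-switch probability for the transition (j-1 -> j)
    switch_p = np.full(n_snp, recomb_within)
    boundary = np.zeros(n_snp, dtype=bool)
    for s, _ in block_bounds[1:]:
        boundary[s] = True
    switch_p[boundary] = recomb_between_blocks
    switch_p[0] = 1.0

    base_freq = rng.uniform(lo, hi, size=n_snp)
    # few founders -> realistic block LD (pool r2 scales like 1/n_seed)
    n_seed = min(n_seed_haplotypes, n_hap)
    H = np.empty((n_hap, n_snp), dtype=np.uint8)
    H[:n_seed] = rng.random((n_seed, n_snp)) < base_freq
    # remember each haplotype's template chain so out-of-range columns can be
    # regenerated without disturbing the LD structure
    tmpl = np.zeros((n_hap, n_snp), dtype=np.int32)
    tmpl[:n_seed] = np.arange(n_seed)[:, None]
    col = np.arange(n_snp)
    for h in range(n_seed, n_hap):
        switch = rng.random(n_snp) < switch_p
        seg = np.cumsum(switch) - 1
        choices = rng.integers(0, h, size=seg[-1] + 1)
        t = choices[seg]
        hap = H[t, col]
        mut = rng.random(n_snp) < mutation
        H[h] = np.where(mut, 1 - hap, hap)
        tmpl[h] = t

    freq = H.mean(axis=0)
    bad = np.flatnonzero((freq < lo) | (freq > hi))
    tries = 0
    while bad.size:
        tries += 1
        if tries > max_retries:
            raise GenerationError(
                f"{bad.size} SNPs outside maf_range {maf_range} after "
                f"{max_retries} retries")
        new_base = rng.uniform(lo, hi, size=bad.size)
        H[:n_seed, bad] = rng.random((n_seed, bad.size)) < new_base
        for h in range(n_seed, n_hap):
            hap = H[tmpl[h, bad], bad]
            mut = rng.random(bad.size) < mutation
            H[h, bad] = np.where(mut, 1 - hap, hap)
        freq_bad = H[:, bad].mean(axis=0)
        bad = bad[(freq_bad < lo) | (freq_bad > hi)]

    pos = start_bp + spacing_bp * np.arange(n_snp)
    alleles_a1 = rng.choice(list("ACGT"), size=n_snp)
    # pick a2 different from a1; complements allowed so strand-ambiguous
    # pairs occur at a realistic rate
    offsets = rng.integers(1, 4, size=n_snp)
    lut = np.array(list("ACGT"))
    a1_idx = np.searchsorted(lut, alleles_a1)
    alleles_a2 = lut[(a1_idx + offsets) % 4]
    variants = variant_frame(
        chrom=np.full(n_snp, chrom), pos=pos,
        vid=[f"snp{chrom}_{p}" for p in pos],
        a1=alleles_a1, a2=alleles_a2)
    return HaplotypePool(H, block_bounds, H.mean(axis=0), variants)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

def _causal_indices(pool: HaplotypePool, effects) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve effect specs to (snp index, ln OR, sex code) arrays.

    sex code: 0 = both, 1 = male only, 2 = female only.
    """
    vid_to_idx = {v: i for i, v in enumerate(pool.variants["vid"])}
    idx, lnor, sexc = [], [], []
    code = {"both": 0, "male_only": 1, "female_only": 2}
    pos0 = pool.variants["pos"].to_numpy() - 1
    chroms = pool.variants["chrom"].to_numpy()
    for eff in effects:
        for vid in eff.causal_ids:
            if vid not in vid_to_idx:
                raise ValueError(f"causal SNP {vid} not in pool")
            j = vid_to_idx[vid]
            r = eff.region
            if not (chroms[j] == r.chrom and r.start <= pos0[j] < r.end):
                raise ValueError(f"causal SNP {vid} outside its region {r.label}")
            idx.append(j)
            lnor.append(np.log(eff.or_per_allele))
            sexc.append(code[eff.sex_restriction])
    return (np.asarray(idx, dtype=int), np.asarray(lnor, dtype=float),
            np.asarray(sexc, dtype=int))


def _jitter_targets(pool: HaplotypePool, maf_jitter: float,
                    rng: np.random.Generator) -> np.ndarray | None:
    """Per-study target frequencies: a bounded Beta(2,2) perturbation.

    Emulates between-study allele-frequency heterogeneity (different arrays,
    populations); maf_jitter = 0 reproduces the pool exactly.
    """
    if maf_jitter <= 0:
        return None
    f = pool.maf
    u = rng.beta(2.0, 2.0, size=f.size)  # centred on 0.5
    return np.clip((1.0 - maf_jitter) * f + maf_jitter * u, 0.01, 0.99)


def _flip_probs(f: np.ndarray, f_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry flip probabilities moving allele frequency f -> f_new."""
    up = np.clip((f_new - f) / np.maximum(1.0 - f, 1e-9), 0.0, 1.0)   # 0 -> 1
    down = np.clip((f - f_new) / np.maximum(f, 1e-9), 0.0, 1.0)       # 1 -> 0
    return up, down


def simulate_study(
    pool: HaplotypePool,
    n_case: int,
    n_ctrl: int,
    effects=(),
    base_prev: float = 0.1,
    age_model: AgeModel | None = AgeModel(),
    missing_rate: float = 0.0,
    sex_ratio_male: float = 0.5,
    maf_jitter: float = 0.0,
    study_label: str = "study",
    seed: int = 0,
    max_batches: int = 400,
) -> StudyGenotypes:
    """Simulate one case-control study from the pool.

    Individuals are drawn as random haplotype pairs (with replacement),
    assigned sex, then case status from the logistic disease model; rejection
    sampling continues until exactly n_case cases and n_ctrl controls are
    collected. Genotypes are then materialized for the accepted individuals
    and masked missing completely at random at missing_rate.
    """
    rng = np.random.default_rng(seed)
    cidx, lnor, sexc = _causal_indices(pool, effects)
    f_new = _jitter_targets(pool, maf_jitter, rng)
    alpha = logit_fn(base_prev)

    need = {True: n_case, False: n_ctrl}
    kept_h1, kept_h2, kept_sex, kept_case = [], [], [], []
    kept_causal = []  # per accepted individual, alleles at causal SNPs (2 x k)
    batch = max(1024, 2 * (n_case + n_ctrl))
    n_batches = 0
    while need[True] > 0 or need[False] > 0:
        n_batches += 1
        if n_batches > max_batches:
            raise SimulationError(
                f"could not collect {n_case} cases / {n_ctrl} controls within "
                f"{max_batches} batches (base_prev={base_prev})")
        h1 = rng.integers(0, pool.n_haplotypes, size=batch)
        h2 = rng.integers(0, pool.n_haplotypes, size=batch)
        is_male = rng.random(batch) < sex_ratio_male
        if cidx.size:
            a1 = pool.haplotypes[h1[:, None], cidx].astype(np.int8)
            a2 = pool.haplotypes[h2[:, None], cidx].astype(np.int8)
            if f_new is not None:
                up, down = _flip_probs(pool.maf[cidx], f_new[cidx])
                for a in (a1, a2):
                    r = rng.random(a.shape)
                    a[:] = np.where(a == 0, (r < up).astype(np.int8),
                                    1 - (r < down).astype(np.int8))
            g = a1 + a2
            active = np.ones((batch, cidx.size), dtype=bool)
            active[:, sexc == 1] &= is_male[:, None]
            active[:, sexc == 2] &= ~is_male[:, None]
            eta = alpha + (g * lnor * active).sum(axis=1)
        else:
            g = a1 = a2 = None
            eta = np.full(batch, alpha)
        case = rng.random(batch) < expit(eta)
        for want_case in (True, False):
            if need[want_case] == 0:
                continue
            pick = np.flatnonzero(case == want_case)[: need[want_case]]
            need[want_case] -= pick.size
            kept_h1.append(h1[pick]); kept_h2.append(h2[pick])
            kept_sex.append(is_male[pick])
            kept_case.append(np.full(pick.size, want_case))
            if cidx.size:
                kept_causal.append(np.stack([a1[pick], a2[pick]], axis=1))

    h1 = np.concatenate(kept_h1); h2 = np.concatenate(kept_h2)
    is_male = np.concatenate(kept_sex); is_case = np.concatenate(kept_case)
    order = rng.permutation(h1.size)
    h1, h2, is_male, is_case = h1[order], h2[order], is_male[order], is_case[order]

    A1 = pool.haplotypes[h1].astype(np.int8)
    A2 = pool.haplotypes[h2].astype(np.int8)
    if f_new is not None:
        up, down = _flip_probs(pool.maf, f_new)
        for A in (A1, A2):
            r = rng.random(A.shape)
            A[:] = np.where(A == 0, (r < up).astype(np.int8),
                            1 - (r < down).astype(np.int8))
    if cidx.size:
        causal = np.concatenate(kept_causal)[order]  # n x 2 x k
        A1[:, cidx] = causal[:, 0, :]
        A2[:, cidx] = causal[:, 1, :]
    dosage = (A1 + A2).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING

    n = dosage.shape[0]
    ages = (age_model.draw(rng, is_case) if age_model is not None
            else np.full(n, np.nan))
    samples = pd.DataFrame({
        "sid": [f"{study_label}_{i:06d}" for i in range(n)],
        "phenotype": np.where(is_case, "case", "control"),
        "sex": np.where(is_male, "male", "female"),
        "age": ages,
        "study": study_label,
    })
    return StudyGenotypes(samples, pool.variants.copy(), dosage)


# ---------------------------------------------------------------------------
# summary-only study
# ---------------------------------------------------------------------------

def emit_summary_study(
    pool: HaplotypePool,
    n_case: int,
    n_ctrl: int,
    effects=(),
    seed: int = 0,
    covariates: tuple[str, ...] = ("sex", "age"),
    variant_mask: np.ndarray | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Simulate a study and return only its per-SNP summary statistics.

    Runs a covariate-adjusted logistic regression for every SNP (optionally
    restricted by variant_mask) and discards the genotypes, emulating a
    validation study available only as summary statistics. SNPs whose fit
    does not converge are omitted.
    """
    study = simulate_study(pool, n_case, n_ctrl, effects=effects, seed=seed,
                           **sim_kwargs)
    y = study.y.astype(float)
    X0 = design_matrix(study.samples, covariates)
    idx = (np.arange(study.n_variants) if variant_mask is None
           else np.flatnonzero(np.asarray(variant_mask)))
    d = study.dosage[:, idx].astype(float)
    obs = d >= 0
    col_mean = np.where(obs, d, 0).sum(0) / np.maximum(obs.sum(0), 1)
    d = np.where(obs, d, col_mean)  # mean-impute for the regression only

    from scipy.stats import norm
    rows = []
    v = study.variants
    nca = int((y == 1).sum()); nco = int((y == 0).sum())
    X = np.column_stack([X0, np.zeros(len(y))])
    for k, j in enumerate(idx):
        X[:, -1] = d[:, k]
        try:
            beta, cov = fit_logistic(X, y)
        except SeparationError:
            continue
        b = beta[-1]
        se = float(np.sqrt(cov[-1, -1]))
        p = float(2.0 * norm.sf(abs(b) / se))
        rows.append((v["chrom"].iat[j], int(v["pos"].iat[j]), v["vid"].iat[j],
                     v["a1"].iat[j], v["a2"].iat[j], float(b), se,
                     min(max(p, 5e-324), 1.0), nca, nco))
    out = pd.DataFrame(rows, columns=[
        "chrom", "pos", "vid", "a1", "a2", "beta", "se", "p", "n_case", "n_ctrl"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# correlated null z draws (GBJ null calibration input)
# ---------------------------------------------------------------------------

def null_z_sampler(sigma: np.ndarray, n_draws: int, seed: int = 0) -> np.ndarray:
    """Draw n_draws rows from N(0, sigma) with unit-diagonal correlation sigma.

    Negative eigenvalues (numerical indefiniteness) are clipped at zero for
    PSD repair; the clip amount is logged when it exceeds 1e-8.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"sigma must be square, got {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    w, V = np.linalg.eigh(sigma)
    clip = float(-w.min()) if w.min() < 0 else 0.0
    if clip > 1e-8:
        import logging
        logging.getLogger(__name__).warning(
            "null_z_sampler: clipped eigenvalues by %.3g for PSD repair", clip)
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_draws, sigma.shape[0])) @ (V * np.sqrt(w)).T
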