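"""Per-SNP logistic association, weighted-Z meta-analysis and sex-difference tests.

Per-study effects are Wald estimates from covariate-adjusted logistic
regression (beta = log odds per effect-allele copy, 95% CI =
exp(beta +/- 1.96 se)). Studies combine by the sample-size-weighted Z
(Stouffer) fixed-effects model,

    z_i = sign_i * Phi^{-1}(1 - p_i/2),
    z_meta = sum_i sqrt(n_eff,i) z_i / sqrt(sum_i n_eff,i),

with the effective case-control size n_eff = 4 / (1/N_case + 1/N_ctrl) as
the default weight (equal-information size of a balanced study; total-N
weighting is available but fits published case-control meta results
demonstrably worse when case:control ratios differ across studies).

Sex heterogeneity of an effect is tested by
beta_diff = beta_female - beta_male with
se_diff = sqrt(se_female^2 + se_male^2) and a two-sided normal p-value;
printed OR/CI tables can be fed in through :func:`beta_from_or_ci`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Region, StudyGenotypes
from ._glm import SeparationError, fit_logistic

__all__ = [
    "SnpAssoc", "MetaSnpResult", "SexDiffResult", "snp_logistic",
    "beta_from_or_ci", "effective_n", "weighted_z_meta", "sex_difference",
    "bonferroni_threshold", "meta_region_test",
]

_Z975 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class SnpAssoc:
    """One SNP's association result in one study/stratum."""

    vid: str
    beta: float
    se: float
    n_case: int
    n_ctrl: int
    stratum: str = "all"

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be > 0")

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def l95(self) -> float:
        return float(np.exp(self.beta - _Z975 * self.se))

    @property
    def u95(self) -> float:
        return float(np.exp(self.beta + _Z975 * self.se))

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass(frozen=True)
class MetaSnpResult:
    vid: str
    z_meta: float
    p_meta: float
    weights: tuple[float, ...]
    directions: str  # one of '+'/'-' per study, in input order

    def __post_init__(self):
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class SexDiffResult:
    vid: str
    beta_diff: float  # beta_female - beta_male
    se_diff: float
    p_diff: float


# ---------------------------------------------------------------------------
# per-study logistic
# ---------------------------------------------------------------------------

def snp_logistic(study: StudyGenotypes, vid: str,
                 X: np.ndarray | None = None,
                 stratum: str = "all") -> SnpAssoc:
    """Wald logistic association of one SNP, adjusted for covariates X.

    Missing genotype calls are dropped (the SNP's rows), not imputed.
    Raises :class:`~regiongwas._glm.SeparationError` on non-convergence and
    ValueError on a constant SNP.
    """
    j = study.variants.index[study.variants["vid"] == vid]
    if len(j) == 0:
        raise KeyError(f"SNP {vid} not in study")
    g = study.dosage[:, int(j[0])].astype(float)
    y = study.y.astype(float)
    if X is None:
        X = np.ones((len(y), 1))
    keep = g >= 0
    g, y, Xk = g[keep], y[keep], X[keep]
    if np.ptp(g) == 0:
        raise ValueError(f"SNP {vid} is constant in the analysis sample")
    design = np.column_stack([Xk, g])
    beta, cov = fit_logistic(design, y)
    return SnpAssoc(vid=vid, beta=float(beta[-1]),
                    se=float(np.sqrt(cov[-1, -1])),
                    n_case=int(y.sum()), n_ctrl=int((1 - y).sum()),
                    stratum=stratum)


def beta_from_or_ci(or_: float, l95: float, u95: float) -> tuple[float, float]:
    """Recover (beta, se) from a printed OR with 95% CI.

    beta = ln OR; se = (ln U95 - ln L95) / (2 * 1.96), the normal-theory CI
    width on the log scale.
    """
    if not (0 < l95 < or_ < u95):
        raise ValueError(f"need 0 < l95 < or < u95, got ({or_}, {l95}, {u95})")
    return float(np.log(or_)), float((np.log(u95) - np.log(l95)) / (2.0 * _Z975))


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def effective_n(n_case: int, n_ctrl: int) -> float:
    """Effective sample size 4 / (1/N_case + 1/N_ctrl) of a case-control study."""
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("both group sizes must be positive")
    return 4.0 / (1.0 / n_case + 1.0 / n_ctrl)


def weighted_z_meta(entries, vid: str = "") -> MetaSnpResult:
    """Sample-size-weighted Z (Stouffer) fixed-effects meta-analysis.

    entries: iterable of (p, direction, n_eff) with p the two-sided p-value,
    direction +1/-1 (sign of the effect), n_eff the weighting sample size.
    p = 0 is clipped to the smallest positive float with a warning.
    """
    entries = list(entries)
    if len(entries) < 2:
        raise ValueError("meta-analysis needs >= 2 studies")
    ps = np.array([e[0] for e in entries], dtype=float)
    signs = np.array([np.sign(e[1]) for e in entries], dtype=float)
    ns = np.array([e[2] for e in entries], dtype=float)
    if (ps <= 0).any():
        import warnings
        warnings.warn("p = 0 input clipped to the smallest representable value")
        ps = np.clip(ps, 5e-324, None)
    if (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (signs == 0).any():
        raise ValueError("directions must be nonzero")
    z = signs * stats.norm.isf(ps / 2.0)
    w = np.sqrt(ns)
    z_meta = float(w @ z / np.sqrt(ns.sum()))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return MetaSnpResult(vid=vid, z_meta=z_meta, p_meta=max(p_meta, 5e-324),
                         weights=tuple(ns),
                         directions="".join("+" if s > 0 else "-" for s in signs))


def sex_difference(female: SnpAssoc, male: SnpAssoc) -> SexDiffResult:
    """Two-sided normal test of beta_female - beta_male."""
    if female.vid != male.vid:
        raise ValueError("sex-difference test needs the same SNP in both sexes")
    bd = female.beta - male.beta
    sd = float(np.hypot(female.se, male.se))
    p = float(2.0 * stats.norm.sf(abs(bd) / sd))
    return SexDiffResult(vid=female.vid, beta_diff=float(bd), se_diff=sd, p_diff=p)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# region test on meta results
# ---------------------------------------------------------------------------

def meta_region_test(meta_results, region: Region,
                     ld_reference: StudyGenotypes, config=None):
    """GBJ on the per-SNP meta z-scores of a region, with reference LD.

    meta_results: iterable of MetaSnpResult for SNPs in the region (vids must
    exist in the reference). Reuses the summary-statistics region test with
    z_meta as the per-SNP evidence.
    """
    import pandas as pd

    from .regiontest import GbjConfig, test_region_summary

    config = config or GbjConfig()
    metas = [m for m in meta_results]
    if not metas:
        raise ValueError("no meta results supplied")
    ref = ld_reference.variants.set_index("vid")
    rows = []
    for m in metas:
        if m.vid not in ref.index:
            continue
        v = ref.loc[m.vid]
        # encode z_meta as beta=z, se=1 so that beta/se reproduces z
        rows.append((str(v["chrom"]), int(v["pos"]), m.vid, v["a1"], v["a2"],
                     m.z_meta, 1.0, max(m.p_meta, 5e-324), 1, 1))
    ss = pd.DataFrame(rows, columns=[
        "chrom", "pos", "vid", "a1", "a2", "beta", "se", "p", "n_case", "n_ctrl"])
    ss = ss.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return test_region_summary(ss, region, ld_reference, config=config)
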