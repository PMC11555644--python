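"""Sample- and SNP-level quality control with an auditable exclusion report.

Filter cascade (fixed order, samples first so SNP statistics are computed on
the retained samples):

1. samples: missing phenotype/sex, then call rate < threshold;
2. SNPs: call rate < threshold, differential case/control missingness
   (Fisher exact), minor allele frequency < threshold (strict: MAF exactly at
   the threshold is retained), Hardy-Weinberg exact test in controls —
   overall and additionally within male-only and female-only controls (a
   guard against sex-specific genotyping error).

Every filter logs removed/retained counts into a :class:`QcReport`, so the
full exclusion cascade can be reconstructed. Filters are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, StudyGenotypes

__all__ = [
    "QcReport", "hwe_exact_pvalue", "differential_missingness_pvalue",
    "snp_filters", "sample_filters", "find_duplicates",
]


@dataclass
class QcReport:
    """Per-filter exclusion ledger plus the per-unit statistics behind it."""

    steps: list[dict] = field(default_factory=list)
    snp_stats: pd.DataFrame | None = None
    sample_stats: pd.DataFrame | None = None

    def record(self, filter_name: str, unit: str, n_in: int, n_removed: int) -> None:
        self.steps.append({
            "filter": filter_name, "unit": unit, "n_in": int(n_in),
            "n_removed": int(n_removed), "n_retained": int(n_in - n_removed),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["filter", "unit", "n_in", "n_removed", "n_retained"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts: over heterozygote counts with the same
    parity and allele total, sums the probabilities of all outcomes whose
    conditional probability is <= that of the observed count (the standard
    exact formulation; well-defined at low counts where the chi-square
    approximation is not).
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    # work with the rarer allele
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # P(het = h | allele counts) proportional to
    #   2^h / (hom_rare! * hom_common! * h!)
    # over het counts h with the parity of the rare-allele total
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln
    logw = (hets * np.log(2.0) - gammaln(hom_r + 1.0)
            - gammaln(hom_c + 1.0) - gammaln(hets + 1.0))
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[(hets == n_ab).argmax()]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def differential_missingness_pvalue(miss_case: int, n_case: int,
                                    miss_ctrl: int, n_ctrl: int) -> float:
    """Two-sided Fisher exact test on the missing/observed x case/control table."""
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("group sizes must be positive")
    if miss_case > n_case or miss_ctrl > n_ctrl:
        raise ValueError("missing count exceeds group size")
    table = [[miss_case, n_case - miss_case], [miss_ctrl, n_ctrl - miss_ctrl]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _genotype_counts(dosage: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Counts of dosage 2/1/0 (hom-a1 / het / hom-a2) per SNP over rows."""
    d = dosage[rows]
    return np.stack([(d == 2).sum(0), (d == 1).sum(0), (d == 0).sum(0)], axis=1)


def sample_filters(study: StudyGenotypes, call_rate_min: float = 0.95,
                   report: QcReport | None = None) -> tuple[StudyGenotypes, QcReport]:
    """Remove samples with missing phenotype/sex or low genotyping call rate."""
    report = report or QcReport()
    n0 = study.n_samples
    has_pheno = (study.samples["phenotype"].isin(["case", "control"])
                 & study.samples["sex"].isin(["male", "female"])).to_numpy()
    report.record("missing_phenotype_or_sex", "samples", n0, int((~has_pheno).sum()))
    study = study.subset_samples(has_pheno)

    cr = study.call_rate_samples()
    keep = cr >= call_rate_min
    report.record("sample_call_rate", "samples", study.n_samples, int((~keep).sum()))
    report.sample_stats = pd.DataFrame({
        "sid": study.samples["sid"], "call_rate": cr, "retained": keep})
    study = study.subset_samples(keep)
    if study.n_samples == 0:
        raise RuntimeError("all samples removed by QC; downstream stages undefined")
    return study, report


def snp_filters(study: StudyGenotypes, call_rate_min: float = 0.95,
                maf_min: float = 0.01, hwe_alpha: float = 1e-5,
                diffmiss_alpha: float = 1e-5,
                report: QcReport | None = None) -> tuple[StudyGenotypes, QcReport]:
    """Apply the SNP filter cascade; returns the filtered study and report.

    Removal is strict-inequality throughout: call rate < threshold,
    MAF < threshold, p < alpha.
    """
    report = report or QcReport()
    if study.n_variants == 0:
        return study, report
    d = study.dosage
    y = study.y.astype(bool)
    female = (study.samples["sex"] == "female").to_numpy()
    obs = d != MISSING

    call_rate = obs.mean(axis=0)
    n_case = int(y.sum()); n_ctrl = int((~y).sum())
    miss_case = (~obs[y]).sum(axis=0)
    miss_ctrl = (~obs[~y]).sum(axis=0)
    diffmiss_p = np.ones(study.n_variants)
    if n_case and n_ctrl:
        candidates = np.flatnonzero((miss_case + miss_ctrl) > 0)
        for j in candidates:
            diffmiss_p[j] = differential_missingness_pvalue(
                int(miss_case[j]), n_case, int(miss_ctrl[j]), n_ctrl)
    freq = study.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)

    ctrl = ~y
    hwe_p = np.ones(study.n_variants)
    hwe_p_m = np.ones(study.n_variants)
    hwe_p_f = np.ones(study.n_variants)
    for out, rows in ((hwe_p, ctrl), (hwe_p_m, ctrl & ~female), (hwe_p_f, ctrl & female)):
        if rows.sum() == 0:
            continue
        counts = _genotype_counts(d, np.flatnonzero(rows))
        for j in range(study.n_variants):
            if counts[j].sum() > 0:
                out[j] = hwe_exact_pvalue(*counts[j])

    keep = np.ones(study.n_variants, dtype=bool)
    cascade = [
        ("snp_call_rate", call_rate < call_rate_min),
        ("differential_missingness", diffmiss_p < diffmiss_alpha),
        ("maf", maf < maf_min),
        ("hwe_controls", hwe_p < hwe_alpha),
        ("hwe_male_controls", hwe_p_m < hwe_alpha),
        ("hwe_female_controls", hwe_p_f < hwe_alpha),
    ]
    for name, fail in cascade:
        removed = keep & fail
        report.record(name, "snps", int(keep.sum()), int(removed.sum()))
        keep &= ~fail

    report.snp_stats = pd.DataFrame({
        "vid": study.variants["vid"],
        "call_rate": call_rate, "maf": maf,
        "diffmiss_p": diffmiss_p, "hwe_p": hwe_p,
        "hwe_p_male_controls": hwe_p_m, "hwe_p_female_controls": hwe_p_f,
        "retained": keep,
    })
    return study.subset_variants(keep), report


def run_qc(study: StudyGenotypes, call_rate_min_samples: float = 0.95,
           call_rate_min_snps: float = 0.95, maf_min: float = 0.01,
           hwe_alpha: float = 1e-5, diffmiss_alpha: float = 1e-5,
           ) -> tuple[StudyGenotypes, QcReport]:
    """Full cascade: sample filters first, then SNP filters, one report."""
    study, report = sample_filters(study, call_rate_min_samples)
    return snp_filters(study, call_rate_min_snps, maf_min, hwe_alpha,
                       diffmiss_alpha, report=report)


def find_duplicates(study: StudyGenotypes, other: StudyGenotypes | None = None,
                    concordance_min: float = 0.95, min_shared: int = 100,
                    ) -> pd.DataFrame:
    """Flag (cross-)study duplicate samples by genotype concordance.

    Compares every sample pair (within the study, or across two studies over
    their shared SNPs) and reports pairs whose exact-genotype concordance over
    jointly non-missing SNPs exceeds concordance_min.
    """
    if other is None:
        other = study
        within = True
    else:
        within = False
    shared = np.intersect1d(study.variants["vid"], other.variants["vid"])
    if shared.size < min_shared:
        raise ValueError(f"only {shared.size} shared SNPs (< {min_shared})")
    ia = study.variants.set_index("vid").index.get_indexer(shared)
    ib = other.variants.set_index("vid").index.get_indexer(shared)
    da = study.dosage[:, ia]
    db = other.dosage[:, ib]
    rows = []
    for i in range(da.shape[0]):
        j0 = i + 1 if within else 0
        both = (da[i] != MISSING) & (db[j0:] != MISSING)
        match = (da[i] == db[j0:]) & both
        n_obs = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            conc = np.where(n_obs > 0, match.sum(axis=1) / np.maximum(n_obs, 1), 0.0)
        for k in np.flatnonzero((conc > concordance_min) & (n_obs >= min_shared)):
            rows.append((study.samples["sid"].iat[i],
                         other.samples["sid"].iat[j0 + k], float(conc[k])))
    return pd.DataFrame(rows, columns=["sid_a", "sid_b", "concordance"])
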