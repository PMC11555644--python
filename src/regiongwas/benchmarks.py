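"""Reproducible calibration studies and worked examples.

Every function here recomputes a quantity from scratch — analytic ledgers,
published-table reconstructions, and seeded simulation studies of the
screen's and the region test's operating characteristics. They are shared by
the test suite and by ``scripts/acceptance.py`` so the numbers asserted and
the numbers reported come from the same code path.

Seeding: each study derives its own independent integer streams from
``numpy.random.SeedSequence([base_seed, study_tag])``, so a single base seed
reproduces everything and studies stay decoupled.
"""

from __future__ import annotations

import numpy as np
from numpy.random import SeedSequence
from scipy import stats

from .io import Region
from .meta import (beta_from_or_ci, bonferroni_threshold, effective_n,
                   sex_difference, weighted_z_meta, SnpAssoc, snp_logistic)
from .pipeline import PipelineConfig, run_stage1, run_stage2
from .regiontest import GbjConfig, _SigmaContext, _gbj_stats
from .screen import TreePrior, WindowModel, bootstrap_null, make_windows
from .simulate import (EffectSpec, build_haplotype_pool, null_z_sampler,
                       simulate_study)

__all__ = [
    "bonferroni_ledgers", "screen_conventions", "worked_single_study_examples",
    "worked_meta_examples", "gbj_calibration", "screen_calibration",
    "end_to_end_recovery", "sex_difference_recovery", "oracle_equivalences",
]


def _seeds(base_seed: int, tag: int, n: int) -> list[int]:
    state = SeedSequence([int(base_seed), int(tag)]).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# analytic ledgers and conventions
# ---------------------------------------------------------------------------

def bonferroni_ledgers() -> dict:
    """Family-wise thresholds for 61 regions and 15,148 SNPs at alpha 0.05."""
    return {
        "region_threshold_61": bonferroni_threshold(0.05, 61),
        "snp_threshold_15148": bonferroni_threshold(0.05, 15_148),
    }


def screen_conventions() -> dict:
    """The PLO odds convention and the relatedness cutoff's definition."""
    prior = TreePrior()
    # PLO is a base-10 posterior log-odds with unit prior odds: a score of
    # 2.0 means posterior odds of 10^2
    posterior_odds_at_plo2 = 10.0 ** (2.0 - prior.prior_log10_odds)
    # the relatedness cutoff sits halfway between the expected sharing of
    # second-degree (0.25) and third-degree (0.125) relatives
    ibd_cutoff = (0.25 + 0.125) / 2.0
    return {"posterior_odds_at_plo2": posterior_odds_at_plo2,
            "ibd_cutoff_midpoint": ibd_cutoff}


# ---------------------------------------------------------------------------
# worked examples from published OR/CI tables
# ---------------------------------------------------------------------------

# per-study sex-stratified sample sizes (cases, controls) of the four glioma
# case-control studies used in the worked examples
MALE_COUNTS = {"gliomascan": (749, 687), "agog": (346, 962),
               "gicc": (2401, 1377), "ucsf_mayo": (1251, 1134)}
FEMALE_COUNTS = {"gliomascan": (567, 606), "agog": (214, 1275),
                 "gicc": (1599, 1034), "ucsf_mayo": (890, 755)}

# printed per-study two-sided p-values and effect directions
RS35042965_MALE_P = {"gliomascan": (0.3269, -1), "agog": (0.0285, -1),
                     "gicc": (0.0016, -1), "ucsf_mayo": (0.0030, -1)}
RS2346609_FEMALE_P = {"gliomascan": (0.0536, +1), "agog": (0.1677, +1),
                      "gicc": (0.0008, +1), "ucsf_mayo": (0.0019, +1)}

# printed OR (L95, U95) rows used to rebuild Wald statistics
RS35042965_AGOG_MALE_OR = (0.75, 0.58, 0.97)
RS35042965_MAYO_MALE_OR = (0.77, 0.65, 0.92)
RS2346609_MAYO_FEMALE_OR = (1.31, 1.11, 1.56)
RS2346609_MAYO_MALE_OR = (0.99, 0.86, 1.14)


def worked_single_study_examples() -> dict:
    """Wald and sex-difference p-values rebuilt from printed OR/CI rows."""
    out = {}
    for key, row in (("wald_p_agog_male_rs35042965", RS35042965_AGOG_MALE_OR),
                     ("wald_p_mayo_male_rs35042965", RS35042965_MAYO_MALE_OR)):
        beta, se = beta_from_or_ci(*row)
        out[key] = float(2.0 * stats.norm.sf(abs(beta) / se))
    bf, sef = beta_from_or_ci(*RS2346609_MAYO_FEMALE_OR)
    bm, sem = beta_from_or_ci(*RS2346609_MAYO_MALE_OR)
    d = sex_difference(
        SnpAssoc("rs2346609", bf, sef, *FEMALE_COUNTS["ucsf_mayo"], "female"),
        SnpAssoc("rs2346609", bm, sem, *MALE_COUNTS["ucsf_mayo"], "male"))
    out["sexdiff_p_mayo_rs2346609"] = d.p_diff
    return out


def worked_meta_examples() -> dict:
    """Weighted-Z meta p from printed per-study p-values and directions.

    Computed with both weighting conventions — effective case-control size
    4/(1/Ncase + 1/Nctrl) (the default) and total N — so the calibration
    against the published meta p-values can be compared directly.
    """
    out = {}
    for label, table, counts in (
            ("male_rs35042965", RS35042965_MALE_P, MALE_COUNTS),
            ("female_rs2346609", RS2346609_FEMALE_P, FEMALE_COUNTS)):
        eff = [(p, s, effective_n(*counts[k])) for k, (p, s) in table.items()]
        tot = [(p, s, float(sum(counts[k]))) for k, (p, s) in table.items()]
        out[f"meta_p_{label}"] = weighted_z_meta(eff).p_meta
        out[f"meta_p_{label}_total_n"] = weighted_z_meta(tot).p_meta
    return out


# ---------------------------------------------------------------------------
# GBJ calibration
# ---------------------------------------------------------------------------

def gbj_calibration(base_seed: int = 1, d: int = 50, rho: float = 0.3,
                    n_rep: int = 2000, n_mc: int = 20_000) -> dict:
    """Type-I error of the Monte Carlo GBJ test at alpha = 0.05.

    Draws n_rep null z-vectors from the exchangeable-correlation normal and
    computes each one's Monte Carlo p-value against a shared pool of n_mc
    null draws (shared pool: the statistic and the reference distribution use
    the same machinery, so this is exactly the test as deployed).
    """
    null_seed, rep_seed = _seeds(base_seed, 5, 2)
    sigma = np.full((d, d), rho)
    np.fill_diagonal(sigma, 1.0)
    ctx = _SigmaContext(sigma)

    def batch(seed, n):
        Z = null_z_sampler(sigma, n, seed=seed)
        return _gbj_stats(np.sort(np.abs(Z), axis=1)[:, ::-1], ctx,
                          exact_f=False)

    null_stats = np.sort(batch(null_seed, n_mc))
    rep_stats = batch(rep_seed, n_rep)
    exceed = null_stats.size - np.searchsorted(null_stats, rep_stats - 1e-12,
                                               side="left")
    pvals = (1.0 + exceed) / (null_stats.size + 1.0)
    return {"gbj_type1_error": float((pvals <= 0.05).mean()),
            "n_replicates": n_rep}


# ---------------------------------------------------------------------------
# screen (PLO) calibration
# ---------------------------------------------------------------------------

def screen_calibration(base_seed: int = 1, n_case: int = 500,
                       n_ctrl: int = 500, n_snp: int = 2600,
                       n_boot: int = 500) -> dict:
    """Permutation-null behavior of the window screen on a null study.

    For every window of one null study: the original PLO, the bootstrap
    95th percentile, whether that percentile sits below 2.0, and whether the
    original PLO exceeds it (nominally a 5% event under exchangeability).
    """
    pool_seed, study_seed, boot_seed = _seeds(base_seed, 6, 3)
    pool = build_haplotype_pool(n_hap=1500, n_snp=n_snp, block_len=25,
                                seed=pool_seed)
    study = simulate_study(pool, n_case, n_ctrl, seed=study_seed)
    windows = make_windows(study.variants)
    prior = TreePrior()
    y = study.y
    below2 = exceed = 0
    for i, w in enumerate(windows):
        g = study.dosage[:, w.snp_start:w.snp_stop]
        model = WindowModel(g, prior)
        plo = model.plo(y)
        p95, _ = bootstrap_null(y, g, prior, n_boot=n_boot,
                                seed=boot_seed + i)
        below2 += p95 < 2.0
        exceed += plo > p95
    n = len(windows)
    return {"boot_p95_below2_fraction": float(below2 / n),
            "plo_exceedance_rate": float(exceed / n),
            "n_windows": n, "n_boot": n_boot}


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

def _planted_effect(pool, start_bp: int = 8_000_000, length: int = 100_000,
                    n_causal: int = 3, or_per_allele: float = 1.3,
                    sex_restriction: str = "both"):
    region = Region("1", start_bp, start_bp + length, "planted")
    pos0 = pool.variants["pos"].to_numpy() - 1
    inside = np.flatnonzero((pos0 >= region.start) & (pos0 < region.end))
    picks = inside[np.linspace(2, inside.size - 3, n_causal).astype(int)]
    vids = pool.variants["vid"].to_numpy()[picks]
    return region, EffectSpec(region, tuple(vids), or_per_allele,
                              sex_restriction)


def end_to_end_recovery(base_seed: int = 1, n_rep: int = 20,
                        n_case: int = 2000, n_ctrl: int = 2000,
                        n_snp: int = 5000, or_per_allele: float = 1.3) -> dict:
    """Stage 1+2 recovery of one planted region across seeded replicates.

    Per replicate: a fresh haplotype pool, three studies of n_case/n_ctrl
    each sharing it, one planted 100-kb region with 3 causal SNPs. Reports
    the fraction of replicates in which the planted region survives both
    stages, the false-candidate rate from non-planted windows, and the
    single- vs multi-study window exceedance rates behind the concordance
    rule.
    """
    cfg = PipelineConfig(strata=("both",), n_boot=200, n_pcs=2,
                         gbj=GbjConfig(n_mc=2000, seed=_seeds(base_seed, 7, 1)[0]),
                         seed=_seeds(base_seed, 8, 1)[0])
    recovered = 0
    false_candidates = 0
    single_hits = np.zeros(3)
    single_total = 0
    multi_hits = 0
    multi_total = 0
    for rep in range(n_rep):
        pool_seed, *study_seeds = _seeds(base_seed, 100 + rep, 4)
        pool = build_haplotype_pool(n_hap=2000, n_snp=n_snp, block_len=25,
                                    seed=pool_seed)
        region, eff = _planted_effect(pool, or_per_allele=or_per_allele)
        studies = {
            f"study{k}": simulate_study(pool, n_case, n_ctrl, effects=[eff],
                                        seed=study_seeds[k],
                                        study_label=f"study{k}")
            for k in range(3)
        }
        # window-level exceedance bookkeeping (non-planted windows = null)
        from .screen import screen_study
        windows = make_windows(next(iter(studies.values())).variants,
                               cfg.window)
        null_mask = np.array([not w.region.overlaps(region) for w in windows])
        plo_mat = np.stack([
            screen_study(st, cfg.window, cfg.prior, windows=windows)["plo"]
            .to_numpy() for st in studies.values()])
        hits = plo_mat[:, null_mask] >= cfg.plo_min
        single_hits += hits.sum(axis=1)
        single_total += int(null_mask.sum())
        multi_hits += int((hits.sum(axis=0) >= cfg.min_studies).sum())
        multi_total += int(null_mask.sum())

        cands, _ = run_stage1(studies, cfg)
        retained = run_stage2(studies, cands, cfg)
        recovered += any(c.region.overlaps(region) for c in retained)
        false_candidates += sum(not c.region.overlaps(region)
                                for c in retained)
    single_rate = float(single_hits.max() / single_total)
    return {
        "planted_recovery_rate": float(recovered / n_rep),
        "false_candidates_per_replicate": float(false_candidates / n_rep),
        "null_window_single_study_rate": float(single_rate),
        "null_window_multi_study_rate": float(multi_hits / multi_total),
        "n_replicates": n_rep,
    }


def sex_difference_recovery(base_seed: int = 1, n_rep: int = 20,
                            n_case: int = 2000, n_ctrl: int = 2000,
                            or_per_allele: float = 1.3) -> dict:
    """Power of the sex-difference test at a planted male-only causal SNP."""
    pool_seed, *rep_seeds = _seeds(base_seed, 9, n_rep + 1)
    pool = build_haplotype_pool(n_hap=1500, n_snp=120, block_len=25,
                                seed=pool_seed)
    region, eff = _planted_effect(pool, start_bp=200_000, n_causal=1,
                                  or_per_allele=or_per_allele,
                                  sex_restriction="male_only")
    vid = eff.causal_ids[0]
    sig = 0
    for rep in range(n_rep):
        study = simulate_study(pool, n_case, n_ctrl, effects=[eff],
                               seed=rep_seeds[rep])
        male = study.subset_samples((study.samples["sex"] == "male").to_numpy())
        female = study.subset_samples((study.samples["sex"] == "female").to_numpy())
        a_m = snp_logistic(male, vid, stratum="male")
        a_f = snp_logistic(female, vid, stratum="female")
        sig += sex_difference(a_f, a_m).p_diff < 0.05
    return {"sexdiff_detection_rate": float(sig / n_rep), "n_replicates": n_rep}


# ---------------------------------------------------------------------------
# oracle equivalences
# ---------------------------------------------------------------------------

def oracle_equivalences(base_seed: int = 1) -> dict:
    """Deterministic agreement of core statistics with independent oracles.

    Returns maximum absolute deviations of: the marginal score Z against the
    Cochran-Armitage trend test; the no-split tree marginal against the
    Beta-Binomial closed form; windowed LD pruning against brute-force
    removal; and the equal-weight weighted-Z against the Stouffer closed
    form. The GBJ-vs-Berk-Jones independence check is included as well.
    """
    rng = np.random.default_rng(_seeds(base_seed, 10, 1)[0])

    # trend test
    from .io import StudyGenotypes, variant_frame
    import pandas as pd
    n, m = 500, 8
    dosage = rng.choice([0, 1, 2], size=(n, m), p=[0.4, 0.4, 0.2]).astype(np.int8)
    samples = pd.DataFrame({
        "sid": [f"s{i}" for i in range(n)],
        "phenotype": np.where(rng.random(n) < 0.5, "case", "control"),
        "sex": rng.choice(["male", "female"], n), "age": 50.0, "study": "b"})
    variants = variant_frame(["1"] * m, (np.arange(m) + 1) * 1000,
                             [f"v{j}" for j in range(m)], ["A"] * m, ["G"] * m)
    study = StudyGenotypes(samples, variants, dosage)
    from .regiontest import marginal_scores
    sc = marginal_scores(study, Region("1", 0, 10_000, "o"))
    y = study.y
    w = np.array([0.0, 1.0, 2.0])
    trend_gap = 0.0
    for j in range(m):
        tbl = np.array([[np.sum((y == yy) & (dosage[:, j] == gg))
                         for gg in (0, 1, 2)] for yy in (0, 1)], dtype=float)
        N, R = tbl.sum(), tbl[1].sum()
        ng = tbl.sum(axis=0)
        T = (w * tbl[1]).sum() - R / N * (w * ng).sum()
        var = R / N * (1 - R / N) * ((w**2 * ng).sum() - (w * ng).sum()**2 / N)
        trend_gap = max(trend_gap, abs(sc.z[j] - T / np.sqrt(var)))

    # no-split tree marginal vs Beta-Binomial closed form
    from .screen import window_log_marginal
    yv = np.array([1, 1, 1, 0, 0])
    bb_gap = abs(window_log_marginal(yv, np.zeros((5, 1), np.int8))
                 - np.log(1 / 60))

    # pruning vs brute force on 10-SNP instances
    from .regiontest import prune_indices
    prune_agree = True
    for _ in range(20):
        g = rng.choice([0, 1, 2], size=(200, 10)).astype(float)
        for j in range(1, 10):
            if rng.random() < 0.5:
                mix = rng.random(200) < 0.6
                g[mix, j] = g[mix, j - 1]
        maf = rng.uniform(0.05, 0.5, 10)
        pos = np.arange(10) * 100.0
        kept = prune_indices(g, maf, pos, 0.5, 50, 5)
        prune_agree &= np.array_equal(kept, _brute_prune(g, maf, pos, 0.5))

    # Stouffer identity
    from .meta import weighted_z_meta
    mk = weighted_z_meta([(0.04, 1, 777.0)] * 4)
    stouffer_gap = abs(mk.z_meta - 2 * stats.norm.isf(0.02))

    # GBJ = Berk-Jones under independence
    from .regiontest import MarginalScores, gbj_statistic
    bj_gap = 0.0
    for _ in range(50):
        d = int(rng.integers(1, 60))
        z = rng.standard_normal(d) * rng.uniform(0.5, 2.0)
        s = MarginalScores(Region("1", 0, 10, "o"), z, np.eye(d),
                           [f"v{i}" for i in range(d)], "individual")
        bj_gap = max(bj_gap, abs(gbj_statistic(s) - _bj_brute(z)))

    return {
        "trend_z_max_abs_diff": float(trend_gap),
        "beta_binomial_logml_abs_diff": float(bb_gap),
        "prune_matches_bruteforce": float(prune_agree),
        "stouffer_z_abs_diff": float(stouffer_gap),
        "gbj_vs_berkjones_max_abs_diff": float(bj_gap),
    }


def _brute_prune(g, maf, pos, r2max):
    gq = g - g.mean(0)
    sd = gq.std(0)
    sd[sd == 0] = 1
    r2 = ((gq / sd).T @ (gq / sd) / g.shape[0]) ** 2
    alive = np.ones(g.shape[1], bool)
    while True:
        cur = np.flatnonzero(alive)
        if len(cur) < 2:
            break
        sub = r2[np.ix_(cur, cur)].copy()
        np.fill_diagonal(sub, 0)
        hi = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[hi] <= r2max:
            break
        i, j = sorted((cur[hi[0]], cur[hi[1]]))
        if maf[i] < maf[j]:
            drop = i
        elif maf[j] < maf[i]:
            drop = j
        else:
            drop = i if pos[i] > pos[j] else j
        alive[drop] = False
    return np.flatnonzero(alive)


def _bj_brute(z):
    d = len(z)
    a = np.sort(np.abs(z))[::-1]
    best = 0.0
    for k in range(1, d + 1):
        t = a[k - 1]
        if t <= 1:
            continue
        p = 2 * stats.norm.sf(t)
        x = k / d
        if x <= p:
            continue
        ll = k * np.log(x / p)
        if k < d:
            ll += (d - k) * np.log((1 - x) / (1 - p))
        best = max(best, ll)
    return best
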