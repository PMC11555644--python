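"""Four-stage region-discovery pipeline.

Stage 1 screens every study with the sliding-window tree screen and keeps
windows with PLO >= 2 in at least two studies of the same stratum, then
gates them by the bootstrap null 95th percentile; contiguous qualifying
windows merge into candidate regions, and regions overlapping a user-
supplied list of known susceptibility regions are routed to a separate
ledger. Stage 2 re-tests candidates with the covariate-adjusted GBJ in the
qualifying studies (same-stratum rule, with other-stratum hits recorded but
flagged). Stage 3 validates against a summary-statistics study using
reference LD. Stage 4 runs per-SNP logistic association in every study,
sample-size-weighted Z meta-analysis including the summary-only study,
sex-difference tests for sex-specific candidates, and Bonferroni ledgers.

Every inclusion/exclusion appends a machine-parseable line to the
candidate's decision trail, so a report can be replayed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Region, StudyGenotypes
from ._glm import SeparationError, design_matrix
from .meta import (bonferroni_threshold, effective_n, meta_region_test,
                   sex_difference, snp_logistic, weighted_z_meta)
from .popstruct import compute_pcs
from .regiontest import GbjConfig, test_region_individual, test_region_summary
from .screen import (TreePrior, WindowSpec, add_bootstrap, concordance_select,
                     make_windows, screen_study)

__all__ = ["PipelineConfig", "CandidateRegion", "run_stage1", "run_stage2",
           "run_stage3", "run_stage4", "known_region_scan"]

SEX_STRATA = ("both", "male", "female")
X_CHROMS = {"X", "23", "chrX"}


@dataclass(frozen=True)
class PipelineConfig:
    strata: tuple[str, ...] = SEX_STRATA
    plo_min: float = 2.0
    min_studies: int = 2
    n_boot: int = 1000
    gbj_alpha: float = 0.05
    fw_alpha: float = 0.05
    covariates: tuple[str, ...] = ("sex", "age")
    n_pcs: int = 7
    window: WindowSpec = WindowSpec()
    prior: TreePrior = TreePrior()
    gbj: GbjConfig = GbjConfig()
    seed: int = 0
    exclude_x_combined_sex: bool = True
    pca_max_snps: int = 2000  # evenly thinned SNP subset for covariate PCs

    def __post_init__(self):
        for s in self.strata:
            if s not in SEX_STRATA:
                raise ValueError(f"unknown stratum {s!r}")
        if not (0 < self.gbj_alpha <= 1 and 0 < self.fw_alpha <= 1):
            raise ValueError("alphas must be in (0, 1]")


@dataclass
class CandidateRegion:
    region: Region
    stratum: str
    studies: tuple[str, ...] = ()            # qualifying studies at stage 1
    plo: dict = field(default_factory=dict)  # study -> PLO (max over windows)
    gbj_p: dict = field(default_factory=dict)        # study -> stage-2 p
    other_stratum: str | None = None          # stage-2 rescue stratum, if any
    validation_p: float | None = None
    validation_other_sex_p: dict = field(default_factory=dict)
    meta_region_p: float | None = None
    lowest_snp: dict = field(default_factory=dict)
    trail: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.trail.append(msg)


def _stratum_subset(study: StudyGenotypes, stratum: str) -> StudyGenotypes:
    if stratum == "both":
        return study
    return study.subset_samples((study.samples["sex"] == stratum).to_numpy())


def _drop_x(study: StudyGenotypes) -> StudyGenotypes:
    keep = ~study.variants["chrom"].isin(X_CHROMS).to_numpy()
    return study if keep.all() else study.subset_variants(keep)


def _design(study: StudyGenotypes, stratum: str, config: PipelineConfig,
            seed: int = 0) -> np.ndarray:
    covs = tuple(c for c in config.covariates
                 if not (c == "sex" and stratum != "both"))
    pcs = None
    if config.n_pcs > 0:
        pca_study = study
        if config.pca_max_snps and study.n_variants > config.pca_max_snps:
            stride = int(np.ceil(study.n_variants / config.pca_max_snps))
            pca_study = study.subset_variants(np.arange(0, study.n_variants,
                                                        stride))
        pcs = compute_pcs(pca_study, k=config.n_pcs, seed=seed).scores
    return design_matrix(study.samples, covs, pcs)


class _DesignCache:
    """Per (study, stratum) cache of subsets and covariate designs."""

    def __init__(self, studies: dict[str, StudyGenotypes],
                 config: PipelineConfig):
        self.studies = studies
        self.config = config
        self._memo: dict[tuple[str, str], tuple[StudyGenotypes, np.ndarray]] = {}

    def get(self, name: str, stratum: str) -> tuple[StudyGenotypes, np.ndarray]:
        key = (name, stratum)
        if key not in self._memo:
            sub = _stratum_subset(self.studies[name], stratum)
            X = _design(sub, stratum, self.config, seed=self.config.seed)
            self._memo[key] = (sub, X)
        return self._memo[key]


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def run_stage1(studies: dict[str, StudyGenotypes], config: PipelineConfig,
               known_regions: list[Region] | None = None,
               ) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Window screen + concordance selection; returns (candidates, known_hits)."""
    if len(studies) < 2:
        raise ValueError("stage 1 needs >= 2 studies")
    known_regions = known_regions or []
    candidates: list[CandidateRegion] = []
    known_hits: list[CandidateRegion] = []
    for stratum in config.strata:
        tables: dict[str, pd.DataFrame] = {}
        subsets: dict[str, StudyGenotypes] = {}
        windows_by_study = {}
        for name, study in studies.items():
            sub = _stratum_subset(study, stratum)
            if stratum == "both" and config.exclude_x_combined_sex:
                sub = _drop_x(sub)
            subsets[name] = sub
            windows = make_windows(sub.variants, config.window)
            windows_by_study[name] = windows
            tables[name] = screen_study(sub, config.window, config.prior,
                                        windows=windows)
        # bootstrap only windows that clear the multi-study PLO rule
        plo = np.stack([t["plo"].to_numpy() for t in tables.values()])
        step_a = (plo >= config.plo_min).sum(axis=0) >= config.min_studies
        for s, name in enumerate(tables):
            need = step_a & (plo[s] >= config.plo_min)
            tables[name] = add_bootstrap(
                tables[name], subsets[name], windows_by_study[name], need,
                config.prior, n_boot=config.n_boot, seed=config.seed)
        regions = concordance_select(tables, config.plo_min,
                                     config.min_studies)
        for region in regions:
            qual, plos = [], {}
            for s, name in enumerate(tables):
                t = tables[name]
                inwin = ((t["chrom"].astype(str) == region.chrom)
                         & (t["start"] < region.end) & (t["end"] > region.start))
                plos[name] = float(t.loc[inwin, "plo"].max())
                if (t.loc[inwin, "plo"] >= config.plo_min).any():
                    qual.append(name)
            cand = CandidateRegion(region=region, stratum=stratum,
                                   studies=tuple(qual), plo=plos)
            cand.log(f"stage1:selected stratum={stratum} studies={','.join(qual)}")
            hit_known = [k for k in known_regions if k.overlaps(region)]
            if hit_known:
                cand.log("stage1:known_region " +
                         ",".join(k.label for k in hit_known))
                known_hits.append(cand)
            else:
                candidates.append(cand)
    return candidates, known_hits


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def run_stage2(studies: dict[str, StudyGenotypes],
               candidates: list[CandidateRegion], config: PipelineConfig,
               ) -> list[CandidateRegion]:
    """Covariate-adjusted GBJ in the qualifying studies; same-stratum rule.

    A candidate is retained when its GBJ p < alpha in at least min_studies of
    its stage-1 qualifying studies for the same stratum. When that fails but
    the rule passes in a different stratum for the same studies, the
    candidate is retained with the other stratum recorded and flagged.
    """
    retained: list[CandidateRegion] = []
    cache = _DesignCache(studies, config)
    for cand in candidates:
        p_by_stratum: dict[str, dict[str, float]] = {}
        for stratum in config.strata:
            ps = {}
            for name in cand.studies:
                try:
                    sub, X = cache.get(name, stratum)
                    res = test_region_individual(sub, cand.region, X=X,
                                                 config=config.gbj)
                    ps[name] = res.p
                except (SeparationError, ValueError) as exc:
                    cand.log(f"stage2:error study={name} stratum={stratum}: {exc}")
            p_by_stratum[stratum] = ps

        def n_hits(stratum):
            return sum(p < config.gbj_alpha
                       for p in p_by_stratum[stratum].values())

        cand.gbj_p = p_by_stratum[cand.stratum]
        if n_hits(cand.stratum) >= config.min_studies:
            cand.log(f"stage2:retained stratum={cand.stratum} "
                     f"p={ {k: round(v, 4) for k, v in cand.gbj_p.items()} }")
            retained.append(cand)
            continue
        rescue = [s for s in config.strata
                  if s != cand.stratum and n_hits(s) >= config.min_studies]
        if rescue:
            cand.other_stratum = rescue[0]
            cand.gbj_p = p_by_stratum[rescue[0]]
            cand.log(f"stage2:retained_other_stratum {rescue[0]}")
            retained.append(cand)
        else:
            cand.log("stage2:dropped gbj_rule_failed")
    return retained


# ---------------------------------------------------------------------------
# stage 3
# ---------------------------------------------------------------------------

def run_stage3(candidates: list[CandidateRegion],
               validation: dict[str, pd.DataFrame],
               ld_reference: StudyGenotypes, config: PipelineConfig,
               ) -> list[CandidateRegion]:
    """Validation GBJ from summary statistics per candidate stratum.

    validation maps stratum -> summary-statistics table. The candidate's own
    stratum gives validation_p; the other sex strata are also tested and
    recorded (a region may validate for a different sex).
    """
    for cand in candidates:
        stratum = cand.other_stratum or cand.stratum
        for s, table in validation.items():
            try:
                res = test_region_summary(table, cand.region, ld_reference,
                                          config=config.gbj)
            except ValueError as exc:
                cand.log(f"stage3:coverage_warning stratum={s}: {exc}")
                continue
            if s == stratum:
                cand.validation_p = res.p
                cand.log(f"stage3:validation stratum={s} p={res.p:.4g} "
                         f"n_snps={res.n_snps_tested}")
            else:
                cand.validation_other_sex_p[s] = res.p
                cand.log(f"stage3:other_sex stratum={s} p={res.p:.4g}")
    return candidates


# ---------------------------------------------------------------------------
# stage 4
# ---------------------------------------------------------------------------

def _study_snp_assoc(cache: _DesignCache, name: str, stratum: str, vid, config):
    sub, X = cache.get(name, stratum)
    return snp_logistic(sub, vid, X=X, stratum=stratum)


def run_stage4(studies: dict[str, StudyGenotypes],
               validation: dict[str, pd.DataFrame],
               candidates: list[CandidateRegion], config: PipelineConfig,
               ) -> dict:
    """SNP meta-analysis, sex-difference tests and Bonferroni ledgers."""
    if len(studies) + (1 if validation else 0) < 2:
        raise ValueError("stage 4 meta-analysis needs >= 2 data sources")
    cache = _DesignCache(studies, config)
    all_meta_rows = []
    for cand in candidates:
        stratum = cand.other_stratum or cand.stratum
        vtab = validation.get(stratum)
        first = next(iter(studies.values()))
        idx = first.region_index(cand.region)
        vids = first.variants["vid"].to_numpy()[idx]
        best = None
        for vid in vids:
            entries = []
            for name in studies:
                try:
                    a = _study_snp_assoc(cache, name, stratum, vid, config)
                except (SeparationError, ValueError, KeyError):
                    continue
                entries.append((a.p, np.sign(a.beta) or 1.0,
                                effective_n(a.n_case, a.n_ctrl)))
            if vtab is not None:
                row = vtab[vtab["vid"] == vid]
                if len(row):
                    r = row.iloc[0]
                    entries.append((float(r["p"]), np.sign(r["beta"]) or 1.0,
                                    effective_n(int(r["n_case"]),
                                                int(r["n_ctrl"]))))
            if len(entries) < 2:
                continue
            m = weighted_z_meta(entries, vid=vid)
            all_meta_rows.append((cand.region.label, stratum, vid,
                                  m.z_meta, m.p_meta, m.directions))
            if best is None or m.p_meta < best[1].p_meta:
                best = (vid, m)
        if best is None:
            cand.log("stage4:no_meta_possible")
            continue
        vid, m = best
        cand.lowest_snp = {"vid": vid, "z_meta": m.z_meta, "p_meta": m.p_meta,
                           "directions": m.directions}
        cand.log(f"stage4:lowest_snp {vid} p_meta={m.p_meta:.3g}")

        if stratum in ("male", "female"):
            diffs = {}
            for name in studies:
                try:
                    f = _study_snp_assoc(cache, name, "female", vid, config)
                    mle = _study_snp_assoc(cache, name, "male", vid, config)
                    diffs[name] = sex_difference(f, mle)
                except (SeparationError, ValueError, KeyError) as exc:
                    cand.log(f"stage4:sexdiff_error study={name}: {exc}")
            cand.lowest_snp["sex_difference"] = {
                name: {"beta_diff": d.beta_diff, "se_diff": d.se_diff,
                       "p_diff": d.p_diff} for name, d in diffs.items()}

    meta_table = pd.DataFrame(all_meta_rows, columns=[
        "region", "stratum", "vid", "z_meta", "p_meta", "directions"])
    n_regions = max(len(candidates), 1)
    n_snps = max(len(meta_table), 1)
    ledger = {
        "n_regions": len(candidates),
        "n_meta_snps": len(meta_table),
        "region_threshold": bonferroni_threshold(config.fw_alpha, n_regions),
        "snp_threshold": bonferroni_threshold(config.fw_alpha, n_snps),
    }
    return {"candidates": candidates, "meta_table": meta_table,
            "ledger": ledger}


# ---------------------------------------------------------------------------
# known-region scan
# ---------------------------------------------------------------------------

def known_region_scan(studies: dict[str, StudyGenotypes],
                      regions: list[Region], config: PipelineConfig,
                      ) -> pd.DataFrame:
    """PLO and GBJ p for every known region x study x stratum."""
    from .screen import WindowModel

    cache = _DesignCache(studies, config)
    rows = []
    for region in regions:
        for name in studies:
            for stratum in config.strata:
                sub, X = cache.get(name, stratum)
                idx = sub.region_index(region)
                if idx.size == 0:
                    rows.append((region.label, name, stratum, np.nan,
                                 np.nan, 0))
                    continue
                model = WindowModel(sub.dosage[:, idx], config.prior)
                plo = model.plo(sub.y)
                try:
                    res = test_region_individual(sub, region, X=X,
                                                 config=config.gbj)
                    gbj_p = res.p
                except (SeparationError, ValueError):
                    gbj_p = np.nan
                rows.append((region.label, name, stratum, plo, gbj_p,
                             int(idx.size)))
    return pd.DataFrame(rows, columns=["region", "study", "stratum", "plo",
                                       "gbj_p", "n_snps"])


# ---------------------------------------------------------------------------
# aggregated-data diagnostic
# ---------------------------------------------------------------------------

def aggregate_studies(studies: dict[str, StudyGenotypes]) -> StudyGenotypes:
    """Concatenate studies over their shared variants (diagnostic use only).

    The aggregated study is meant for the attenuation diagnostic — running
    the region test with a study indicator in the covariates to see whether
    a region's evidence survives pooling — never for discovery, since the
    member studies differ in collection and genotyping.
    """
    names = list(studies)
    shared = studies[names[0]].variants["vid"]
    for name in names[1:]:
        shared = shared[shared.isin(studies[name].variants["vid"])]
    shared = shared.tolist()
    parts, metas = [], []
    for name in names:
        st = studies[name]
        idx = st.variants.set_index("vid").index.get_indexer(shared)
        parts.append(st.dosage[:, idx])
        s = st.samples.copy()
        s["study"] = name
        s["sid"] = name + ":" + s["sid"].astype(str)
        metas.append(s)
    first = studies[names[0]]
    variants = first.variants.set_index("vid").loc[shared].reset_index()
    variants = variants[["chrom", "pos", "vid", "a1", "a2"]]
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort")
    order = variants.index.to_numpy()
    variants = variants.reset_index(drop=True)
    return StudyGenotypes(pd.concat(metas, ignore_index=True),
                          variants, np.vstack(parts)[:, order])


def aggregated_region_test(studies: dict[str, StudyGenotypes], region: Region,
                           config: PipelineConfig):
    """GBJ on pooled studies, adjusting for study membership.

    Covariates: the configured set plus one indicator per non-reference
    study. Used to diagnose attenuation of a region's evidence under
    pooling; compare its p against the per-study stage-2 results.
    """
    pooled = aggregate_studies(studies)
    X = _design(pooled, "both", config, seed=config.seed)
    names = sorted(studies)
    dummies = np.column_stack([
        (pooled.samples["study"] == name).to_numpy(float)
        for name in names[1:]]) if len(names) > 1 else None
    if dummies is not None:
        X = np.column_stack([X, dummies])
    return test_region_individual(pooled, region, X=X, config=config.gbj)
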