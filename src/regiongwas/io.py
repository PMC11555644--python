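"""Genotype, region and summary-statistic file formats and the shared data model.

Genotypes travel as :class:`StudyGenotypes`: a samples x variants dosage matrix
counting copies of the effect allele (bim A1), with ``-1`` marking a missing
call. Binary genotypes use the PLINK 1 bed/bim/fam triple (SNP-major, two-bit
encoding); regions use BED (0-based half-open); per-SNP summary statistics use
a fixed-column TSV.

Conventions
-----------
* Genomic intervals are 0-based half-open internally (BED convention).
* The effect allele is always bim A1. No strand flipping is attempted;
  strand-ambiguous variants (A/T, C/G) are flagged, not removed.
* Missing dosage is a distinct symbol (-1), never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype call

PLINK_BED_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01

#: columns every summary-statistics table must carry
SUMMARY_COLUMNS = [
    "chrom", "pos", "vid", "a1", "a2", "beta", "se", "p", "n_case", "n_ctrl",
]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """Malformed file contents (bad magic bytes, bad schema...)."""


class IntegrityError(ValueError):
    """Structurally valid file whose pieces disagree (dimension mismatch...)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"region start must be < end, got [{self.start}, {self.end})")
        if not self.label:
            object.__setattr__(self, "label", f"{self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def variant_frame(chrom, pos, vid, a1, a2) -> pd.DataFrame:
    """Assemble and validate a variant metadata table."""
    df = pd.DataFrame({
        "chrom": np.asarray(chrom, dtype=str),
        "pos": np.asarray(pos, dtype=np.int64),
        "vid": np.asarray(vid, dtype=str),
        "a1": np.asarray(a1, dtype=str),
        "a2": np.asarray(a2, dtype=str),
    })
    _validate_variants(df)
    return df


def _validate_variants(df: pd.DataFrame) -> None:
    if (df["pos"] < 1).any():
        raise ValueError("variant positions must be >= 1 (1-based)")
    if (df["a1"] == df["a2"]).any():
        bad = df.loc[df["a1"] == df["a2"], "vid"].iloc[0]
        raise ValueError(f"effect and other allele identical for {bad}")
    if df["vid"].duplicated().any():
        dup = df.loc[df["vid"].duplicated(), "vid"].iloc[0]
        raise ValueError(f"duplicate variant id {dup}")


def flag_ambiguous(variants: pd.DataFrame) -> np.ndarray:
    """True for strand-ambiguous (A/T, C/G) variants.

    These cannot be strand-resolved from alleles alone and are a documented
    source of cross-study effect attenuation; they are reported, not removed.
    """
    pairs = list(zip(variants["a1"].str.upper(), variants["a2"].str.upper()))
    return np.array([p in _AMBIGUOUS_PAIRS for p in pairs], dtype=bool)


@dataclass
class StudyGenotypes:
    """Hard-called genotypes for one case-control study.

    Attributes
    ----------
    samples : DataFrame with columns sid, phenotype ('case'/'control'),
        sex ('male'/'female'), age (years, NaN allowed), study.
    variants : DataFrame with columns chrom, pos, vid, a1, a2,
        sorted by (chrom, pos).
    dosage : int8 array, samples x variants, values in {0, 1, 2, -1};
        counts of the a1 (effect) allele, -1 = missing.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise IntegrityError(
                f"dosage is {self.dosage.shape} but study has "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        _validate_variants(self.variants)
        v = self.variants
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(v))):
            raise ValueError("variants must be sorted by (chrom, pos)")
        if self.samples["sid"].duplicated().any():
            raise ValueError("duplicate sample ids")
        ok_phe = self.samples["phenotype"].isin(["case", "control"])
        if not ok_phe.all():
            raise ValueError("phenotype must be 'case' or 'control'")
        ok_sex = self.samples["sex"].isin(["male", "female"])
        if not ok_sex.all():
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def y(self) -> np.ndarray:
        """Phenotype as 0/1 (1 = case)."""
        return (self.samples["phenotype"] == "case").to_numpy().astype(np.int8)

    def subset_samples(self, mask) -> "StudyGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return StudyGenotypes(self.samples.iloc[idx], self.variants, self.dosage[idx])

    def subset_variants(self, mask) -> "StudyGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return StudyGenotypes(self.samples, self.variants.iloc[idx], self.dosage[:, idx])

    def region_index(self, region: Region) -> np.ndarray:
        """Indices of variants falling in a 0-based half-open region."""
        v = self.variants
        pos0 = v["pos"].to_numpy() - 1  # 1-based -> 0-based
        return np.flatnonzero(
            (v["chrom"].to_numpy() == region.chrom)
            & (pos0 >= region.start) & (pos0 < region.end))

    def allele_freq(self) -> np.ndarray:
        """Per-variant a1 frequency over non-missing calls."""
        d = self.dosage
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(0) / (2.0 * obs.sum(0))

    def call_rate_variants(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=1)

    def __eq__(self, other) -> bool:
        return (isinstance(other, StudyGenotypes)
                and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
                and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
                and np.array_equal(self.dosage, other.dosage))


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------
# Two-bit code per genotype, SNP-major (one SNP's samples packed 4 per byte,
# low bits first):  00 = hom A1 (dosage 2), 01 = missing, 10 = het (1),
# 11 = hom A2 (0).

_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_SEX_TO_FAM = {"male": 1, "female": 2}
_FAM_TO_SEX = {1: "male", 2: "female"}
_PHE_TO_FAM = {"control": 1, "case": 2}
_FAM_TO_PHE = {1: "control", 2: "case"}


def read_genotypes(prefix: str | Path) -> StudyGenotypes:
    """Read a PLINK bed/bim/fam triple.

    Dosage counts copies of the bim A1 allele; missing calls stay missing.
    Ages are not stored in fam and come back as NaN; the study label is the
    file stem.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "sid", "pid", "mid", "sex", "phenotype"],
                      dtype={"fid": str, "sid": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "vid", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "vid": str, "a1": str, "a2": str})
    if not fam["sex"].isin(_FAM_TO_SEX).all():
        raise FormatError("fam sex codes must be 1 (male) or 2 (female)")
    if not fam["phenotype"].isin(_FAM_TO_PHE).all():
        raise FormatError("fam phenotype codes must be 1 (control) or 2 (case)")
    samples = pd.DataFrame({
        "sid": fam["sid"],
        "phenotype": fam["phenotype"].map(_FAM_TO_PHE),
        "sex": fam["sex"].map(_FAM_TO_SEX),
        "age": np.nan,
        "study": prefix.name,
    })
    variants = pd.DataFrame({
        "chrom": bim["chrom"], "pos": bim["pos"].astype(np.int64),
        "vid": bim["vid"], "a1": bim["a1"], "a2": bim["a2"],
    })

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != PLINK_BED_MAGIC:
        raise FormatError(f"bad bed magic bytes {raw[:2]!r}")
    if raw[2] != SNP_MAJOR:
        raise FormatError("only SNP-major bed files are supported")
    n, m = len(samples), len(variants)
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise IntegrityError(
            f"bed payload has {payload.size} bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs")
    if m == 0:
        dosage = np.zeros((n, 0), dtype=np.int8)
    else:
        codes = payload.reshape(m, bytes_per_snp)
        # unpack 4 two-bit fields per byte, low bits = first sample
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
        dosage = _DECODE[two_bit.reshape(m, -1)[:, :n]].T.copy()
    return StudyGenotypes(samples, variants, dosage)


def write_genotypes(study: StudyGenotypes, prefix: str | Path) -> None:
    """Write a PLINK bed/bim/fam triple (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    s = study.samples
    fam = pd.DataFrame({
        "fid": s["sid"], "sid": s["sid"], "pid": 0, "mid": 0,
        "sex": s["sex"].map(_SEX_TO_FAM),
        "phenotype": s["phenotype"].map(_PHE_TO_FAM),
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    v = study.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "vid": v["vid"], "cm": 0, "pos": v["pos"],
        "a1": v["a1"], "a2": v["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = study.dosage.shape
    code_lut = np.empty(4, dtype=np.uint8)
    for dose, code in _ENCODE.items():
        code_lut[dose % 4] = code  # -1 % 4 == 3
    if m == 0:
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(PLINK_BED_MAGIC + bytes([SNP_MAJOR]))
        return
    codes = code_lut[study.dosage.T % 4]  # m x n two-bit values
    pad = (-n) % 4
    if pad:
        # pad with 00 (hom A1); padding bits are ignored on read
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_BED_MAGIC + bytes([SNP_MAJOR]))
        fh.write(packed.tobytes())


def write_sample_table(study: StudyGenotypes, path: str | Path) -> None:
    """Write the sample table (sid, phenotype, sex, age, study) as TSV."""
    study.samples.to_csv(path, sep="\t", index=False)


def attach_sample_table(study: StudyGenotypes, path: str | Path) -> StudyGenotypes:
    """Replace fam-derived sample metadata with a full sample TSV (adds age)."""
    tab = pd.read_csv(path, sep="\t", dtype={"sid": str})
    tab = tab.set_index("sid").loc[study.samples["sid"]].reset_index()
    return StudyGenotypes(tab, study.variants, study.dosage)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP summary-statistics TSV.

    Required columns: chrom, pos, vid, a1, a2, beta, se, p, n_case, n_ctrl.
    Rows violating the invariants (se <= 0, p outside (0, 1], pos < 1,
    a1 == a2) are skipped; the number skipped is logged and attached as
    ``df.attrs['n_skipped']``. Rows come back sorted by (chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "vid": str,
                                            "a1": str, "a2": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    ok = (
        (df["se"] > 0)
        & (df["p"] > 0) & (df["p"] <= 1)
        & (df["pos"] >= 1)
        & (df["a1"] != df["a2"])
        & df["beta"].notna()
    )
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("read_summary_stats: skipped %d malformed rows", n_skipped)
    df = df[ok].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def summary_p_from_beta(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided Wald p from beta and its standard error."""
    z = np.asarray(beta, float) / np.asarray(se, float)
    return 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# regions (BED)
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> list[Region]:
    """Read a 3+ column BED file into Regions (0-based half-open, no merging).

    Column 4 supplies the label when present, else "chrom:start-end".
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) >= 4 else ""
            regions.append(Region(chrom, start, end, label))
    return regions


def write_regions(regions: list[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
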