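"""Genotype/phenotype I/O and quality control.

Genotypes are held as an additive dosage matrix (samples x variants, values
in {0, 1, 2} with NaN for missing) counting copies of a declared effect
allele, together with variant and sample metadata tables. Readers and
writers cover PLINK binary (BED/BIM/FAM, SNP-major) and a simple TSV dosage
dialect; phenotype/covariate tables are plain TSV.

QC applies the usual variant filters (call rate, minor allele frequency,
Hardy-Weinberg equilibrium exact test) and sample filters (call rate,
covariate completeness), with a report that accounts for every removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "FormatError",
    "AlignmentError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "validate_phenotypes",
    "hwe_exact_test",
    "snp_qc_filter",
    "sample_qc_filter",
    "intersect_variants",
]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "status",
    "trait",
    "age",
    "sex",
    "height",
    "pack_years",
    "family_history",
    "ethnicity",
]

#: covariates whose completeness is required at sample QC
REQUIRED_COVARIATES = ["age", "sex", "pack_years", "family_history"]

STRAND_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class FormatError(ValueError):
    """A genotype file violates its declared format."""


class AlignmentError(ValueError):
    """Sample or variant identifiers do not line up between inputs."""


@dataclass
class GenotypeMatrix:
    """Additive dosages with variant/sample metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_variants)`` float array with entries in {0, 1, 2}
        counting the effect allele; NaN marks a missing call.
    variants
        DataFrame with columns ``id, chrom, pos, allele_effect, allele_other``.
    samples
        DataFrame with columns ``id, reported_sex``.
    """

    values: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variants)")
        if self.values.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def allele_frequency(self) -> np.ndarray:
        """Effect-allele frequency per variant, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=1)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index, :],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing calls replaced by the variant mean.

        Modeling stages require a complete matrix; per-variant mean
        imputation is the neutral fill after QC has bounded missingness.
        """
        out = self.values.copy()
        miss = np.isnan(out)
        if miss.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(out, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out


@dataclass
class QCThresholds:
    """Variant/sample QC thresholds; removal uses strict inequalities,
    so a variant exactly at a boundary is retained."""

    max_snp_missing: float = 0.05
    min_maf: float = 0.05
    min_hwe_p: float = 1e-5
    max_sample_missing: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_snp_missing", "min_maf", "min_hwe_p", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Per-axis bookkeeping: in - removed == out, removals attributed to the
    first failing criterion in the declared precedence order."""

    axis: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_in - sum(self.removed.values()) != self.n_out:
            raise ValueError("QC report does not balance")

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis": self.axis,
                "n_in": self.n_in,
                "n_out": self.n_out,
                "removed": self.removed,
                "retained_ids": list(self.retained_ids),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# PLINK binary + TSV dosage I/O

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: dosage of allele A1 (our effect allele)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11


def write_genotypes(g: GenotypeMatrix, prefix: str | Path, dialect: str = "plink_bed") -> None:
    prefix = Path(prefix)
    if dialect == "plink_bed":
        _write_bed(g, prefix)
    elif dialect == "tsv_dosage":
        _write_tsv_dosage(g, prefix.with_suffix(".dosage.tsv"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_genotypes(prefix: str | Path, dialect: str = "plink_bed") -> GenotypeMatrix:
    prefix = Path(prefix)
    if dialect == "plink_bed":
        return _read_bed(prefix)
    if dialect == "tsv_dosage":
        return _read_tsv_dosage(prefix.with_suffix(".dosage.tsv"))
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["allele_effect"],
            "a2": g.variants["allele_other"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    sex_code = g.samples["reported_sex"].map({"male": 1, "female": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": g.samples["id"],
            "iid": g.samples["id"],
            "pat": 0,
            "mat": 0,
            "sex": sex_code,
            "phe": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = g.n_samples
    vals = g.values
    # map dosage of A1 -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    code = np.full(vals.shape, 3, dtype=np.uint8)
    code[vals == 2.0] = 0
    code[np.isnan(vals)] = 1
    code[vals == 1.0] = 2
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((g.n_variants, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = code.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"],
        dtype={"iid": str},
    )
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad BED magic bytes (not a SNP-major PLINK file)")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise FormatError(
            f"{bed_path}: expected {m * n_bytes} data bytes for {n} samples x {m} variants, got {body.size}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0x03
    codes[:, 1::4] = (body >> 2) & 0x03
    codes[:, 2::4] = (body >> 4) & 0x03
    codes[:, 3::4] = (body >> 6) & 0x03
    values = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele_effect": bim["a1"],
            "allele_other": bim["a2"],
        }
    )
    sex = fam["sex"].map({1: "male", 2: "female"}).fillna("unknown")
    samples = pd.DataFrame({"id": fam["iid"], "reported_sex": sex})
    return GenotypeMatrix(values, variants, samples)


def _write_tsv_dosage(g: GenotypeMatrix, path: Path) -> None:
    meta = g.variants[["id", "chrom", "pos", "allele_effect", "allele_other"]]
    dosages = pd.DataFrame(g.values.T, columns=g.samples["id"])
    out = pd.concat([meta.reset_index(drop=True), dosages], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def _read_tsv_dosage(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    meta_cols = ["id", "chrom", "pos", "allele_effect", "allele_other"]
    if df.columns[: len(meta_cols)].tolist() != meta_cols:
        raise FormatError(f"{path}: header must start with {meta_cols}")
    sample_ids = df.columns[len(meta_cols):].tolist()
    block = df[sample_ids]
    values = block.to_numpy(dtype=np.float64, na_value=np.nan).T
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-{{0,1,2,NA}} dosage at variant row {j + 2}, sample column {sample_ids[i]!r}"
        )
    variants = df[meta_cols].copy()
    samples = pd.DataFrame({"id": sample_ids, "reported_sex": "unknown"})
    return GenotypeMatrix(values, variants, samples)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ethnicity": str})
    validate_phenotypes(phen)
    return phen


def write_phenotypes(phen: pd.DataFrame, path: str | Path) -> None:
    phen.to_csv(path, sep="\t", index=False, na_rep="NA")


def validate_phenotypes(phen: pd.DataFrame) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phen.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    status = phen["status"].dropna()
    if not status.isin([0, 1]).all():
        raise ValueError("status must be binary 0/1")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count. Probabilities are computed in log space from the exact
    hypergeometric-type distribution of heterozygote counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice irrelevant
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    het_obs = n_Aa
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log P(het) ∝ n_het*log2 + log n! - log[((n_a-het)/2)! het! ((2n-n_a-het)/2)!]
    from scipy.special import gammaln

    rare_hom = (n_a - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == het_obs][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = g.values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        out[j] = hwe_exact_test(n_AA, n_het, n_aa)
    return out


# ---------------------------------------------------------------------------
# Filters


def snp_qc_filter(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing call-rate, MAF, or HWE criteria.

    Removal requires strictly exceeding (missingness) or strictly falling
    below (MAF, HWE p) the threshold; boundary values survive. Each removal
    is attributed to the first failing criterion in the order
    missingness -> MAF -> HWE.
    """
    t = thresholds or QCThresholds()
    if g.n_variants == 0:
        report = QCReport("variant", 0, 0, {"missingness": 0, "maf": 0, "hwe": 0}, [])
        return g, report
    miss = g.variant_missingness()
    maf = g.maf()
    fail_miss = miss > t.max_snp_missing
    fail_maf = maf < t.min_maf
    hwe_p = _hwe_pvalues(g)
    fail_hwe = hwe_p < t.min_hwe_p
    keep = ~(fail_miss | fail_maf | fail_hwe)
    attributed_maf = fail_maf & ~fail_miss
    attributed_hwe = fail_hwe & ~fail_miss & ~fail_maf
    report = QCReport(
        axis="variant",
        n_in=g.n_variants,
        n_out=int(keep.sum()),
        removed={
            "missingness": int(fail_miss.sum()),
            "maf": int(attributed_maf.sum()),
            "hwe": int(attributed_hwe.sum()),
        },
        retained_ids=list(g.variants["id"][keep]),
    )
    return g.subset_variants(np.flatnonzero(keep)), report


def sample_qc_filter(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    required_covariates: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Remove samples with high genotype missingness or incomplete covariates.

    A reported-vs-genetic sex check would require X-chromosome data; when no
    X variants are present (the usual case for simulated panels) that
    criterion is skipped and noted in the report with a count of zero.
    """
    t = thresholds or QCThresholds()
    covs = required_covariates if required_covariates is not None else REQUIRED_COVARIATES
    ids_g = list(g.samples["id"])
    ids_p = list(phen["sample_id"])
    if set(ids_g) != set(ids_p):
        raise AlignmentError("sample ids differ between genotypes and phenotypes")
    phen = phen.set_index("sample_id").loc[ids_g].reset_index()
    fail_miss = g.sample_missingness() > t.max_sample_missing
    fail_cov = phen[covs].isna().any(axis=1).to_numpy()
    keep = ~(fail_miss | fail_cov)
    report = QCReport(
        axis="sample",
        n_in=g.n_samples,
        n_out=int(keep.sum()),
        removed={
            "missingness": int(fail_miss.sum()),
            "covariate_completeness": int((fail_cov & ~fail_miss).sum()),
            "sex_inconsistency": 0,  # skipped: no X-chromosome genotypes
        },
        retained_ids=list(g.samples["id"][keep]),
    )
    idx = np.flatnonzero(keep)
    return g.subset_samples(idx), phen.iloc[idx].reset_index(drop=True), report


def intersect_variants(
    cohorts: list[GenotypeMatrix],
) -> tuple[list[GenotypeMatrix], pd.DataFrame]:
    """Restrict cohorts to variants shared by id with consistent alleles.

    The first cohort fixes the effect-allele orientation. In other cohorts a
    variant whose alleles are swapped relative to the reference is retained
    with dosages flipped to ``2 - dosage``; allele pairs that cannot be
    reconciled, including strand-ambiguous A/T and C/G pairs, are dropped.
    Returns the restricted cohorts and a log of dropped/flipped variants.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to intersect")
    ref = cohorts[0]
    shared = set(ref.variants["id"])
    for c in cohorts[1:]:
        shared &= set(c.variants["id"])
    log_rows = []
    keep_ids: list[str] = []
    ref_alleles = ref.variants.set_index("id")[["allele_effect", "allele_other"]]
    flips: list[dict[int, bool]] = [dict() for _ in cohorts]
    for vid in ref.variants["id"]:
        if vid not in shared:
            continue
        a_eff, a_oth = ref_alleles.loc[vid]
        if frozenset({a_eff, a_oth}) in STRAND_AMBIGUOUS:
            log_rows.append({"id": vid, "action": "dropped", "reason": "strand_ambiguous"})
            continue
        ok = True
        for ci, c in enumerate(cohorts[1:], start=1):
            row = c.variants.loc[c.variants["id"] == vid].iloc[0]
            if (row["allele_effect"], row["allele_other"]) == (a_eff, a_oth):
                flips[ci][vid] = False
            elif (row["allele_effect"], row["allele_other"]) == (a_oth, a_eff):
                flips[ci][vid] = True
                log_rows.append({"id": vid, "action": "flipped", "reason": f"cohort_{ci}_swapped"})
            else:
                log_rows.append({"id": vid, "action": "dropped", "reason": f"cohort_{ci}_allele_mismatch"})
                ok = False
                break
        if ok:
            keep_ids.append(vid)
    if not keep_ids:
        raise ValueError("no variants shared across cohorts after harmonization")
    out = []
    for ci, c in enumerate(cohorts):
        pos = {vid: k for k, vid in enumerate(c.variants["id"])}
        idx = np.array([pos[vid] for vid in keep_ids])
        sub = c.subset_variants(idx)
        if ci > 0:
            flip_mask = np.array([flips[ci][vid] for vid in keep_ids])
            if flip_mask.any():
                sub.values[:, flip_mask] = 2.0 - sub.values[:, flip_mask]
                sub.variants.loc[flip_mask, ["allele_effect", "allele_other"]] = (
                    sub.variants.loc[flip_mask, ["allele_other", "allele_effect"]].to_numpy()
                )
        out.append(sub)
    log = pd.DataFrame(log_rows, columns=["id", "action", "reason"])
    return out, log
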