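"""Variant quality control and cross-consortium imputation harmonization.

The basic QC stage reproduces the array-genotype filter set (chromosome Y,
call rate, the joint MAF/call-rate rule, monomorphism, country-stratified
Hardy-Weinberg).  The harmonization stage applies the graded delta-r2 rule
used to reconcile the two consortia's separately imputed datasets, followed
by the MAF floor in population cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeMatrix

__all__ = [
    "HweResult",
    "QcReport",
    "hwe_test_stratified",
    "apply_basic_qc",
    "harmonize_imputation",
    "DELTA_R2_RULES",
]

FAIL_REASONS = [
    "chrY", "call_rate", "maf_callrate", "monomorphic", "hwe",
    "r2_low", "delta_r2", "maf_floor",
]

# (lower bin edge, upper bin edge] of min(r2) -> strict delta-r2 threshold
DELTA_R2_RULES = [
    (0.9, 1.0, 0.05),
    (0.8, 0.9, 0.02),
    (0.5, 0.8, 0.01),
]


@dataclass
class HweResult:
    p: float
    chi2: float
    df: int
    all_monomorphic: bool = False


@dataclass
class QcReport:
    """Per-variant verdicts; counts partition the input exactly."""

    verdicts: pd.Series  # variant_id -> 'pass' or a fail reason
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = dict(self.verdicts.value_counts())

    @property
    def n_pass(self) -> int:
        return int((self.verdicts == "pass").sum())

    def passing_ids(self) -> list:
        return list(self.verdicts.index[self.verdicts == "pass"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variant_id": self.verdicts.index,
                             "verdict": self.verdicts.values})


def hwe_test_stratified(genotype_counts_by_country: dict) -> HweResult:
    """Country-stratified Hardy-Weinberg test.

    ``genotype_counts_by_country`` maps country -> (n_AA, n_Aa, n_aa) counted
    among controls.  Each informative country contributes a 1-df chi-square
    against its own allele frequency; statistics are summed with
    df = number of informative countries.  If every country is monomorphic
    the combined p is 1 with the ``all_monomorphic`` flag set.
    """
    chi2_total, df = 0.0, 0
    for country, (n_aa, n_ab, n_bb) in genotype_counts_by_country.items():
        n = n_aa + n_ab + n_bb
        if n == 0:
            continue
        p_hat = (2 * n_aa + n_ab) / (2 * n)
        if p_hat in (0.0, 1.0):
            continue  # monomorphic stratum: uninformative for HWE
        exp = np.array([n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        chi2_total += float(np.sum((obs - exp) ** 2 / exp))
        df += 1
    if df == 0:
        return HweResult(p=1.0, chi2=0.0, df=0, all_monomorphic=True)
    return HweResult(p=float(stats.chi2.sf(chi2_total, df)), chi2=chi2_total, df=df)


def _hwe_counts_from_dosages(dosage, samples: pd.DataFrame) -> dict:
    """Hard-call genotype counts among controls, per country."""
    is_control = (samples["status"] == "control").to_numpy()
    counts = {}
    for country in samples["country"].unique():
        mask = is_control & (samples["country"] == country).to_numpy()
        d = dosage[mask]
        d = d[np.isfinite(d)]
        g = np.rint(d).astype(int)
        counts[country] = (int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
    return counts


def apply_basic_qc(matrix: GenotypeMatrix, samples: pd.DataFrame,
                   hwe_p_threshold: float = 1e-7) -> QcReport:
    """Array-genotype QC with a fixed order of checks.

    Per variant the first matching failure is recorded: chromosome Y; call
    rate < 95%; MAF < 0.05 together with call rate < 98%; monomorphic;
    Hardy-Weinberg departure at p < ``hwe_p_threshold`` (country-stratified,
    among controls).  Call rate comes from the variant metadata when present
    (``call_rate`` column), else from the fraction of non-missing dosages.
    """
    variants = matrix.variants
    if "call_rate" in variants.columns:
        call_rate = variants["call_rate"].to_numpy(dtype=float)
    else:
        call_rate = np.isfinite(matrix.dosages).mean(axis=0)
    verdicts = {}
    for j, row in variants.iterrows():
        vid = row["variant_id"]
        d = matrix.dosages[:, j]
        d_obs = d[np.isfinite(d)]
        freq = d_obs.mean() / 2 if d_obs.size else np.nan
        maf = min(freq, 1 - freq) if np.isfinite(freq) else np.nan
        if str(row["chrom"]).lstrip("chr") == "Y" or str(row["chrom"]) == "chrY":
            verdicts[vid] = "chrY"
        elif call_rate[j] < 0.95:
            verdicts[vid] = "call_rate"
        elif np.isfinite(maf) and maf < 0.05 and call_rate[j] < 0.98:
            verdicts[vid] = "maf_callrate"
        elif d_obs.size == 0 or np.all(d_obs == d_obs[0]) or maf == 0:
            verdicts[vid] = "monomorphic"
        else:
            hwe = hwe_test_stratified(_hwe_counts_from_dosages(d, samples))
            verdicts[vid] = "hwe" if hwe.p < hwe_p_threshold else "pass"
    return QcReport(pd.Series(verdicts, name="verdict"))


def harmonize_imputation(r2_bcac: float, r2_cimba: float, maf_bcac_cases: float,
                         maf_floor: float = 0.01, delta_rules=None) -> str:
    """Cross-consortium imputation-quality verdict for one variant.

    Returns ``'keep'`` or the fail reason.  A variant is excluded when either
    r^2 < 0.5; otherwise the absolute r^2 difference must fall below a
    threshold graded by quality bin (0.05 above 0.9; 0.02 in (0.8, 0.9];
    0.01 in (0.5, 0.8]), taking the stricter threshold of the lower bin when
    the two r^2 fall in different bins.  Finally the variant must exceed the
    MAF floor in population (BCAC) cases.
    """
    rules = DELTA_R2_RULES if delta_rules is None else delta_rules
    lo = min(r2_bcac, r2_cimba)
    if r2_bcac < 0.5 or r2_cimba < 0.5:
        return "r2_low"
    threshold = None
    for low, high, thr in rules:
        if low < lo <= high:
            threshold = thr
            break
    if threshold is None:  # lo == 0.5 exactly: below the lowest open bin
        return "r2_low"
    if not abs(r2_bcac - r2_cimba) < threshold:
        return "delta_r2"
    if maf_bcac_cases <= maf_floor:
        return "maf_floor"
    return "keep"


def harmonize_matrix(matrix: GenotypeMatrix, maf_floor: float = 0.01) -> QcReport:
    """Apply :func:`harmonize_imputation` across a variant panel."""
    verdicts = {}
    for _, row in matrix.variants.iterrows():
        v = harmonize_imputation(row["r2_bcac"], row["r2_cimba"],
                                 row["maf_bcac_cases"], maf_floor=maf_floor)
        verdicts[row["variant_id"]] = "pass" if v == "keep" else v
    return QcReport(pd.Series(verdicts, name="verdict"))
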