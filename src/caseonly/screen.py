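"""Screening logic: proximity exclusion, independence screen, threshold
gates, the ER-negative validation step, region clustering and the known-SNP
interaction assessment.

All threshold comparisons are strict (``<``); region chaining treats a gap of
exactly the link distance as linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "Region",
    "exclude_proximal",
    "independence_screen",
    "gate_novel_brca1",
    "gate_novel",
    "assess_known_snps",
    "cluster_regions",
    "accounting",
]


@dataclass(frozen=True)
class ScreenConfig:
    proximity_window: int = 500_000
    p_control_only: float = 1e-8
    p_novel: float = 1e-8
    p_novel_er_step: float = 1e-7
    p_known: float = 2.7e-4
    p_known_er_step: float = 0.05
    region_link_distance: int = 500_000

    def __post_init__(self):
        for name in ["p_control_only", "p_novel", "p_novel_er_step", "p_known", "p_known_er_step"]:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.proximity_window <= 0 or self.region_link_distance <= 0:
            raise ValueError("windows must be positive")


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    members: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def exclude_proximal(variants: pd.DataFrame, gene_chrom: str, gene_start: int,
                     gene_end: int, window: int = 500_000) -> pd.DataFrame:
    """Drop variants in or within ``window`` of the mutation gene's interval.

    A variant is removed when it lies on the gene's chromosome inside
    [gene_start - window, gene_end + window] (1-based inclusive); variants on
    other chromosomes are untouched.
    """
    same_chrom = variants["chrom"].astype(str) == str(gene_chrom)
    pos = variants["pos"].to_numpy()
    inside = same_chrom.to_numpy() & (pos >= gene_start - window) & (pos <= gene_end + window)
    return variants.loc[~inside].copy()


def independence_screen(control_only_results: pd.DataFrame,
                        threshold: float = 1e-8):
    """Partition variants by association with carrier status among controls.

    Variants with control-only p strictly below the threshold violate the
    genotype/mutation independence assumption and are excluded.  Returns
    ``(kept, excluded)`` DataFrames; the excluded frame retains chromosome
    for per-chromosome reporting.
    """
    p = control_only_results["p"].to_numpy()
    bad = p < threshold
    return (control_only_results.loc[~bad].copy(),
            control_only_results.loc[bad].copy())


def gate_novel_brca1(case_only_all: pd.DataFrame, case_only_er_neg: pd.DataFrame,
                     config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Candidate novel modifiers for the BRCA1 analysis.

    A variant passes either via the overall route (all-cases p < 1e-8 and
    ER-negative p < 1e-7, ruling out associations driven by the tumour
    ER-status mixture) or via the ER-specific discovery route
    (ER-negative p < 1e-8 on its own).
    """
    merged = case_only_all.merge(case_only_er_neg[["variant_id", "p"]],
                                 on="variant_id", suffixes=("", "_er"))
    overall = (merged["p"] < config.p_novel) & (merged["p_er"] < config.p_novel_er_step)
    er_route = merged["p_er"] < config.p_novel
    out = merged.loc[overall | er_route].copy()
    out["route"] = np.where(overall[overall | er_route], "overall", "er_specific")
    return out


def gate_novel(case_only_all: pd.DataFrame,
               config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Candidate novel modifiers without the ER step (the BRCA2 analysis)."""
    return case_only_all.loc[case_only_all["p"] < config.p_novel].copy()


def assess_known_snps(case_only_all: pd.DataFrame, case_only_er_neg,
                      known: pd.DataFrame, carrier_gene: str,
                      config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Interaction verdict for each established susceptibility SNP.

    BRCA1, overall-list SNPs: all-cases p < 2.7e-4 AND ER-negative p < 0.05.
    BRCA1, ER-negative-list SNPs: ER-negative p < 2.7e-4.
    BRCA2 (no ER step): all-cases p < 2.7e-4.
    Known SNPs absent from the association results (e.g. failed QC) are
    reported as ``not_evaluable``.
    """
    pa = case_only_all.set_index("variant_id")["p"]
    ors = case_only_all.set_index("variant_id")["or"] if "or" in case_only_all else None
    if case_only_er_neg is not None:
        pe = case_only_er_neg.set_index("variant_id")["p"]
        ore = case_only_er_neg.set_index("variant_id")["or"] if "or" in case_only_er_neg else None
    else:
        pe = ore = None
    rows = []
    for _, snp in known.iterrows():
        vid = snp["variant_id"]
        source = snp.get("source", "overall")
        row = {"variant_id": vid, "source": source,
               "p_all": pa.get(vid, np.nan),
               "p_er": pe.get(vid, np.nan) if pe is not None else np.nan,
               "or_all": ors.get(vid, np.nan) if ors is not None else np.nan,
               "or_er": ore.get(vid, np.nan) if ore is not None else np.nan}
        if carrier_gene == "BRCA2":
            if not np.isfinite(row["p_all"]):
                verdict = "not_evaluable"
            else:
                verdict = "interaction" if row["p_all"] < config.p_known else "no_interaction"
        elif source == "er_negative":
            if not np.isfinite(row["p_er"]):
                verdict = "not_evaluable"
            else:
                verdict = "interaction" if row["p_er"] < config.p_known else "no_interaction"
        else:
            if not (np.isfinite(row["p_all"]) and np.isfinite(row["p_er"])):
                verdict = "not_evaluable"
            else:
                verdict = ("interaction"
                           if row["p_all"] < config.p_known and row["p_er"] < config.p_known_er_step
                           else "no_interaction")
        row["verdict"] = verdict
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_regions(variants: pd.DataFrame, link_distance: int = 500_000) -> list:
    """Single-linkage chaining of variants into regions.

    Two variants on the same chromosome belong to the same region when they
    can be chained through gaps of at most ``link_distance`` (inclusive).
    Regions are returned sorted by chromosome then start.
    """
    regions = []
    for chrom, grp in variants.groupby(variants["chrom"].astype(str), sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        ids = grp["variant_id"].to_numpy()
        start_idx = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > link_distance:
                members = list(ids[start_idx:i])
                regions.append(Region(chrom=str(chrom), start=int(pos[start_idx]),
                                      end=int(pos[i - 1]), members=members))
                start_idx = i
    return regions


def accounting(n_input: int, n_excluded_proximal: int, n_excluded_control: int) -> int:
    """Stage bookkeeping identity: variants reaching the case-only analysis."""
    n = n_input - n_excluded_proximal - n_excluded_control
    if n < 0:
        raise ValueError("exclusions exceed the input count")
    return n
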