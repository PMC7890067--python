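"""Forward stepwise conditional analysis and credible-causal-variant sets.

Within a region that passed the novel-modifier gates, the stepwise routine
selects conditionally independent top SNPs: at each step the variant with
the smallest conditional LRT p (adjusting for all previously selected
variants plus the standard covariates) is added while that p stays below
the selection threshold.  CCV sets follow the conditioning recursion: the
first signal is the unconditional scan's top SNP plus every variant whose p
lies within two orders of magnitude of it (p <= 100 * p_top); subsequent
signals rescan conditional on the previous top SNPs and are formed only
while some conditional p remains below the continuation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import Contrast, fit_variant
from .geno_io import GenotypeMatrix
from .screen import Region

__all__ = ["Signal", "SignalSet", "forward_stepwise", "build_ccv_sets"]

CCV_FOLD = 100.0  # within two orders of magnitude of the top SNP


def within_two_orders(p_values: dict, p_top: float) -> set:
    """Variant ids whose p lies within two orders of magnitude of the top p
    (inclusive: p <= 100 * p_top)."""
    return {v for v, p in p_values.items() if p <= CCV_FOLD * p_top}


@dataclass
class Signal:
    top_variant: str
    top_p: float
    top_or: float
    ccvs: pd.DataFrame = None  # variant_id, p, or


@dataclass
class SignalSet:
    region: Region
    signals: list = field(default_factory=list)

    @property
    def top_snps(self) -> list:
        return [s.top_variant for s in self.signals]


def _ordered_ids(matrix: GenotypeMatrix) -> list:
    """Deterministic candidate order: position then id (tie-break rule)."""
    v = matrix.variants
    order = v.sort_values(["chrom", "pos", "variant_id"]).index
    return list(v.loc[order, "variant_id"])


def _conditional_scan(matrix, samples, contrast, selected, candidates,
                      adjust, pcs, min_cimba, r2_guard=0.99):
    """Conditional p/OR for every candidate given the selected set."""
    cond = (np.column_stack([matrix.dosage_for(v) for v in selected])
            if selected else None)
    results = {}
    for vid in candidates:
        d = matrix.dosage_for(vid)
        if cond is not None:
            collinear = False
            for k in range(cond.shape[1]):
                ok = np.isfinite(d) & np.isfinite(cond[:, k])
                if np.std(d[ok]) == 0 or np.std(cond[ok, k]) == 0:
                    collinear = True
                    break
                r = np.corrcoef(d[ok], cond[ok, k])[0, 1]
                if r * r > r2_guard:
                    collinear = True
                    break
            if collinear:
                warnings.warn(f"{vid} collinear with selected set; skipped", stacklevel=2)
                continue
        try:
            res = fit_variant(d, samples, contrast, adjust=adjust, pcs=pcs,
                              condition_on=cond, min_cimba_per_country=min_cimba)
        except ValueError:
            continue
        if not res.converged:
            warnings.warn(f"conditional fit for {vid} did not converge; excluded",
                          stacklevel=2)
            continue
        results[vid] = (res.p, res.or_)
    return results


def forward_stepwise(matrix: GenotypeMatrix, samples: pd.DataFrame,
                     contrast: Contrast, threshold: float = 1e-8,
                     candidate_ids=None, adjust=("age", "country"), pcs=None,
                     min_cimba_per_country: int = 10) -> pd.DataFrame:
    """Greedy selection of conditionally independent top SNPs in one region.

    ``candidate_ids`` restricts the pool (typically the variants already
    genome-wide significant); ties on conditional p break by position then
    id.  Returns the ordered selection with conditional p and OR at entry.
    """
    ordered = _ordered_ids(matrix)
    pool = [v for v in ordered if candidate_ids is None or v in set(candidate_ids)]
    selected, rows = [], []
    while pool:
        scan = _conditional_scan(matrix, samples, contrast, selected, pool,
                                 adjust, pcs, min_cimba_per_country)
        if not scan:
            break
        best = min(scan, key=lambda v: (scan[v][0], pool.index(v)))
        p_best, or_best = scan[best]
        if not (p_best < threshold):
            break
        selected.append(best)
        rows.append({"variant_id": best, "conditional_p": p_best,
                     "conditional_or": or_best, "step": len(selected)})
        pool.remove(best)
    return pd.DataFrame(rows, columns=["variant_id", "conditional_p", "conditional_or", "step"])


def build_ccv_sets(matrix: GenotypeMatrix, samples: pd.DataFrame,
                   contrast: Contrast, region: Region = None,
                   continue_threshold: float = 1e-6,
                   adjust=("age", "country"), pcs=None,
                   min_cimba_per_country: int = 10,
                   max_signals: int = 20) -> SignalSet:
    """Iterative credible-causal-variant set construction for one region."""
    if region is None:
        v = matrix.variants
        region = Region(chrom=str(v["chrom"].iloc[0]), start=int(v["pos"].min()),
                        end=int(v["pos"].max()), members=list(v["variant_id"]))
    ordered = _ordered_ids(matrix)
    selected_tops = []
    signals = []
    for k in range(max_signals):
        candidates = [v for v in ordered if v not in selected_tops]
        scan = _conditional_scan(matrix, samples, contrast, selected_tops, candidates,
                                 adjust, pcs, min_cimba_per_country)
        if not scan:
            break
        best = min(scan, key=lambda v: (scan[v][0], ordered.index(v)))
        p_top, or_top = scan[best]
        if k > 0 and not (p_top < continue_threshold):
            break
        members = within_two_orders({v: pv for v, (pv, _) in scan.items()}, p_top)
        ccv_rows = [{"variant_id": v, "p": pv, "or": orv}
                    for v, (pv, orv) in scan.items() if v in members]
        ccv = pd.DataFrame(ccv_rows).sort_values("p").reset_index(drop=True)
        signals.append(Signal(top_variant=best, top_p=p_top, top_or=or_top, ccvs=ccv))
        selected_tops.append(best)
    return SignalSet(region=region, signals=signals)


def signal_set_frame(signal_set: SignalSet) -> pd.DataFrame:
    """Flat per-signal summary table (signal, #CCV, top SNP, conditional stats)."""
    rows = []
    for i, s in enumerate(signal_set.signals, start=1):
        rows.append({"region": signal_set.region.label, "signal": i,
                     "n_ccv": len(s.ccvs), "top_snp": s.top_variant,
                     "conditional_or": s.top_or, "conditional_p": s.top_p})
    return pd.DataFrame(rows)
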