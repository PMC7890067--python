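"""Target-gene prioritisation for credible causal variants.

A point-scoring scheme over three evidence categories nominates the genes a
CCV set most plausibly regulates or alters.  Distal evidence combines
physical chromatin links (ChIA-PET, Hi-C), computational enhancer-promoter
predictions, and eQTL associations; promoter evidence requires the CCV to
sit in a promoter-class histone peak overlapping the strand-aware TSS
window [TSS-1000, TSS+100]; coding evidence covers deleterious missense or
nonsense changes (REVEL > 0.5) and predicted splice alterations (ada or rf
score above the splice threshold).  Scores cap at 8 (distal), 4 (promoter)
and 3 (coding) and map to confidence levels: Level 1 when distal > 4,
promoter >= 3 or coding > 1; Level 2 when 1 <= distal <= 4, promoter in
{1, 2} or coding = 1; Level 3 when any category lies strictly between 0 and
1.  The per-evidence point table is a deliberately minimal reconstruction
(one point per independent evidence class plus the named bonuses) and is
isolated in ``ScoringTable`` so users can recalibrate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .geno_io import AnnotationBundle

__all__ = [
    "EvidenceHit",
    "TargetScore",
    "ScoringTable",
    "eqtl_scan",
    "collect_evidence",
    "score_targets",
    "confidence_level",
]

PHYSICAL_LINK_TYPES = {"chia_pet_link", "hic_link"}
COMPUTATIONAL_TYPES = {"computational_ep", "super_enhancer_overlap"}

PROMOTER_UPSTREAM = 1_000
PROMOTER_DOWNSTREAM = 100

CAPS = {"distal": 8.0, "promoter": 4.0, "coding": 3.0}


@dataclass(frozen=True)
class EvidenceHit:
    variant_id: str
    gene: str
    category: str        # distal / promoter / coding
    evidence_type: str
    signal: int = 1


@dataclass
class TargetScore:
    gene: str
    signal: int
    distal: float = 0.0
    promoter: float = 0.0
    coding: float = 0.0
    level: str = "none"


@dataclass(frozen=True)
class ScoringTable:
    """Configurable point assignments; defaults follow the published ranges."""

    distal_per_class: float = 1.0
    distal_enriched_bonus: float = 1.0
    distal_multi_link_bonus: float = 1.0
    promoter_base: float = 1.0
    promoter_depth_bonus: float = 1.0   # >= 2 promoter hits
    promoter_eqtl_total: float = 3.0    # promoter hit with supporting eQTL
    coding_per_type: float = 1.0
    not_expressed_penalty: float = 1.0
    driver_bonus: float = 1.0
    revel_threshold: float = 0.5
    splice_threshold: float = 0.6


def eqtl_scan(expression: pd.DataFrame, dosages: pd.DataFrame, lead_chrom: str,
              lead_pos: int, gene_models: pd.DataFrame, covariates: pd.DataFrame = None,
              window: int = 2_000_000, min_samples: int = 10) -> pd.DataFrame:
    """Covariate-adjusted linear eQTL scan around a lead variant.

    ``expression`` is genes x samples (already log2 / quantile-normalised and
    filtered to genes with nonzero median expression); ``dosages`` is
    variants x samples.  Every gene with a TSS within ``window`` of the lead
    position on its chromosome is regressed on each variant's dosage plus
    the covariate columns (e.g. ESR1 expression; copy number for tumours).
    Genes with fewer than ``min_samples`` complete observations are skipped.
    """
    import statsmodels.api as sm

    in_cis = gene_models[
        (gene_models["chrom"].astype(str) == str(lead_chrom))
        & (np.abs(gene_models["tss"] - lead_pos) <= window)
    ]
    samples = list(expression.columns)
    rows = []
    for _, g in in_cis.iterrows():
        gene = g["gene"]
        if gene not in expression.index:
            continue
        y_all = expression.loc[gene, samples].to_numpy(dtype=float)
        for vid in dosages.index:
            x_all = dosages.loc[vid, samples].to_numpy(dtype=float)
            ok = np.isfinite(y_all) & np.isfinite(x_all)
            X = x_all[ok][:, None]
            if covariates is not None:
                C = covariates.loc[samples].to_numpy(dtype=float)[ok]
                ok2 = np.all(np.isfinite(C), axis=1)
                X = np.column_stack([X[ok2], C[ok2]])
                y = y_all[ok][ok2]
            else:
                y = y_all[ok]
            if len(y) < min_samples:
                continue
            model = sm.OLS(y, sm.add_constant(X)).fit()
            rows.append({"variant_id": vid, "gene": gene,
                         "slope": float(model.params[1]),
                         "t": float(model.tvalues[1]),
                         "p": float(model.pvalues[1]),
                         "n": int(len(y)), "source": "scan"})
    return pd.DataFrame(rows, columns=["variant_id", "gene", "slope", "t", "p", "n", "source"])


def _tree_per_chrom(track: pd.DataFrame) -> dict:
    trees = {}
    for _, r in track.iterrows():
        start, end = int(r["start"]), int(r["end"])
        if end <= start:
            end = start + 1  # degenerate interval: treat as a point
        trees.setdefault(str(r["chrom"]), IntervalTree()).addi(start, end, r.get("gene"))
    return trees


def _crosses_tad(tad_trees, chrom, pos_a, pos_b) -> bool:
    tree = tad_trees.get(str(chrom))
    if tree is None:
        return False
    lo, hi = sorted((pos_a, pos_b))
    return bool(tree.overlap(lo, hi))


def collect_evidence(ccvs: pd.DataFrame, annotations: AnnotationBundle,
                     eqtl_table: pd.DataFrame = None, signal: int = 1,
                     scoring: ScoringTable = ScoringTable()) -> list:
    """Intersect CCV positions with annotation tracks into evidence hits.

    ``ccvs`` needs variant_id, chrom, pos (1-based).  Link tracks contribute
    distal hits when the distal anchor contains a CCV and names a target
    gene; links whose CCV-to-TSS span crosses a TAD boundary are discarded.
    Hits naming genes absent from the gene models are dropped.
    """
    known_genes = set(annotations.gene_models["gene"])
    tss_by_gene = annotations.gene_models.set_index("gene")
    tad_trees = _tree_per_chrom(annotations.tracks.get("tad_boundary", pd.DataFrame(
        columns=["chrom", "start", "end", "gene"])))
    hits = []

    link_type_map = {"chia_pet_link": "chia_pet_link", "hic_link": "hic_link",
                     "computational_ep": "computational_ep",
                     "super_enhancer": "super_enhancer_overlap"}
    trees = {name: _tree_per_chrom(annotations.tracks.get(name, pd.DataFrame(
        columns=["chrom", "start", "end", "gene"]))) for name in link_type_map}
    enriched_trees = _tree_per_chrom(annotations.tracks.get("enriched_feature", pd.DataFrame(
        columns=["chrom", "start", "end", "gene"])))
    promoter_trees = _tree_per_chrom(annotations.tracks.get("promoter_histone", pd.DataFrame(
        columns=["chrom", "start", "end", "gene"])))

    for _, v in ccvs.iterrows():
        vid, chrom, pos = v["variant_id"], str(v["chrom"]), int(v["pos"])
        pos0 = pos - 1  # to half-open 0-based for interval queries

        # distal: link and prediction tracks
        for track_name, ev_type in link_type_map.items():
            for iv in trees[track_name].get(chrom, IntervalTree()).at(pos0):
                gene = iv.data
                if gene is None or gene not in known_genes:
                    continue
                tss = int(tss_by_gene.loc[gene, "tss"])
                if str(tss_by_gene.loc[gene, "chrom"]) == chrom and _crosses_tad(
                        tad_trees, chrom, pos, tss):
                    continue
                hits.append(EvidenceHit(vid, gene, "distal", ev_type, signal))
        # enriched-feature overlap upweights distal enhancers (gene-agnostic:
        # attach to every distally linked gene of this CCV)
        if enriched_trees.get(chrom, IntervalTree()).at(pos0):
            for g in {h.gene for h in hits
                      if h.variant_id == vid and h.category == "distal"}:
                hits.append(EvidenceHit(vid, g, "distal", "enriched_feature", signal))

        # distal eQTL evidence
        eq_sources = [t for t in (eqtl_table, annotations.eqtl) if t is not None and len(t)]
        for tab in eq_sources:
            sub = tab[(tab["variant_id"] == vid) & (tab["p"] < 0.05)]
            for _, e in sub.iterrows():
                if e["gene"] in known_genes:
                    hits.append(EvidenceHit(vid, e["gene"], "distal", "eqtl", signal))

        # promoter: histone peak containing the CCV and overlapping a TSS window
        peak_hits = promoter_trees.get(chrom, IntervalTree()).at(pos0)
        if peak_hits:
            for gene, g in tss_by_gene.iterrows():
                if str(g["chrom"]) != chrom:
                    continue
                tss = int(g["tss"])
                if g["strand"] == "-":
                    win_lo, win_hi = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
                else:
                    win_lo, win_hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
                if not (win_lo <= pos <= win_hi):
                    continue
                for iv in peak_hits:
                    if iv.begin <= win_hi and iv.end >= win_lo + 1:
                        hits.append(EvidenceHit(vid, gene, "promoter",
                                                "promoter_histone", signal))
                        break

        # coding consequences
        cons = annotations.coding[annotations.coding["variant_id"] == vid]
        for _, c in cons.iterrows():
            gene = c["gene"]
            if gene not in known_genes:
                continue
            kind = c["consequence"]
            revel = c.get("revel", np.nan)
            if kind in {"missense", "nonsense"}:
                if np.isfinite(revel) and revel > scoring.revel_threshold:
                    hits.append(EvidenceHit(vid, gene, "coding", kind, signal))
            elif kind in {"splice_ada", "splice_rf", "splice"}:
                ada = c.get("splice_ada", np.nan)
                rf = c.get("splice_rf", np.nan)
                best = np.nanmax([ada, rf]) if np.isfinite([ada, rf]).any() else np.nan
                if np.isfinite(best) and best > scoring.splice_threshold:
                    hits.append(EvidenceHit(vid, gene, "coding", "splice", signal))
    return hits


def confidence_level(distal: float, promoter: float, coding: float) -> str:
    """Map the three category scores to a confidence level."""
    if distal > 4 or promoter >= 3 or coding > 1:
        return "1"
    if (1 <= distal <= 4) or promoter in (1, 2) or coding == 1:
        return "2"
    if (0 < distal < 1) or (0 < promoter < 1) or (0 < coding < 1):
        return "3"
    return "none"


def score_targets(evidence: list, driver_genes=frozenset(), expressed_genes=None,
                  scoring: ScoringTable = ScoringTable()) -> pd.DataFrame:
    """Point totals per (gene, signal) with the mapped confidence level.

    Distal: one point per evidence class present (physical link,
    computational prediction, eQTL), plus the enriched-feature and
    multiple-independent-interaction bonuses and the driver bonus; cap 8.
    Promoter: one point for a promoter hit, a second for depth (>= 2 hits),
    three in total when an eQTL supports the same gene; minus one when the
    gene is not expressed (floor 0); cap 4.  Coding: one point per change
    type (deleterious missense, nonsense, splice); same expression penalty;
    cap 3.  The driver bonus applies per category when the base score is
    positive.  The gene-level ``level`` column reports the best level over
    categories; per gene the best row across signals should be retained by
    the caller when aggregating.
    """
    rows = []
    by_key = {}
    for h in evidence:
        by_key.setdefault((h.gene, h.signal), []).append(h)
    for (gene, signal), hs in sorted(by_key.items()):
        distal_hits = [h for h in hs if h.category == "distal"]
        classes = set()
        for h in distal_hits:
            if h.evidence_type in PHYSICAL_LINK_TYPES:
                classes.add("physical")
            elif h.evidence_type in COMPUTATIONAL_TYPES:
                classes.add("computational")
            elif h.evidence_type == "eqtl":
                classes.add("eqtl")
        distal = scoring.distal_per_class * len(classes)
        if any(h.evidence_type == "enriched_feature" for h in distal_hits):
            distal += scoring.distal_enriched_bonus
        physical = {(h.variant_id, h.evidence_type) for h in distal_hits
                    if h.evidence_type in PHYSICAL_LINK_TYPES}
        if len(physical) >= 2:
            distal += scoring.distal_multi_link_bonus

        prom_hits = [h for h in hs if h.category == "promoter"]
        eqtl_support = any(h.evidence_type == "eqtl" for h in hs)
        if prom_hits:
            if eqtl_support:
                promoter = scoring.promoter_eqtl_total
            else:
                promoter = scoring.promoter_base
                if len(prom_hits) >= 2:
                    promoter += scoring.promoter_depth_bonus
        else:
            promoter = 0.0

        coding_types = {h.evidence_type for h in hs if h.category == "coding"}
        coding = scoring.coding_per_type * len(coding_types)

        not_expressed = expressed_genes is not None and gene not in expressed_genes
        if not_expressed:
            promoter = max(promoter - scoring.not_expressed_penalty, 0.0)
            coding = max(coding - scoring.not_expressed_penalty, 0.0)
        if gene in driver_genes:
            if distal > 0:
                distal += scoring.driver_bonus
            if promoter > 0:
                promoter += scoring.driver_bonus
            if coding > 0:
                coding += scoring.driver_bonus

        distal = min(distal, CAPS["distal"])
        promoter = min(promoter, CAPS["promoter"])
        coding = min(coding, CAPS["coding"])
        rows.append({"gene": gene, "signal": signal, "distal": distal,
                     "promoter": promoter, "coding": coding,
                     "level": confidence_level(distal, promoter, coding)})
    return pd.DataFrame(rows, columns=["gene", "signal", "distal", "promoter", "coding", "level"])
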