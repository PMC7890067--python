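"""Evidence collection, eQTL scan and target-gene scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caseonly.geno_io import AnnotationBundle
from caseonly.inquisit import (CAPS, EvidenceHit, ScoringTable,
                               collect_evidence, confidence_level, eqtl_scan,
                               score_targets)


@pytest.fixture()
def gene_models():
    return pd.DataFrame({
        "gene": ["G1", "G2", "Gminus"],
        "chrom": ["1", "1", "1"],
        "tss": [50_000, 900_000, 70_000],
        "strand": ["+", "+", "-"],
    })


def _bundle(gene_models, **tracks):
    empty = pd.DataFrame(columns=["chrom", "start", "end", "gene"])
    all_tracks = {name: tracks.get(name, empty) for name in
                  ["chia_pet_link", "hic_link", "computational_ep", "super_enhancer",
                   "promoter_histone", "enriched_feature", "tad_boundary"]}
    return AnnotationBundle(tracks=all_tracks, gene_models=gene_models,
                            coding=tracks.get("coding"), eqtl=tracks.get("eqtl"))


def _ccv(pos, vid="ccv1", chrom="1"):
    return pd.DataFrame({"variant_id": [vid], "chrom": [chrom], "pos": [pos]})


class TestEqtlScan:
    def _data(self, slope=0.5, n=200, noise=0.5, seed=0, tss=50_000):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        d = rng.binomial(2, 0.3, n).astype(float)
        y = slope * d + rng.normal(0, noise, n)
        expr = pd.DataFrame([y], index=["G1"], columns=samples)
        dos = pd.DataFrame([d], index=["lead"], columns=samples)
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["1"], "tss": [tss],
                              "strand": ["+"]})
        return expr, dos, genes

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_slope_recovered(self, seed):
        expr, dos, genes = self._data(seed=seed)
        out = eqtl_scan(expr, dos, "1", 40_000, genes)
        assert len(out) == 1
        assert 0.35 <= out.slope.item() <= 0.65

    def test_gene_outside_window_not_tested(self):
        expr, dos, genes = self._data(tss=2_200_000)
        out = eqtl_scan(expr, dos, "1", 40_000, genes)
        assert len(out) == 0

    def test_permuted_dosage_null(self):
        ps = []
        for seed in range(20):
            expr, dos, genes = self._data(seed=seed)
            rng = np.random.default_rng(100 + seed)
            dos.iloc[0] = rng.permutation(dos.iloc[0].to_numpy())
            ps.append(eqtl_scan(expr, dos, "1", 40_000, genes).p.item())
        assert 0.2 < np.mean(ps) < 0.8

    def test_covariate_adjustment_runs(self):
        expr, dos, genes = self._data()
        cov = pd.DataFrame({"esr1": np.random.default_rng(5).normal(size=200)},
                           index=expr.columns)
        out = eqtl_scan(expr, dos, "1", 40_000, genes, covariates=cov)
        assert 0.3 <= out.slope.item() <= 0.7

    def test_too_few_samples_skipped(self):
        expr, dos, genes = self._data(n=5)
        out = eqtl_scan(expr, dos, "1", 40_000, genes)
        assert len(out) == 0


class TestCollectEvidence:
    def test_chia_pet_anchor_gives_distal_hit(self, gene_models):
        track = pd.DataFrame({"chrom": ["1"], "start": [499_000], "end": [501_000],
                              "gene": ["G1"]})
        bundle = _bundle(gene_models, chia_pet_link=track)
        hits = collect_evidence(_ccv(500_000), bundle)
        assert any(h.gene == "G1" and h.category == "distal"
                   and h.evidence_type == "chia_pet_link" for h in hits)

    def test_tad_boundary_discards_crossing_link(self, gene_models):
        track = pd.DataFrame({"chrom": ["1"], "start": [499_000], "end": [501_000],
                              "gene": ["G1"]})
        tad = pd.DataFrame({"chrom": ["1"], "start": [200_000], "end": [200_100],
                            "gene": [None]})
        bundle = _bundle(gene_models, chia_pet_link=track, tad_boundary=tad)
        hits = collect_evidence(_ccv(500_000), bundle)  # CCV at 500k, G1 TSS at 50k
        assert not hits

    def test_unknown_gene_dropped(self, gene_models):
        track = pd.DataFrame({"chrom": ["1"], "start": [499_000], "end": [501_000],
                              "gene": ["NOT_A_GENE"]})
        bundle = _bundle(gene_models, chia_pet_link=track)
        assert collect_evidence(_ccv(500_000), bundle) == []

    def test_promoter_window_strand_aware(self, gene_models):
        peak = pd.DataFrame({"chrom": ["1", "1"], "start": [49_000, 69_800],
                             "end": [50_200, 70_500], "gene": [None, None]})
        bundle = _bundle(gene_models, promoter_histone=peak)
        # + strand: TSS 50,000, window [49,000, 50,100]; CCV at TSS+50 is inside
        hits = collect_evidence(_ccv(50_050), bundle)
        assert any(h.gene == "G1" and h.category == "promoter" for h in hits)
        # + strand: TSS+200 is outside the downstream bound of 100
        assert not any(h.gene == "G1" for h in collect_evidence(_ccv(50_200), bundle))
        # - strand gene: window flips to [TSS-100, TSS+1000]
        hits_minus = collect_evidence(_ccv(70_400), bundle)
        assert any(h.gene == "Gminus" and h.category == "promoter" for h in hits_minus)

    @pytest.mark.parametrize("consequence, revel, expect", [
        ("missense", 0.4, False),   # below the deleteriousness threshold
        ("missense", 0.6, True),
        ("nonsense", 0.8, True),
    ])
    def test_coding_revel_rule(self, gene_models, consequence, revel, expect):
        coding = pd.DataFrame({"variant_id": ["ccv1"], "gene": ["G1"],
                               "consequence": [consequence], "revel": [revel],
                               "splice_ada": [np.nan], "splice_rf": [np.nan]})
        bundle = _bundle(gene_models, coding=coding)
        hits = collect_evidence(_ccv(123), bundle)
        assert any(h.category == "coding" for h in hits) is expect

    def test_splice_threshold(self, gene_models):
        coding = pd.DataFrame({"variant_id": ["ccv1", "ccv1"], "gene": ["G1", "G2"],
                               "consequence": ["splice_ada", "splice_rf"],
                               "revel": [np.nan, np.nan],
                               "splice_ada": [0.7, np.nan], "splice_rf": [np.nan, 0.5]})
        bundle = _bundle(gene_models, coding=coding)
        hits = collect_evidence(_ccv(123), bundle)
        genes = {h.gene for h in hits if h.evidence_type == "splice"}
        assert genes == {"G1"}  # 0.7 > 0.6 passes, 0.5 does not


class TestScoring:
    def test_level_rule_golden_grid(self):
        # enumerate representative triples against the printed mapping
        cases = {
            (5, 0, 0): "1", (8, 0, 0): "1", (0, 3, 0): "1", (0, 4, 0): "1",
            (0, 0, 2): "1", (0, 0, 3): "1",
            (4, 0, 0): "2", (1, 0, 0): "2", (0, 1, 0): "2", (0, 2, 0): "2",
            (0, 0, 1): "2",
            (0.5, 0, 0): "3", (0, 0.5, 0): "3", (0, 0, 0.5): "3",
            (0, 0, 0): "none",
        }
        for (d, p, c), lvl in cases.items():
            assert confidence_level(d, p, c) == lvl, (d, p, c)

    def test_driver_bonus_worked_example(self):
        # distal 4 before the bonus -> 5 after -> Level 1
        hits = [
            EvidenceHit("v1", "G", "distal", "chia_pet_link"),
            EvidenceHit("v1", "G", "distal", "hic_link"),          # 2 physical links
            EvidenceHit("v1", "G", "distal", "computational_ep"),
            EvidenceHit("v1", "G", "distal", "eqtl"),
        ]
        base = score_targets(hits, driver_genes=set())
        assert base.distal.item() == 4 and base.level.item() == "2"
        boosted = score_targets(hits, driver_genes={"G"})
        assert boosted.distal.item() == 5 and boosted.level.item() == "1"

    def test_promoter_scoring_depth_and_eqtl(self):
        prom = [EvidenceHit("v1", "G", "promoter", "promoter_histone")]
        assert score_targets(prom).promoter.item() == 1
        deep = prom + [EvidenceHit("v2", "G", "promoter", "promoter_histone")]
        assert score_targets(deep).promoter.item() == 2
        with_eqtl = prom + [EvidenceHit("v1", "G", "distal", "eqtl")]
        out = score_targets(with_eqtl)
        assert out.promoter.item() == 3 and out.level.item() == "1"

    def test_expression_downweighting_with_floor(self):
        coding = [EvidenceHit("v1", "G", "coding", "missense")]
        expressed = score_targets(coding, expressed_genes={"G"})
        silent = score_targets(coding, expressed_genes={"OTHER"})
        assert expressed.coding.item() == 1
        assert silent.coding.item() == 0
        assert silent.level.item() == "none"

    def test_driver_bonus_never_creates_score_from_nothing(self):
        hits = [EvidenceHit("v1", "G", "promoter", "promoter_histone")]
        out = score_targets(hits, driver_genes={"G"})
        assert out.distal.item() == 0 and out.coding.item() == 0

    evidence_strategy = st.lists(
        st.builds(
            EvidenceHit,
            variant_id=st.sampled_from(["v1", "v2", "v3"]),
            gene=st.sampled_from(["G1", "G2"]),
            category=st.just("ignored"),
            evidence_type=st.sampled_from(
                ["chia_pet_link", "hic_link", "computational_ep", "eqtl",
                 "enriched_feature", "promoter_histone", "missense", "nonsense",
                 "splice"]),
            signal=st.integers(1, 2),
        ).map(lambda h: EvidenceHit(
            h.variant_id, h.gene,
            {"chia_pet_link": "distal", "hic_link": "distal",
             "computational_ep": "distal", "eqtl": "distal",
             "enriched_feature": "distal", "promoter_histone": "promoter",
             "missense": "coding", "nonsense": "coding",
             "splice": "coding"}[h.evidence_type],
            h.evidence_type, h.signal)),
        max_size=25)

    @given(evidence_strategy, st.booleans(), st.booleans())
    def test_caps_never_exceeded(self, hits, driver, expressed):
        out = score_targets(hits, driver_genes={"G1"} if driver else set(),
                            expressed_genes={"G1", "G2"} if expressed else set())
        assert (out.distal <= CAPS["distal"]).all()
        assert (out.promoter <= CAPS["promoter"]).all()
        assert (out.coding <= CAPS["coding"]).all()
        assert (out[["distal", "promoter", "coding"]] >= 0).all().all()

    @given(evidence_strategy)
    def test_adding_evidence_is_monotone(self, hits):
        extra = EvidenceHit("vX", "G1", "distal", "chia_pet_link", 1)
        before = score_targets(hits, driver_genes=set(), expressed_genes=None)
        after = score_targets(hits + [extra], driver_genes=set(), expressed_genes=None)
        b = before[(before.gene == "G1") & (before.signal == 1)]
        a = after[(after.gene == "G1") & (after.signal == 1)]
        b_distal = b.distal.item() if len(b) else 0.0
        assert a.distal.item() >= b_distal
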