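import numpy as np
import pandas as pd
import pytest

from stratfdr.annotation import (
    GeneModel,
    LDNeighborhood,
    ReferencePanel,
    ScoringConfig,
    annotate_tag_snps,
    assign_positional_categories,
    assign_positional_category,
    compute_pairwise_ld,
    flag_intergenic,
    ld_weighted_scores,
    profiles_to_frame,
    qc_reference_panel,
)
from stratfdr.constants import CATEGORIES
from stratfdr import simulate as sim

from conftest import independent_neighborhoods


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _panel_from_dosages(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n_snps, n_ind = dosages.shape
    snps = pd.DataFrame({
        "snp": [f"s{i}" for i in range(n_snps)],
        "chrom": "1",
        "pos": 1000 * np.arange(1, n_snps + 1),
    })
    return ReferencePanel(snps, dosages, [f"i{j}" for j in range(n_ind)])


class TestQC:
    def test_low_maf_snp_removed(self):
        # 100 individuals; SNP 0 has one alt allele -> MAF 0.005 < 1%
        dosages = np.zeros((2, 100))
        dosages[0, 0] = 1.0
        dosages[1, :50] = 1.0
        out = qc_reference_panel(_panel_from_dosages(dosages))
        assert out.snps["snp"].tolist() == ["s1"]

    def test_high_missingness_snp_removed(self):
        # 50 SNPs so individual missingness stays under its 10% cut
        dosages = np.tile([0.0, 1.0], (50, 50))
        dosages[0, :6] = np.nan  # 6% missing > 5%
        out = qc_reference_panel(_panel_from_dosages(dosages))
        assert "s0" not in out.snps["snp"].tolist()
        assert out.n_snps == 49

    def test_high_missingness_individual_removed(self):
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(50, 20)).astype(float)
        dosages[:6, 0] = np.nan  # individual 0 missing 12% > 10%
        out = qc_reference_panel(
            _panel_from_dosages(dosages), hwe_p_min=0.0
        )
        assert out.n_individuals == 19
        assert "i0" not in out.individuals

    def test_clean_panel_unchanged(self):
        # MAF 0.3, no missingness, HWE-perfect genotype counts
        n = 100
        row = np.array([0.0] * 49 + [1.0] * 42 + [2.0] * 9)  # f = 0.3
        dosages = np.tile(row, (5, 1))
        panel = _panel_from_dosages(dosages)
        out = qc_reference_panel(panel)
        assert out.n_snps == 5 and out.n_individuals == n

    def test_hwe_violation_removed(self):
        # all hets at f=0.5: chi2 = n, p << 1e-6 at n=200
        bad = np.ones(200)
        good = np.array([0.0] * 50 + [1.0] * 100 + [2.0] * 50)
        out = qc_reference_panel(_panel_from_dosages([bad, good]))
        assert out.snps["snp"].tolist() == ["s1"]

    def test_error_names_filter(self):
        dosages = np.zeros((3, 100))
        dosages[:, 0] = 1.0  # all MAF 0.005
        with pytest.raises(ValueError, match="MAF"):
            qc_reference_panel(_panel_from_dosages(dosages))

    def test_empty_panel_rejected(self):
        panel = ReferencePanel(
            pd.DataFrame(columns=["snp", "chrom", "pos"]),
            np.empty((0, 3)), ["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="empty"):
            qc_reference_panel(panel)


# ---------------------------------------------------------------------------
# positional categories
# ---------------------------------------------------------------------------

class TestPositional:
    def test_exon_lookup(self, plus_gene):
        assert assign_positional_category("1", 1500, [plus_gene]) == "exon"

    def test_all_elements(self, plus_gene):
        for pos, want in [(1100, "utr5"), (3000, "intron"), (4200, "exon"),
                          (4700, "utr3")]:
            assert assign_positional_category("1", pos, [plus_gene]) == want

    def test_plus_strand_upstream(self):
        gene = GeneModel("g", "t", "1", "+", 5000, 6000)
        assert assign_positional_category("1", 4500, [gene]) == "1k_up"
        assert assign_positional_category("1", 3999, [gene]) == "10k_up"
        assert assign_positional_category("1", 6200, [gene]) == "1k_down"
        assert assign_positional_category("1", 8000, [gene]) == "10k_down"

    def test_minus_strand_upstream(self):
        gene = GeneModel("g", "t", "1", "-", 4000, 10_000)
        # transcription start is the high-coordinate end on '-'
        assert assign_positional_category("1", 10_500, [gene]) == "1k_up"
        assert assign_positional_category("1", 3500, [gene]) == "1k_down"

    def test_far_from_everything(self, plus_gene):
        assert assign_positional_category("1", 150_000, [plus_gene]) is None

    def test_other_chromosome(self, plus_gene):
        assert assign_positional_category("2", 1500, [plus_gene]) is None

    def test_precedence_resolves_overlap(self):
        g1 = GeneModel("g1", "t1", "1", "+", 100, 600,
                       elements=(("intron", 100, 600),))
        g2 = GeneModel("g2", "t2", "1", "+", 50, 700,
                       elements=(("utr5", 50, 700),))
        assert assign_positional_category("1", 300, [g1, g2]) == "utr5"

    def test_malformed_gene_rejected(self):
        with pytest.raises(ValueError, match="end <= start"):
            GeneModel("g", "t", "1", "+", 100, 600,
                      elements=(("exon", 500, 400),))

    def test_element_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GeneModel("g", "t", "1", "+", 100, 600,
                      elements=(("exon", 50, 200),))

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel("g", "t", "1", "+", 0, 1000,
                      elements=(("exon", 0, 500), ("intron", 400, 900)))


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

class TestPairwiseLD:
    def test_identical_dosages_r2_one(self, small_panel):
        nbs = compute_pairwise_ld(small_panel, ["s0"])
        assert nbs[0].partners["s1"] == pytest.approx(1.0)

    def test_self_pair_always_present(self, small_panel):
        for nb in compute_pairwise_ld(small_panel, ["s0", "s5"]):
            assert nb.partners[nb.tag] == 1.0

    def test_below_threshold_dropped(self):
        rng = np.random.default_rng(3)
        # two independent SNPs over many individuals: sample r^2 ~ 0
        dosages = rng.integers(0, 3, size=(2, 500)).astype(float)
        panel = _panel_from_dosages(dosages)
        nbs = compute_pairwise_ld(panel, ["s0"])
        assert "s1" not in nbs[0].partners

    def test_window_excludes_distant_pair(self):
        dosages = np.tile(
            np.random.default_rng(4).integers(0, 3, 50).astype(float), (2, 1)
        )
        snps = pd.DataFrame({
            "snp": ["a", "b"], "chrom": "1", "pos": [1, 1_200_002],
        })
        panel = ReferencePanel(snps, dosages, [f"i{j}" for j in range(50)])
        nbs = compute_pairwise_ld(panel, ["a"])
        assert "b" not in nbs[0].partners  # r^2=1 but 1.2 Mb away
        wide = compute_pairwise_ld(
            panel, ["a"], ScoringConfig(window=2_000_000)
        )
        assert wide[0].partners["b"] == pytest.approx(1.0)

    def test_monomorphic_partner_skipped(self, small_panel):
        nbs = compute_pairwise_ld(small_panel, ["s0"])
        assert "s9" not in nbs[0].partners
        # the monomorphic tag still gets its self pair
        nbs9 = compute_pairwise_ld(small_panel, ["s9"])
        assert nbs9[0].partners == {"s9": 1.0}

    def test_absent_tags_dropped(self, small_panel):
        nbs = compute_pairwise_ld(small_panel, ["s0", "nope"])
        assert [nb.tag for nb in nbs] == ["s0"]

    def test_missing_data_pairwise_complete(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=float)
        y = x.copy()
        y[0] = np.nan  # r^2 on complete pairs still 1
        panel = _panel_from_dosages([x, y])
        nbs = compute_pairwise_ld(panel, ["s0"])
        assert nbs[0].partners["s1"] == pytest.approx(1.0)

    def test_brute_force_additivity_oracle(self, block_panel):
        """Scores equal a double loop over all pairs on a <=50-SNP panel."""
        sub = ReferencePanel(
            block_panel.snps.iloc[:50].reset_index(drop=True),
            block_panel.dosages[:50], block_panel.individuals,
        )
        config = ScoringConfig()
        tags = sub.snps["snp"].tolist()
        positional = {s: "exon" for s in tags}  # everything one category
        nbs = compute_pairwise_ld(sub, tags, config)
        positions = dict(zip(sub.snps["snp"],
                             zip(sub.snps["chrom"], sub.snps["pos"])))
        profiles = ld_weighted_scores(nbs, positional, positions, config)
        # oracle: brute-force double loop
        dos = sub.dosages
        pos = sub.snps["pos"].to_numpy()
        for k, tag in enumerate(tags):
            expected = 0.0
            for j in range(len(tags)):
                if abs(pos[j] - pos[k]) > config.window:
                    continue
                if j == k:
                    expected += 1.0
                    continue
                r = np.corrcoef(dos[k], dos[j])[0, 1]
                if r * r >= config.r2_min:
                    expected += r * r
            assert profiles[k].scores["exon"] == pytest.approx(expected)

    def test_threshold_monotonicity(self, block_panel):
        """Raising r2_min never increases any category score."""
        tags = block_panel.snps["snp"].tolist()[:40]
        positional = {s: "intron" for s in block_panel.snps["snp"]}
        positions = dict(zip(block_panel.snps["snp"],
                             zip(block_panel.snps["chrom"],
                                 block_panel.snps["pos"])))
        lo = ld_weighted_scores(
            compute_pairwise_ld(block_panel, tags,
                                ScoringConfig(r2_min=0.2)),
            positional, positions,
        )
        hi = ld_weighted_scores(
            compute_pairwise_ld(block_panel, tags,
                                ScoringConfig(r2_min=0.5)),
            positional, positions,
        )
        for a, b in zip(lo, hi):
            for c in CATEGORIES:
                assert b.scores[c] <= a.scores[c] + 1e-12

    def test_alternate_config_dominates_default(self, block_panel):
        """r^2 > 0.05 within 2 Mb yields scores >= the default's."""
        tags = block_panel.snps["snp"].tolist()[:40]
        positional = {s: "intron" for s in block_panel.snps["snp"]}
        positions = dict(zip(block_panel.snps["snp"],
                             zip(block_panel.snps["chrom"],
                                 block_panel.snps["pos"])))
        default = ld_weighted_scores(
            compute_pairwise_ld(block_panel, tags, ScoringConfig()),
            positional, positions,
        )
        alternate = ld_weighted_scores(
            compute_pairwise_ld(
                block_panel, tags,
                ScoringConfig(r2_min=0.05, window=2_000_000),
            ),
            positional, positions,
        )
        for a, b in zip(default, alternate):
            for c in CATEGORIES:
                assert b.scores[c] >= a.scores[c] - 1e-12


# ---------------------------------------------------------------------------
# LD-weighted scores
# ---------------------------------------------------------------------------

POSITIONS = {s: ("1", i * 1000) for i, s in
             enumerate(["tag", "n1", "n2", "n3"])}


class TestScores:
    def test_direct_sum_example(self):
        nb = LDNeighborhood("tag", {
            "tag": 1.0, "n1": 0.5, "n2": 0.6, "n3": 0.25,
        })
        positional = {"tag": "exon", "n1": "intron", "n2": "intron",
                      "n3": "exon"}
        (pr,) = ld_weighted_scores([nb], positional, POSITIONS)
        assert pr.scores["exon"] == pytest.approx(1.25)
        assert pr.scores["intron"] == pytest.approx(1.10)
        assert pr.memberships["exon"] and pr.memberships["intron"]
        assert pr.total_ld == pytest.approx(2.35)
        assert pr.n_tagged == 4

    def test_no_neighbors_self_category_only(self):
        nb = LDNeighborhood("tag", {"tag": 1.0})
        (pr,) = ld_weighted_scores([nb], {"tag": "utr3"}, POSITIONS)
        assert pr.scores["utr3"] == 1.0
        members = [c for c, m in pr.memberships.items() if m]
        assert members == ["utr3"]

    def test_score_below_threshold_no_membership(self):
        nb = LDNeighborhood("tag", {"tag": 1.0, "n1": 0.9})
        positional = {"tag": None, "n1": "intron"}
        (pr,) = ld_weighted_scores([nb], positional, POSITIONS)
        assert pr.scores["intron"] == pytest.approx(0.9)
        assert not any(pr.memberships.values())

    def test_missing_self_pair_rejected(self):
        nb = LDNeighborhood("tag", {"n1": 0.5})
        with pytest.raises(ValueError, match="self pair"):
            ld_weighted_scores([nb], {"n1": "exon"}, POSITIONS)

    def test_genic_tag_is_member_of_own_category(self, annotated_track):
        """Self term r^2=1.0 >= threshold forces own-category membership."""
        _, _, frame = annotated_track
        genic = frame[frame["category"].notna()]
        assert len(genic) > 50
        for _, row in genic.iterrows():
            assert row[f"member_{row['category']}"] == 1

    def test_score_bounded_by_total_ld(self, annotated_track):
        _, _, frame = annotated_track
        for c in CATEGORIES:
            assert (frame[f"score_{c}"] <= frame["total_ld"] + 1e-9).all()


# ---------------------------------------------------------------------------
# intergenic flag
# ---------------------------------------------------------------------------

def _lonely_profile(positions, genes, masks=None):
    nb = LDNeighborhood("t", {"t": 1.0})
    profiles = ld_weighted_scores([nb], {"t": None}, positions)
    return flag_intergenic(profiles, [nb], genes, positions, masks=masks)[0]


class TestIntergenic:
    def test_far_snp_is_intergenic(self, plus_gene):
        pr = _lonely_profile({"t": ("1", 600_000)}, [plus_gene], masks=[[]])
        assert pr.intergenic

    def test_partner_near_gene_blocks_flag(self, plus_gene):
        # partner 50 kb from the gene => not intergenic
        nb = LDNeighborhood("t", {"t": 1.0, "u": 0.5})
        positions = {"t": ("1", 600_000), "u": ("1", 55_000)}
        profiles = ld_weighted_scores([nb], {"t": None, "u": None}, positions)
        out = flag_intergenic(profiles, [nb], [plus_gene], positions,
                              masks=[[]])
        assert not out[0].intergenic

    def test_mask_hit_blocks_flag(self, plus_gene):
        masks = [[("1", 590_000, 610_000)]]  # e.g. a noncoding RNA
        pr = _lonely_profile({"t": ("1", 600_000)}, [plus_gene], masks=masks)
        assert not pr.intergenic

    def test_member_snp_never_intergenic(self, annotated_track):
        _, _, frame = annotated_track
        members = frame[[f"member_{c}" for c in CATEGORIES]].sum(axis=1) > 0
        assert not (members & (frame["intergenic"] == 1)).any()

    def test_intergenic_scores_all_zero(self, annotated_track):
        _, _, frame = annotated_track
        inter = frame[frame["intergenic"] == 1]
        assert len(inter) > 0
        assert (inter[[f"score_{c}" for c in CATEGORIES]].to_numpy()
                == 0).all()

    def test_missing_masks_warns(self, plus_gene, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="stratfdr.annotation"):
            _lonely_profile({"t": ("1", 600_000)}, [plus_gene], masks=None)
        assert any("mask" in r.message for r in caplog.records)


def test_annotate_tag_snps_roundtrip(annotated_track):
    panel, genes, frame = annotated_track
    assert len(frame) == panel.n_snps
    assert frame["total_ld"].min() >= 1.0  # self term
    assert (frame["n_tagged"] >= 1).all()
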