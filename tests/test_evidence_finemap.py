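"""LD statistics, proxy-SNP search, fine-mapping and LD-block partition."""

import numpy as np
import pytest

from ppimod.evidence_finemap import (
    GeneLocus,
    HaplotypePanel,
    finemap_candidates,
    ld_blocks,
    ld_statistics,
    proxy_snps,
    read_haplotype_tsv,
    read_haplotype_vcf,
    read_loci_table,
)
from ppimod.seed_protomodule import AssociationRecord


def panel_from_columns(cols: dict, positions=None, chrom="chr1"):
    ids = list(cols)
    alleles = np.column_stack([np.asarray(cols[s], dtype=np.int8) for s in ids])
    pos = positions or list(range(1000, 1000 + 1000 * len(ids), 1000))
    return HaplotypePanel(
        snp_ids=ids, chroms=[chrom] * len(ids), positions=np.array(pos), alleles=alleles
    )


def counts_panel(n_ab, n_aB, n_Ab, n_ab0):
    """Panel with two SNPs from explicit two-locus haplotype counts."""
    a = [1] * n_ab + [1] * n_Ab + [0] * n_aB + [0] * n_ab0
    b = [1] * n_ab + [0] * n_Ab + [1] * n_aB + [0] * n_ab0
    return panel_from_columns({"A": a, "B": b})


class TestLDStatistics:
    def test_identical_columns_perfect_ld(self):
        col = [0, 1] * 50
        res = ld_statistics(panel_from_columns({"A": col, "B": col}), "A", "B")
        assert res.r2 == pytest.approx(1.0) and res.d_prime == pytest.approx(1.0)

    def test_closed_form_from_haplotype_counts(self):
        # pA = pB = 0.5, pAB = 0.35 over 100 haplotypes
        res = ld_statistics(counts_panel(35, 15, 15, 35), "A", "B")
        assert res.r2 == pytest.approx(0.16, abs=1e-12)
        assert res.d_prime == pytest.approx(0.4, abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.random(10_000) < 0.5).astype(int)
        b = (rng.random(10_000) < 0.5).astype(int)
        res = ld_statistics(panel_from_columns({"A": a, "B": b}), "A", "B")
        assert res.r2 < 0.01

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = (rng.random(400) < rng.uniform(0.2, 0.8)).astype(int)
            b = np.where(rng.random(400) < 0.3, 1 - a, a)
            if a.min() == a.max() or b.min() == b.max():
                continue
            base = ld_statistics(panel_from_columns({"A": a, "B": b}), "A", "B")
            flipped = ld_statistics(panel_from_columns({"A": 1 - a, "B": b}), "A", "B")
            both = ld_statistics(panel_from_columns({"A": 1 - a, "B": 1 - b}), "A", "B")
            assert flipped.r2 == pytest.approx(base.r2, abs=1e-12)
            assert flipped.d_prime == pytest.approx(base.d_prime, abs=1e-12)
            assert both.r2 == pytest.approx(base.r2, abs=1e-12)
            assert both.d_prime == pytest.approx(base.d_prime, abs=1e-12)

    def test_monomorphic_snp_named_in_error(self):
        panel = panel_from_columns({"A": [1] * 10, "B": [0, 1] * 5})
        with pytest.raises(ValueError, match="A"):
            ld_statistics(panel, "A", "B")

    def test_cross_chromosome_rejected(self):
        panel = HaplotypePanel(
            snp_ids=["A", "B"],
            chroms=["chr1", "chr2"],
            positions=np.array([100, 100]),
            alleles=np.array([[0, 1], [1, 0], [0, 0], [1, 1]], dtype=np.int8),
        )
        with pytest.raises(ValueError, match="different chromosomes"):
            ld_statistics(panel, "A", "B")


class TestProxySnps:
    def test_threshold_one_keeps_only_perfect_proxies(self):
        col = [0, 1, 1, 0] * 25
        other = [0, 1, 0, 1] * 25
        panel = panel_from_columns({"I": col, "P": col, "X": other})
        out = proxy_snps(panel, ["I"], r2_threshold=1.0)
        assert out["I"] == {"I", "P"}

    def test_window_excludes_distant_perfect_proxy(self):
        col = [0, 1] * 50
        panel = panel_from_columns(
            {"I": col, "FAR": col}, positions=[1000, 800_000]
        )
        assert proxy_snps(panel, ["I"], window=500_000)["I"] == {"I"}

    def test_absent_index_snp_skipped(self):
        panel = panel_from_columns({"A": [0, 1] * 10})
        assert proxy_snps(panel, ["MISSING"]) == {}

    def test_shrinks_as_threshold_rises(self, small_cfg):
        from ppimod.synthetic_data import generate_bundle

        panel = generate_bundle(small_cfg).panel
        idx = [panel.snp_ids[0]]
        sizes = [
            len(proxy_snps(panel, idx, r2_threshold=t)[idx[0]])
            for t in (0.2, 0.5, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_block_recovered_at_default_threshold(self, small_cfg):
        from ppimod.synthetic_data import generate_bundle

        bundle = generate_bundle(small_cfg)
        panel = bundle.panel
        first_block = [s for s in panel.snp_ids if s.startswith("rs000_")]
        out = proxy_snps(panel, [first_block[0]], r2_threshold=0.8)
        assert set(first_block) <= out[first_block[0]]


class TestFinemap:
    def locus(self):
        return GeneLocus("GENE1", "chr1", 900, 1_100)

    def assoc(self, p):
        return AssociationRecord(
            gene="X", source="gwas", snp_id="I", chrom="chr1", pos=1000, p_value=p
        )

    def test_signal_inside_gene_body_kept_at_5e4(self):
        panel = panel_from_columns({"I": [0, 1] * 50}, positions=[1000])
        out = finemap_candidates([self.locus()], [self.assoc(5e-4)], panel)
        assert out == {"GENE1"}

    def test_sub_threshold_signal_excluded_at_2e3(self):
        panel = panel_from_columns({"I": [0, 1] * 50}, positions=[1000])
        out = finemap_candidates([self.locus()], [self.assoc(2e-3)], panel)
        assert out == set()

    def test_p_max_zero_returns_empty(self):
        panel = panel_from_columns({"I": [0, 1] * 50}, positions=[1000])
        assert finemap_candidates([self.locus()], [self.assoc(1e-8)], panel, p_max=0) == set()

    def test_gene_reached_only_through_ld_proxy(self):
        col = [0, 1] * 50
        panel = panel_from_columns({"P": col, "I": col}, positions=[1000, 5000])
        # index SNP at 5000 is outside the locus; its perfect proxy at 1000 is inside
        out = finemap_candidates([self.locus()], [self.assoc(5e-4)], panel)
        assert out == {"GENE1"}

    def test_planted_genes_recovered_exactly(self, pipeline, truth):
        assert pipeline.stream_gwas == set(truth.stream_gwas)


class TestLDBlocks:
    def test_two_perfect_triplets_split_by_independent_snp(self):
        rng = np.random.default_rng(5)
        t1 = (rng.random(600) < 0.5).astype(int)
        mid = (rng.random(600) < 0.5).astype(int)
        t2 = (rng.random(600) < 0.5).astype(int)
        panel = panel_from_columns(
            {"A1": t1, "A2": t1, "A3": t1, "M": mid, "B1": t2, "B2": t2, "B3": t2}
        )
        assert ld_blocks(panel) == [(0, 3), (4, 7)]

    def test_independent_snps_form_no_blocks(self):
        rng = np.random.default_rng(6)
        cols = {f"S{i}": (rng.random(800) < 0.5).astype(int) for i in range(5)}
        assert ld_blocks(panel_from_columns(cols)) == []

    def test_single_snp_chromosome_no_blocks(self):
        assert ld_blocks(panel_from_columns({"A": [0, 1] * 10})) == []


class TestPanelIO:
    def test_tsv_roundtrip(self, scenario_dir):
        panel = read_haplotype_tsv(
            scenario_dir / "haplotypes.tsv", scenario_dir / "snp_map.tsv"
        )
        assert panel.n_snps > 0 and set(np.unique(panel.alleles)) <= {0, 1}

    def test_vcf_parsing_matches_tsv(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        body = (
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|0\n"
            "chr1\t300\trs3\tC\tT,G\t.\tPASS\t.\tGT\t0|0\t0|0\n"
        )
        f = tmp_path / "panel.vcf"
        f.write_text(header + body)
        panel, rejected = read_haplotype_vcf(f)
        assert rejected == 1
        assert panel.snp_ids == ["rs1", "rs2"]
        assert panel.column("rs1").tolist() == [0, 1, 1, 1]

    def test_loci_table_is_one_based_inclusive(self, tmp_path):
        f = tmp_path / "loci.tsv"
        f.write_text("chrom\tstart_1based\tend\tgene\nchr1\t10\t20\tg1\n")
        (locus,) = read_loci_table(f)
        assert locus.contains("chr1", 10) and locus.contains("chr1", 20)
        assert not locus.contains("chr1", 21)
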