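"""Regulatory-variant pool, mutual-rank coexpression and shared regulators."""

import numpy as np
import pandas as pd
import pytest

from ppimod.evidence_regulation import (
    ExpressionMatrix,
    GeneSetCollection,
    coexpressed_with_seeds,
    mutual_rank_pairs,
    regulation_candidates,
    regulome_pool,
    shared_regulator_candidates,
)
from ppimod.seed_protomodule import SeedSet


def expr_from(values: dict, n_samples=None) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(values, orient="index")
    return ExpressionMatrix(df)


def brute_force_mutual_pairs(x: np.ndarray, genes, top_k):
    """Double-loop oracle: rank partners per gene, intersect top lists."""
    corr = np.corrcoef(np.log1p(x))
    pairs = set()
    for i, a in enumerate(genes):
        for j, b in enumerate(genes):
            if i == j:
                continue
            order_i = sorted(
                (k for k in range(len(genes)) if k != i),
                key=lambda k: -corr[i, k],
            )
            order_j = sorted(
                (k for k in range(len(genes)) if k != j),
                key=lambda k: -corr[j, k],
            )
            cut_i = corr[i, order_i[top_k - 1]]
            cut_j = corr[j, order_j[top_k - 1]]
            if corr[i, j] >= cut_i and corr[j, i] >= cut_j:
                pairs.add((a, b))
    return pairs


class TestRegulomePool:
    def test_category_one_kept_others_dropped(self):
        flags = {"A": "1f", "B": "2b"}
        assert regulome_pool({"A", "B"}, flags) == {"A"}

    def test_empty_flag_table(self):
        assert regulome_pool({"A"}, {}) == set()

    def test_unknown_category_rejected_with_rows(self):
        with pytest.raises(ValueError, match="ZZ"):
            regulome_pool({"A"}, {"A": "ZZ"})

    def test_planted_category_one_genes_recovered(self, scenario_dir, truth, small_cfg):
        from ppimod.evidence_regulation import read_flag_table

        flags = read_flag_table(scenario_dir / "regulome_flags.tsv")
        planted = set(truth.stream_gwas[: small_cfg.n_regulome_planted])
        pool = regulome_pool(set(flags), flags)
        assert pool == planted


class TestMutualRank:
    def test_identical_profiles_are_mutual(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(5, 1, 50)
        values = {f"N{i}": rng.normal(5, 1, 50) for i in range(20)}
        values["A"] = shared
        values["B"] = shared + rng.normal(0, 1e-3, 50)
        expr = expr_from(values)
        pairs = mutual_rank_pairs(expr, {"A"}, {"B"}, top_fraction=0.06)
        assert ("A", "B") in pairs

    def test_mutuality_is_required(self):
        # A's profile is close to the hub H, but H is even closer to B
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 60)
        values = {
            "H": np.exp(base),
            "B": np.exp(base + rng.normal(0, 0.01, 60)),
            "A": np.exp(base + rng.normal(0, 0.5, 60)),
        }
        values.update({f"N{i}": np.exp(rng.normal(0, 1, 60)) for i in range(40)})
        expr = expr_from(values)
        # top list of size 1: H's single slot is taken by B
        pairs = mutual_rank_pairs(expr, {"A"}, {"H"}, top_fraction=0.02)
        assert ("A", "H") not in pairs

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i:02d}" for i in range(30)]
        x = np.exp(rng.normal(0, 1, (30, 40)))
        for i in range(0, 9, 3):  # three correlated triplets
            x[i + 1] = x[i] * np.exp(rng.normal(0, 0.05, 40))
            x[i + 2] = x[i] * np.exp(rng.normal(0, 0.05, 40))
        expr = expr_from(dict(zip(genes, x)))
        top_k = int(np.ceil(0.1 * 29))
        oracle = brute_force_mutual_pairs(x, genes, top_k)
        pairs = mutual_rank_pairs(expr, set(genes), set(genes), top_fraction=0.1)
        assert pairs == oracle

    def test_symmetric_and_monotone_in_top_fraction(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i:02d}" for i in range(25)]
        expr = expr_from({g: np.exp(rng.normal(0, 1, 30)) for g in genes})
        wide = mutual_rank_pairs(expr, set(genes), set(genes), top_fraction=0.3)
        narrow = mutual_rank_pairs(expr, set(genes), set(genes), top_fraction=0.1)
        assert {(b, a) for a, b in wide} == wide
        assert narrow <= wide

    def test_constant_gene_excluded(self, caplog):
        rng = np.random.default_rng(4)
        values = {f"N{i}": rng.normal(5, 1, 20) for i in range(10)}
        values["FLAT"] = np.ones(20)
        expr = expr_from(values)
        pairs = mutual_rank_pairs(expr, {"FLAT"}, set(values), top_fraction=0.3)
        assert not any("FLAT" in p for p in pairs)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(15)]
        x = np.exp(rng.normal(0, 1, (15, 24)))
        expr = expr_from(dict(zip(genes, x)))
        perm = rng.permutation(24)
        expr_p = expr_from(dict(zip(genes, x[:, perm])))
        assert mutual_rank_pairs(expr, set(genes), set(genes), 0.2) == mutual_rank_pairs(
            expr_p, set(genes), set(genes), 0.2
        )


class TestCoexpressedWithSeeds:
    def test_three_seed_pairs_required(self, pipeline, truth):
        groups = truth.coexpr_groups
        from ppimod.evidence_regulation import ExpressionMatrix

        expr = ExpressionMatrix.from_tsv(pipeline.cfg.expression)
        seeds = SeedSet(genes=set(truth.seeds))
        out = coexpressed_with_seeds(
            expr, pipeline.candidate_universe, seeds,
            min_seeds=3, top_fraction=pipeline.cfg.top_fraction,
        )
        planted = {g for grp in groups for g in grp["candidates"]}
        assert planted <= out

    def test_two_seeds_insufficient(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(0, 1, 80)
        values = {
            g: np.exp(np.sqrt(0.9) * factor + np.sqrt(0.1) * rng.normal(0, 1, 80))
            for g in ("C", "S1", "S2")
        }
        values.update({f"N{i}": np.exp(rng.normal(0, 1, 80)) for i in range(30)})
        expr = expr_from(values)
        seeds = SeedSet(genes={"S1", "S2"})
        out = coexpressed_with_seeds(expr, {"C"}, seeds, min_seeds=3, top_fraction=0.1)
        assert out == set()


class TestSharedRegulators:
    def test_set_with_three_seeds_qualifies_candidate(self):
        coll = GeneSetCollection(sets={"TFT1": {"C", "S1", "S2", "S3"}})
        out = shared_regulator_candidates(coll, {"C"}, SeedSet(genes={"S1", "S2", "S3"}))
        assert out == {"C"}

    def test_seeds_not_pooled_across_sets(self):
        coll = GeneSetCollection(
            sets={"T1": {"C", "S1"}, "T2": {"C", "S2"}, "T3": {"C", "S3"}}
        )
        out = shared_regulator_candidates(coll, {"C"}, SeedSet(genes={"S1", "S2", "S3"}))
        assert out == set()


class TestRegulationCandidates:
    def test_coexpression_needs_shared_regulator(self):
        assert regulation_candidates(set(), {"A"}, set(), set()) == set()
        assert regulation_candidates(set(), {"A"}, {"A"}, set()) == {"A"}
        assert regulation_candidates(set(), {"A"}, set(), {"A"}) == {"A"}

    def test_pool_union_nonredundant(self):
        out = regulation_candidates({"A"}, {"A"}, {"A"}, set())
        assert out == {"A"}

    def test_empty_pool1_result_subset_of_coexpression(self):
        out = regulation_candidates(set(), {"A", "B"}, {"B", "C"}, {"D"})
        assert out <= {"A", "B"}
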