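import itertools
from fractions import Fraction

import numpy as np
import pytest

from netepi import (
    GeneNetwork,
    GeneModel,
    SnpModel,
    SnpGeneMap,
    MappingEntry,
    QCConfig,
    GenotypeDataset,
    SnpRecord,
    ValidationError,
    filter_gene_models,
    combine_mappings,
    enumerate_snp_models,
    snp_maf,
    hwe_exact_test,
    pairwise_r2,
    apply_snp_model_qc,
)
from netepi.io_formats import MISSING


# --- independent oracle: exact HWE test with rational arithmetic -----------

def hwe_oracle(n_hom_a1, n_het, n_hom_a2):
    """Exact-rational enumeration over heterozygote counts, written against
    the conditional distribution of the het count given the allele counts."""
    n = n_hom_a1 + n_het + n_hom_a2
    n_a1 = 2 * n_hom_a1 + n_het
    n_a2 = 2 * n_hom_a2 + n_het
    rare = min(n_a1, n_a2)
    if rare == 0:
        return Fraction(1)

    def fact(k):
        out = 1
        for i in range(2, k + 1):
            out *= i
        return out

    probs = {}
    total = Fraction(0)
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        w = Fraction(fact(n) * 2 ** h, fact(hom_rare) * fact(h) * fact(hom_common))
        probs[h] = w
        total += w
    p_obs = probs[n_het]
    return sum(w for w in probs.values() if w <= p_obs) / total


def _network(rows):
    net = GeneNetwork()
    for a, b, ev in rows:
        net.add_edge(a, b, ev)
    return net


def _mapping(pairs, source="positional"):
    return SnpGeneMap({MappingEntry(s, g, source) for s, g in pairs})


def _dataset(columns, positions=None, chroms=None):
    columns = np.array(columns, dtype=np.int8).T
    n, m = columns.shape
    snps = [
        SnpRecord(f"rs{j+1}", (chroms or ["1"] * m)[j], (positions or [(j + 1) * 1000] * 1)[j]
                  if positions else (j + 1) * 1000)
        for j in range(m)
    ]
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        snps=snps,
        genotypes=columns,
        phenotype=np.zeros(n, dtype=np.int8),
    )


class TestFilterGeneModels:
    def test_threshold_and_self_loop_removal(self):
        net = _network([("A", "B", 2), ("A", "C", 1), ("B", "C", 3), ("D", "D", 5)])
        assert [m.pair for m in filter_gene_models(net)] == [("A", "B"), ("B", "C")]

    def test_min_evidence_one_keeps_all_proper_edges(self):
        net = _network([("A", "B", 2), ("A", "C", 1), ("B", "C", 3)])
        assert [m.pair for m in filter_gene_models(net, min_evidence=1)] == [
            ("A", "B"), ("A", "C"), ("B", "C")]

    def test_empty_network(self):
        assert filter_gene_models(GeneNetwork()) == []


class TestCombineMappings:
    def test_union_projects_to_expected_relation(self):
        m1 = _mapping([("s1", "G1")], "positional")
        m2 = _mapping([("s1", "G1"), ("s2", "G2")], "eqtl")
        combined = combine_mappings([m1, m2])
        assert combined.project() == {("s1", "G1"), ("s2", "G2")}

    def test_idempotent(self):
        m = _mapping([("s1", "G1"), ("s2", "G2")])
        assert combine_mappings([m, m]).entries == m.entries

    def test_tissue_filter(self):
        entries = {
            MappingEntry("s1", "G1", "eqtl", "colon"),
            MappingEntry("s2", "G1", "eqtl", "blood"),
        }
        out = combine_mappings([SnpGeneMap(entries)], tissues={"colon"})
        assert {e.snp_id for e in out.entries} == {"s1"}

    def test_absent_source_warns(self):
        with pytest.warns(UserWarning, match="chromatin"):
            combine_mappings([_mapping([("s1", "G1")])], sources={"positional", "chromatin"})


class TestEnumerateSnpModels:
    def test_cross_product_with_shared_snp(self):
        mapping = _mapping([("s1", "A"), ("s2", "A"), ("s2", "B"), ("s3", "B")])
        models, childless = enumerate_snp_models([GeneModel("A", "B")], mapping)
        assert {m.pair for m in models} == {("s1", "s2"), ("s1", "s3"), ("s2", "s3")}
        assert childless == []

    def test_shared_pair_records_both_parents(self):
        mapping = _mapping([("s1", "A"), ("s5", "B"), ("s1", "C"), ("s5", "D")])
        gms = [GeneModel("A", "B"), GeneModel("C", "D")]
        models, _ = enumerate_snp_models(gms, mapping)
        assert len(models) == 1
        assert models[0].parent_gene_models == set(gms)

    def test_gene_without_snps_yields_no_pairs(self):
        mapping = _mapping([("s1", "A")])
        models, childless = enumerate_snp_models([GeneModel("A", "B")], mapping)
        assert models == [] and [g.pair for g in childless] == [("A", "B")]

    def test_count_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_genes = rng.integers(2, 6)
            genes = [f"G{i}" for i in range(n_genes)]
            snps = [f"s{i}" for i in range(rng.integers(2, 10))]
            rel = {(s, g) for s in snps for g in genes if rng.random() < 0.4}
            gms = [GeneModel(a, b) for a, b in itertools.combinations(genes, 2)
                   if rng.random() < 0.6]
            models, _ = enumerate_snp_models(gms, SnpGeneMap(
                {MappingEntry(s, g, "positional") for s, g in rel}))
            brute = set()
            for gm in gms:
                for a, ga in rel:
                    for b, gb in rel:
                        if ga == gm.gene_a and gb == gm.gene_b and a != b:
                            brute.add(tuple(sorted((a, b))))
            assert {m.pair for m in models} == brute


class TestSnpMaf:
    @pytest.mark.parametrize("col,expected", [
        ([0, 0, 1, 2, 2, 1], 0.5),
        ([0, 2, MISSING, 1], 0.5),
        ([0, 0, 0, 1], 0.125),
    ])
    def test_examples(self, col, expected):
        assert snp_maf(np.array(col)) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            snp_maf(np.array([MISSING, MISSING]))


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_hand_tables_match_oracle(self):
        for table in [(25, 50, 25), (50, 0, 50), (10, 5, 1), (3, 3, 3), (0, 1, 0)]:
            assert hwe_exact_test(*table) == pytest.approx(
                float(hwe_oracle(*table)), abs=1e-12)

    def test_complete_het_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-3

    def test_oracle_sweep_small_tables(self):
        """Agreement with the exact-rational oracle over all tables with n <= 12
        and a grid of larger ones up to n = 200."""
        for n in range(1, 13):
            for n2 in range(n + 1):
                for n1 in range(n - n2 + 1):
                    table = (n2, n1, n - n2 - n1)
                    assert hwe_exact_test(*table) == pytest.approx(
                        float(hwe_oracle(*table)), abs=1e-12), table
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(13, 201))
            n2 = int(rng.integers(0, n + 1))
            n1 = int(rng.integers(0, n - n2 + 1))
            table = (n2, n1, n - n2 - n1)
            assert hwe_exact_test(*table) == pytest.approx(
                float(hwe_oracle(*table)), abs=1e-12), table

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)


class TestPairwiseR2:
    def test_identical_columns(self):
        g = np.array([0, 1, 2, 1, 0])
        assert pairwise_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        g = np.array([0, 1, 2, 1, 0])
        assert pairwise_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=10000)
        b = rng.integers(0, 3, size=10000)
        assert pairwise_r2(a, b) < 0.01

    def test_monomorphic_returns_none(self):
        assert pairwise_r2(np.zeros(10, dtype=int), np.arange(10) % 3) is None


class TestApplySnpModelQc:
    @staticmethod
    def _qc_dataset():
        rng = np.random.default_rng(3)
        n = 400
        common = rng.binomial(2, 0.3, size=(n, 2))
        rare = rng.binomial(2, 0.01, size=(n, 1))
        cols = np.column_stack([common, rare]).astype(np.int8)
        return GenotypeDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            snps=[SnpRecord("rs1", "1", 1000), SnpRecord("rs2", "1", 2000),
                  SnpRecord("rs3", "1", 3000)],
            genotypes=cols,
            phenotype=np.zeros(n, dtype=np.int8),
        )

    def test_rare_snp_dropped_with_rule_maf(self):
        ds = self._qc_dataset()
        kept, log = apply_snp_model_qc([SnpModel("rs1", "rs3")], ds, QCConfig())
        assert kept == []
        assert log[0][:3] == ("rs1", "rs3", "maf")

    def test_whitelisted_rare_snp_retained(self):
        ds = self._qc_dataset()
        kept, _ = apply_snp_model_qc(
            [SnpModel("rs1", "rs3")], ds, QCConfig(whitelist={"rs3"}))
        assert [m.pair for m in kept] == [("rs1", "rs3")]

    def test_ld_rule_strict_inequality(self):
        n = 200
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.4, size=n).astype(np.int8)
        ds = GenotypeDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            snps=[SnpRecord("rs1", "1", 1000), SnpRecord("rs2", "1", 2000)],
            genotypes=np.column_stack([a, a]),
            phenotype=np.zeros(n, dtype=np.int8),
        )
        kept, log = apply_snp_model_qc([SnpModel("rs1", "rs2")], ds, QCConfig())
        assert kept == [] and log[0][2] == "ld" and log[0][3] == pytest.approx(1.0)
        # exact boundary r2 == threshold is retained
        kept2, _ = apply_snp_model_qc([SnpModel("rs1", "rs2")], ds,
                                      QCConfig(ld_r2_max=0.999999999))
        assert kept2 == []  # r2 = 1 > anything < 1
        kept3, _ = apply_snp_model_qc(
            [SnpModel("rs1", "rs2")], ds, QCConfig(ld_r2_max=0.9999999999999999))
        assert kept3 == []

    def test_hla_rule_requires_both_snps_inside(self):
        rng = np.random.default_rng(5)
        n = 300
        cols = rng.binomial(2, 0.3, size=(n, 3)).astype(np.int8)
        ds = GenotypeDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            snps=[SnpRecord("rs1", "6", 26_000_000), SnpRecord("rs2", "6", 27_000_000),
                  SnpRecord("rs3", "1", 1000)],
            genotypes=cols,
            phenotype=np.zeros(n, dtype=np.int8),
        )
        qc = QCConfig(hla_region=("6", 25_000_000, 34_000_000))
        kept, log = apply_snp_model_qc(
            [SnpModel("rs1", "rs2"), SnpModel("rs1", "rs3")], ds, qc)
        assert [m.pair for m in kept] == [("rs1", "rs3")]
        assert log[0][2] == "hla"

    def test_qc_is_order_independent(self):
        ds = self._qc_dataset()
        models = [SnpModel("rs1", "rs2"), SnpModel("rs1", "rs3"), SnpModel("rs2", "rs3")]
        kept_fwd, _ = apply_snp_model_qc(models, ds, QCConfig())
        kept_rev, _ = apply_snp_model_qc(models[::-1], ds, QCConfig())
        assert [m.pair for m in kept_fwd] == [m.pair for m in kept_rev]

    def test_filtering_monotone_in_thresholds(self):
        ds = self._qc_dataset()
        models = [SnpModel("rs1", "rs2"), SnpModel("rs1", "rs3"), SnpModel("rs2", "rs3")]
        strict, _ = apply_snp_model_qc(models, ds, QCConfig(maf_min=0.05, hwe_alpha=0.01))
        relaxed, _ = apply_snp_model_qc(models, ds, QCConfig(maf_min=0.005, hwe_alpha=0.0001))
        assert {m.pair for m in strict} <= {m.pair for m in relaxed}


class TestModelTypes:
    def test_gene_model_sorts_ids_and_rejects_self_pair(self):
        gm = GeneModel("B", "A")
        assert gm.pair == ("A", "B")
        with pytest.raises(ValidationError):
            GeneModel("A", "A")

    def test_snp_model_sorts_ids(self):
        assert SnpModel("s2", "s1").pair == ("s1", "s2")
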