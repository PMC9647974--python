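import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metahic import (
    ContactMatrix, EQTLTable, GeneNetwork, GenomicVariant, InvalidInputError,
    UndefinedAUCError, auroc, candidate_genes, contact_coexpression,
    contact_eqtl, filter_eqtls, make_bins, proximity_eqtl, unit_coexpression,
)
from metahic.structure import CategoricalAssignment, shared_unit_network
from conftest import random_symmetric_network


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    tot = 0.0
    for p in pos:
        for q in neg:
            tot += 1.0 if p > q else (0.5 if p == q else 0.0)
    return tot / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((3, 1, 2), (1, 0, 0), 1.0),
            ((1, 2, 3), (1, 0, 0), 0.0),
            ((2, 2, 1), (1, 0, 0), 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_undefined_without_both_classes(self):
        with pytest.raises(UndefinedAUCError):
            auroc([1, 2], [1, 1])
        with pytest.raises(UndefinedAUCError):
            auroc([1, 2], [0, 0])

    @given(
        scores=st.lists(st.integers(0, 5), min_size=2, max_size=12),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_pair_counting(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(
        scores=st.lists(st.integers(-100, 100), min_size=3, max_size=10),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_complement_and_monotone_invariance(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        scores = np.array(scores, dtype=float)
        a = auroc(scores, labels)
        assert a + auroc(-scores, labels) == pytest.approx(1.0, abs=1e-12)
        assert auroc(np.exp(scores / 25), labels) == pytest.approx(a, abs=1e-12)


class TestContactCoexpression:
    def test_worked_four_gene_case(self):
        """coexp (h:0.9, i:0.2, j:0.1) with k=1 labels h; hic (h:5, i:7, j:1)
        ranks h second of three -> AUC 0.5."""
        ids = np.array(["g", "h", "i", "j"], dtype=object)
        coexp = np.full((4, 4), np.nan)
        coexp[0, 1:] = coexp[1:, 0] = [0.9, 0.2, 0.1]
        coexp[1, 2] = coexp[2, 1] = 0.05
        coexp[1, 3] = coexp[3, 1] = 0.04
        coexp[2, 3] = coexp[3, 2] = 0.03
        hic = np.full((4, 4), np.nan)
        hic[0, 1:] = hic[1:, 0] = [5.0, 7.0, 1.0]
        hic[1, 2] = hic[2, 1] = 0.1
        hic[1, 3] = hic[3, 1] = 0.2
        hic[2, 3] = hic[3, 2] = 0.3
        res = contact_coexpression(
            GeneNetwork(gene_ids=ids, weights=hic),
            GeneNetwork(gene_ids=ids, weights=coexp),
            fraction=0.01,
        )
        assert res.per_entity["g"] == pytest.approx(0.5)

    def test_identical_ranking_is_perfect(self):
        net = random_symmetric_network(120, seed=5)
        copy = GeneNetwork(gene_ids=net.gene_ids.copy(), weights=net.weights.copy())
        res = contact_coexpression(copy, net, fraction=0.01)
        assert res.mean_auc == 1.0 and res.n_scored == 120

    def test_independent_networks_are_null(self):
        coexp = random_symmetric_network(300, seed=1)
        hic = random_symmetric_network(300, seed=2)
        res = contact_coexpression(hic, coexp, fraction=0.01)
        assert res.mean_auc == pytest.approx(0.5, abs=0.03)

    def test_restricted_to_common_genes(self):
        a = random_symmetric_network(30, seed=1)
        b = random_symmetric_network(40, seed=2)  # superset of ids g0000..g0029
        res = contact_coexpression(a, b)
        assert res.n_scored + len(res.skipped) == 30


class TestUnitCoexpression:
    def test_single_unit_all_ties_gives_half(self):
        coexp = random_symmetric_network(30, seed=3)
        asn = CategoricalAssignment("e1", {g: "A" for g in coexp.gene_ids})
        shared = shared_unit_network([asn], coexp.gene_ids)
        res = unit_coexpression(shared, coexp, fraction=0.05)
        assert set(res.per_entity.values()) == {0.5}

    def test_gene_with_no_support_skipped(self):
        coexp = random_symmetric_network(10, seed=4)
        labels = {g: "A" for g in coexp.gene_ids[:-1]}
        asn = CategoricalAssignment("e1", labels)
        shared = shared_unit_network([asn], coexp.gene_ids)
        res = unit_coexpression(shared, coexp, fraction=0.2)
        last = coexp.gene_ids[-1]
        assert res.skipped.get(last) == "no-edges"


def eqtl_fixture():
    """Small 1-kb genome, genes in distinct bins, three candidate genes per
    variant with known contact ranks."""
    genome = make_bins({"c1": 60_000}, 1000)
    genes = pd.DataFrame(
        {
            "gene_id": [f"t{k}" for k in range(3)],
            "chrom": "c1",
            "tss": [5_500, 15_500, 25_500],
            "tes": [5_900, 15_900, 25_900],
            "strand": "+",
        }
    )
    table = EQTLTable(pd.DataFrame(
        {
            "variant_id": ["v1"] * 3,
            "chrom": "c1",
            "pos": 2_500,
            "gene_id": ["t0", "t1", "t2"],
            "tss_distance": [-3_000, -13_000, -23_000],
            "significant": [1, 0, 0],
        }
    ))
    return genome, genes, table


class TestFilterEqtls:
    def test_one_kb_rule_and_coding_removal(self):
        genome, genes, _ = eqtl_fixture()
        coding = pd.DataFrame({"chrom": "c1", "start": [30_000], "end": [31_000]})
        table = EQTLTable(pd.DataFrame(
            {
                "variant_id": ["near_tss", "clear", "in_coding"],
                "chrom": "c1",
                "pos": [5_000, 3_000, 30_500],  # 500 bp from t0 TSS / >1 kb / coding
                "gene_id": ["t1", "t1", "t1"],
                "tss_distance": [1, 1, 1],
                "significant": [1, 1, 1],
            }
        ))
        out = filter_eqtls(table, genes, coding)
        assert set(out.records["variant_id"]) == {"clear"}

    def test_exactly_1001_bp_kept(self):
        genome, genes, _ = eqtl_fixture()
        table = EQTLTable(pd.DataFrame(
            {
                "variant_id": ["edge"],
                "chrom": "c1",
                "pos": [5_500 - 1_001],
                "gene_id": ["t1"],
                "tss_distance": [1],
                "significant": [1],
            }
        ))
        out = filter_eqtls(table, genes, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out.records) == 1


class TestCandidateGenes:
    def test_bin_sharing_genes_all_excluded(self):
        genome = make_bins({"c1": 10_000}, 1000)
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "chrom": "c1",
                "tss": [1_100, 1_900, 5_500],  # a,b share bin 1
                "tes": [1_300, 2_400, 5_800],
                "strand": "+",
            }
        )
        v = GenomicVariant("v", "c1", 8_500)
        assert candidate_genes(v, genes, genome) == ["c"]

    def test_distinct_bins_all_candidates(self):
        genome, genes, _ = eqtl_fixture()
        v = GenomicVariant("v", "c1", 2_500)
        assert candidate_genes(v, genes, genome) == list(genes["gene_id"])


class TestEqtlMetrics:
    def test_contact_tie_case(self):
        genome, genes, table = eqtl_fixture()
        # variant bin 2; contacts to t0/t1 bins tie at 2, t2 lower
        cm = ContactMatrix.from_coo(
            genome, [2, 2, 2], [5, 15, 25], [2.0, 2.0, 1.0]
        )
        res = contact_eqtl(cm, genes, table)
        assert res.per_entity["v1"] == pytest.approx(0.75)

    def test_proximity_middle_egene(self):
        genome = make_bins({"c1": 100_000}, 1000)
        genes = pd.DataFrame(
            {
                "gene_id": ["near", "mid", "far"],
                "chrom": "c1",
                "tss": [20_000, 30_000, 50_000],
                "tes": [20_500, 30_500, 50_500],
                "strand": "+",
            }
        )
        table = EQTLTable(pd.DataFrame(
            {
                "variant_id": ["v"] * 3,
                "chrom": "c1",
                "pos": 10_000,
                "gene_id": ["near", "mid", "far"],
                "tss_distance": [-10_000, -20_000, -40_000],
                "significant": [0, 1, 0],
            }
        ))
        res = proximity_eqtl(genes, table, genome)
        assert res.per_entity["v"] == pytest.approx(0.5)

    def test_min_distance_strictly_removes_close_candidates(self):
        genome, genes, table = eqtl_fixture()
        cm = ContactMatrix.from_coo(genome, [2, 2, 2], [5, 15, 25], [5.0, 2.0, 1.0])
        res = contact_eqtl(cm, genes, table, min_distance=3_000)
        # the significant eGene t0 sits exactly 3000 bp away -> removed -> skip
        assert res.skipped.get("v1") == "no-positives"

    def test_skip_sets_identical_between_metrics(self, default_dataset):
        ds = default_dataset
        coding = pd.DataFrame(
            {
                "chrom": ds.genes["chrom"],
                "start": np.minimum(ds.genes["tss"], ds.genes["tes"]),
                "end": np.maximum(ds.genes["tss"], ds.genes["tes"]),
            }
        )
        table = filter_eqtls(ds.eqtls, ds.genes, coding)
        rc = contact_eqtl(ds.contacts, ds.genes, table)
        rp = proximity_eqtl(ds.genes, table, ds.genome)
        assert set(rc.skipped) == set(rp.skipped)
        assert set(rc.per_entity) == set(rp.per_entity)

    def test_null_contacts_score_half(self):
        rng = np.random.default_rng(9)
        genome = make_bins({"c1": 400_000}, 1000)
        tss = np.arange(50) * 8_000 + 4_100
        genes = pd.DataFrame(
            {"gene_id": [f"t{k}" for k in range(50)], "chrom": "c1",
             "tss": tss, "tes": tss + 500, "strand": "+"}
        )
        rows = []
        for v in range(120):
            pos = int(rng.integers(0, 400_000 // 1000)) * 1000 + 450
            eg = int(rng.integers(0, 50))
            rows.append((f"v{v}", "c1", pos, f"t{eg}", 1, 1))
        table = EQTLTable(pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "gene_id",
                           "tss_distance", "significant"]
        ))
        i, j = np.triu_indices(genome.n_bins)
        keep = rng.random(len(i)) < 0.05
        cm = ContactMatrix.from_coo(
            genome, i[keep], j[keep], rng.random(int(keep.sum()))
        )
        res = contact_eqtl(cm, genes, table)
        assert res.mean_auc == pytest.approx(0.5, abs=0.06)
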