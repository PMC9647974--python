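import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from metahic import (
    ConfigError, InvalidInputError, SimulationConfig, filter_eqtls,
    sample_contacts, simulate_contact_probabilities, simulate_dataset,
    simulate_expression, simulate_species_pair, subsample_contacts,
    tss_bin,
)


def tiny_config(**kw):
    base = dict(n_chroms=2, chrom_length=400_000, resolution=10_000,
                n_genes=30, n_samples=50, depth=100_000, n_variants=5,
                n_functional_pairs=6, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_unknown_key_named(self):
        with pytest.raises(ConfigError, match="bogus"):
            SimulationConfig.from_dict({"bogus": 1})

    @pytest.mark.parametrize("field,value", [
        ("coupling", 1.5), ("divergence", -0.1), ("decay_exponent", 0),
        ("n_genes", 0), ("plaid_boost", 0.5),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(**{field: value})


class TestProbabilities:
    def test_deterministic_under_seed(self):
        P1, t1 = simulate_contact_probabilities(tiny_config())
        P2, t2 = simulate_contact_probabilities(tiny_config())
        assert np.array_equal(P1, P2)
        assert t1.genes.equals(t2.genes)
        assert t1.functional_pairs == t2.functional_pairs

    def test_matrix_is_normalized_probability(self):
        P, _ = simulate_contact_probabilities(tiny_config())
        assert P.sum() == pytest.approx(1.0)
        assert (P >= 0).all()

    def test_plaid_off_cis_depends_only_on_distance(self):
        P, truth = simulate_contact_probabilities(
            tiny_config(plaid_boost=1.0, n_functional_pairs=0, n_variants=0)
        )
        b0, b1 = truth.genome.chrom_bins("chr1")
        block = P[b0:b1, b0:b1]
        for d in (0, 3, 7):
            diag = block.diagonal(d)
            assert np.allclose(diag, diag[0])

    def test_zero_trans_base_and_no_pairs_empties_trans(self):
        P, truth = simulate_contact_probabilities(
            tiny_config(trans_base=0.0, n_functional_pairs=0, n_variants=0)
        )
        g = truth.genome
        trans = g.chrom_of_bin[:, None] != g.chrom_of_bin[None, :]
        assert P[trans].sum() == 0

    def test_strong_decay_concentrates_near_diagonal(self):
        P, truth = simulate_contact_probabilities(
            tiny_config(decay_exponent=6.0, plaid_boost=1.0, trans_base=0.0,
                        n_functional_pairs=0, n_variants=0)
        )
        g = truth.genome
        d = np.abs(np.arange(g.n_bins)[:, None] - np.arange(g.n_bins)[None, :])
        near = P[(d <= 1)].sum()
        assert near > 0.95

    def test_functional_pairs_are_trans_and_boosted(self):
        cfg = tiny_config(n_variants=0)
        P, truth = simulate_contact_probabilities(cfg)
        g = truth.genome
        genes = {r.gene_id: r for r in truth.genes.itertuples(index=False)}
        trans_cells = P[g.chrom_of_bin[:, None] != g.chrom_of_bin[None, :]]
        background = np.median(trans_cells[trans_cells > 0])
        for ga, gb in truth.functional_pairs:
            assert genes[ga].chrom != genes[gb].chrom
            i, j = tss_bin(g, genes[ga]), tss_bin(g, genes[gb])
            assert P[i, j] == pytest.approx(background * cfg.functional_boost, rel=1e-9)


class TestSampling:
    def test_depth_zero_gives_empty_matrix(self):
        P, truth = simulate_contact_probabilities(tiny_config())
        cm = sample_contacts(P, 0, 1, truth.genome)
        assert cm.total_weight == 0

    def test_depth_conserved_exactly_and_seeded(self):
        P, truth = simulate_contact_probabilities(tiny_config())
        a = sample_contacts(P, 12_345, 7, truth.genome)
        b = sample_contacts(P, 12_345, 7, truth.genome)
        assert a.total_weight == 12_345
        assert np.allclose(a.dense_symmetric(), b.dense_symmetric())

    def test_binomial_two_cell_spread(self):
        """Uniform 2-cell structure: counts ~ Binomial(1e6, 1/2), sd ~ 500."""
        from metahic import make_bins
        g = make_bins({"c1": 20}, 10)
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.25
        P[0, 0] = P[1, 1] = 0.25
        draws = [
            sample_contacts(P, 1_000_000, seed, g).matrix[0, 1]
            for seed in range(8)
        ]
        assert all(abs(d - 500_000) < 3_000 for d in draws)

    def test_chi_square_goodness_of_fit(self):
        P, truth = simulate_contact_probabilities(tiny_config())
        depth = 500_000
        cm = sample_contacts(P, depth, 3, truth.genome)
        iu = np.triu_indices(truth.genome.n_bins)
        w = P[iu].copy()
        w[iu[0] != iu[1]] *= 2
        p = w / w.sum()
        obs = np.asarray(cm.matrix[iu]).ravel()
        keep = p * depth >= 10  # chi-square validity
        stat, pval = chisquare(
            obs[keep], depth * p[keep] * (obs[keep].sum() / (depth * p[keep].sum()))
        )
        assert pval > 0.001

    def test_subsample_exact_and_nested(self):
        P, truth = simulate_contact_probabilities(tiny_config())
        big = sample_contacts(P, 100_000, 5, truth.genome)
        sub = subsample_contacts(big, 10_000, 6)
        assert sub.total_weight == 10_000
        assert (sub.dense_symmetric() <= big.dense_symmetric()).all()
        with pytest.raises(InvalidInputError):
            subsample_contacts(sub, 99_999_999, 7)


class TestExpression:
    def test_zero_coupling_is_uncorrelated(self):
        cfg = tiny_config(coupling=0.0, n_samples=200)
        _, truth = simulate_contact_probabilities(cfg)
        expr = simulate_expression(truth, cfg)
        corr = np.corrcoef(expr.to_numpy())
        off = corr[np.triu_indices(len(corr), 1)]
        assert abs(off.mean()) < 0.02

    def test_same_module_correlation_matches_coupling(self):
        """kappa=0.5 with 200 samples: same-module Pearson ~ 0.5 +- 3/sqrt(n-3)."""
        cfg = tiny_config(coupling=0.5, n_samples=200, n_functional_pairs=0)
        _, truth = simulate_contact_probabilities(cfg)
        expr = simulate_expression(truth, cfg)
        comp = truth.gene_compartments()
        genes = truth.genes
        corr = np.corrcoef(expr.to_numpy())
        same_vals, other_vals = [], []
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                ga, gb = genes.iloc[a], genes.iloc[b]
                same_module = (ga.chrom == gb.chrom
                               and comp[ga.gene_id] == comp[gb.gene_id])
                (same_vals if same_module else other_vals).append(corr[a, b])
        assert np.mean(same_vals) == pytest.approx(0.5, abs=0.06)
        assert abs(np.mean(other_vals)) < 0.06

    def test_full_coupling_same_module_near_one(self):
        cfg = tiny_config(coupling=1.0, n_samples=300, n_functional_pairs=0)
        _, truth = simulate_contact_probabilities(cfg)
        expr = simulate_expression(truth, cfg)
        comp = truth.gene_compartments()
        g0 = truth.genes.iloc[0]
        partner = next(
            r for r in truth.genes.iloc[1:].itertuples(index=False)
            if r.chrom == g0.chrom and comp[r.gene_id] == comp[g0.gene_id]
        )
        x = expr.loc[g0.gene_id].to_numpy()
        y = expr.loc[partner.gene_id].to_numpy()
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0, abs=1e-9)


class TestEqtlPlanting:
    def test_variants_survive_the_paper_filter(self):
        ds = simulate_dataset(tiny_config(n_variants=10))
        coding = pd.DataFrame(
            {
                "chrom": ds.genes["chrom"],
                "start": np.minimum(ds.genes["tss"], ds.genes["tes"]),
                "end": np.maximum(ds.genes["tss"], ds.genes["tes"]),
            }
        )
        before = set(ds.eqtls.records["variant_id"])
        after = set(filter_eqtls(ds.eqtls, ds.genes, coding).records["variant_id"])
        assert before == after  # planted >1 kb from TSS/TES and non-coding

    def test_table_has_significant_and_decoy_records(self):
        ds = simulate_dataset(tiny_config(n_variants=8))
        rec = ds.eqtls.records
        per_variant = rec.groupby("variant_id")["significant"].agg(["sum", "count"])
        assert (per_variant["sum"] == 1).all()
        assert (per_variant["count"] > 1).all()


class TestSpeciesPair:
    def test_zero_divergence_copies_structure(self):
        cfg = tiny_config(divergence=0.0)
        P, truth = simulate_contact_probabilities(cfg)
        pair = simulate_species_pair(truth, cfg)
        # species A keeps its eQTL boosts; compare with an A rebuilt without them
        cfg0 = tiny_config(divergence=0.0, n_variants=0)
        P0, _ = simulate_contact_probabilities(cfg0)
        assert np.allclose(pair.probabilities_b, P0)

    def test_full_divergence_rewires_all_pairs(self):
        cfg = tiny_config(divergence=1.0, n_variants=0)
        _, truth = simulate_contact_probabilities(cfg)
        pair = simulate_species_pair(truth, cfg)
        orig = {frozenset(p) for p in truth.functional_pairs}
        new = {frozenset(p) for p in pair.truth_b.functional_pairs}
        assert orig.isdisjoint(new)
        assert len(new) == len(orig)

    def test_ortholog_map_is_identity(self):
        cfg = tiny_config()
        _, truth = simulate_contact_probabilities(cfg)
        pair = simulate_species_pair(truth, cfg)
        assert (pair.orthologs["gene_a"] == pair.orthologs["gene_b"]).all()
        assert set(pair.orthologs["gene_a"]) == set(truth.genes["gene_id"])
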