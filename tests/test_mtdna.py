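"""Haplotype statistics, AMOVA/Phi_ST and the parsimony network."""

import itertools

import numpy as np
import pytest

from tealgen.mtdna import (
    amova,
    collapse_haplotypes,
    hap_diversity,
    nuc_diversity,
    parsimony_limit,
    phi_st,
    tajimas_d,
    tcs_network,
)
from tealgen.simulate import SequenceAlignment


def aln_of(seqs, pops=None, ids=None):
    n = len(seqs)
    return SequenceAlignment(
        sequences=seqs,
        sample_ids=ids or [f"s{i}" for i in range(n)],
        populations=pops or ["P"] * n,
    )


class TestHaplotypes:
    def test_identical_sequences_single_haplotype(self):
        ht = collapse_haplotypes(aln_of(["ACGT"] * 4))
        assert ht.n_haplotypes == 1
        assert ht.labels == ["I"]

    def test_toy_counts_match_hand_tally(self, toy_alignment):
        ht = collapse_haplotypes(toy_alignment)
        assert ht.n_haplotypes == 3
        assert ht.counts.loc["I"].to_dict() == {"P1": 2, "P2": 1}
        assert ht.counts.loc["II"].to_dict() == {"P1": 1, "P2": 1}
        assert ht.counts.loc["III"].to_dict() == {"P1": 0, "P2": 1}
        assert (ht.counts.sum(axis=0) == [3, 3]).all()

    def test_shared_vs_private_classification(self, toy_alignment):
        ht = collapse_haplotypes(toy_alignment)
        assert not ht.private["I"]  # in both populations
        assert ht.private["III"]

    def test_n_wildcard_merges_ambiguous(self):
        strict = collapse_haplotypes(aln_of(["ACGT", "ACGN"]))
        merged = collapse_haplotypes(aln_of(["ACGT", "ACGN"]), n_wildcard=True)
        assert strict.n_haplotypes == 2
        assert merged.n_haplotypes == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aln_of(["ACGT", "ACG"])


class TestDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((9, 1), 0.200), ((10, 10), 0.526), ((5,), 0.0)],
    )
    def test_haplotype_diversity_published_configurations(self, counts, expected):
        hd, var = hap_diversity(counts)
        assert round(hd, 3) == expected
        assert var >= 0

    def test_minimum_sample_rejected(self):
        with pytest.raises(ValueError):
            hap_diversity([1])

    def test_single_difference_pair(self):
        s1 = "A" * 169
        s2 = "A" * 168 + "T"
        assert np.isclose(nuc_diversity(aln_of([s1, s2])), 1 / 169)

    def test_identical_sequences_zero(self):
        assert nuc_diversity(aln_of(["ACGT"] * 3)) == 0.0

    def test_matches_brute_force_average(self):
        seqs = ["ACGTAC", "ACGTAT", "ACCTAT", "GCGTAC"]
        aln = aln_of(seqs)
        pairs = list(itertools.combinations(seqs, 2))
        brute = np.mean(
            [sum(a != b for a, b in zip(x, y)) / 6 for x, y in pairs]
        )
        assert np.isclose(nuc_diversity(aln), brute)

    def test_ambiguity_excluded_pairwise(self):
        # N only blanks the site for pairs involving that sequence
        aln = aln_of(["AAAA", "AAAN", "TAAA"])
        # pairs: (1,2): 0/3 comparable diff? s1 vs s2: sites1-3 equal -> 0/3
        # s1 vs s3: 1/4; s2 vs s3: 1/3
        expected = np.mean([0 / 3, 1 / 4, 1 / 3])
        assert np.isclose(nuc_diversity(aln), expected)

    def test_order_invariance(self, toy_alignment):
        hd1, _ = hap_diversity(
            collapse_haplotypes(toy_alignment).counts.sum(axis=1)
        )
        rev = aln_of(
            toy_alignment.sequences[::-1],
            pops=toy_alignment.populations[::-1],
        )
        hd2, _ = hap_diversity(collapse_haplotypes(rev).counts.sum(axis=1))
        assert np.isclose(hd1, hd2)
        assert np.isclose(nuc_diversity(toy_alignment), nuc_diversity(rev))


class TestTajima:
    def test_no_segregating_sites_error(self):
        with pytest.raises(ValueError, match="segregating"):
            tajimas_d(aln_of(["ACGT"] * 5))

    def test_matches_textbook_oracle(self):
        seqs = ["AAAA", "AAAT", "AATT", "AAAA"]
        # independent textbook computation
        n, S = 4, 2
        diffs = [sum(a != b for a, b in zip(x, y))
                 for x, y in itertools.combinations(seqs, 2)]
        pi = np.mean(diffs)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        oracle = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert np.isclose(tajimas_d(aln_of(seqs)), oracle)

    def test_neutral_simulations_centered(self, study_model):
        from tealgen.models import SimConfig
        from tealgen.simulate import simulate_mtdna

        vals = []
        for seed in range(300):
            cfg = SimConfig(seed=seed, mt_mu=2.5e-6, mt_seq_length=500,
                            samples_per_deme=(12, 1))
            # constant-size single deme: factor 0.5 * 2e4 = 1e4 haploid
            from tealgen.models import DemographicModel

            model = DemographicModel(theta_es=2e4, theta_iq=2e4, t_div=0.0, theta_anc=2e4)
            aln = simulate_mtdna(model, cfg, samples_per_deme=(12, 0))
            try:
                vals.append(tajimas_d(aln))
            except ValueError:
                continue
        assert abs(np.mean(vals)) < 0.15


class TestPhiSt:
    def test_fixed_haplotypes_ten_steps_apart(self):
        a = aln_of(["A" * 10 + "C" * 10] * 4 + ["A" * 20] * 4,
                   pops=["P1"] * 4 + ["P2"] * 4)
        phi, p = phi_st(a, ("P1", "P2"), n_permutations=99, seed=1)
        assert np.isclose(phi, 1.0)

    def test_identical_sequences_undefined(self):
        a = aln_of(["ACGT"] * 6, pops=["P1"] * 3 + ["P2"] * 3)
        with pytest.raises(ValueError, match="identical"):
            phi_st(a, ("P1", "P2"))

    def test_matches_enumeration_oracle(self):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT", "TTTA", "TTAA", "TAAA"]
        pops = ["P1"] * 4 + ["P2"] * 4
        a = aln_of(seqs, pops=pops)
        phi, _ = phi_st(a, ("P1", "P2"), n_permutations=9, seed=1)
        # brute-force variance components from the distance matrix
        d = np.array([[sum(x != y for x, y in zip(s, t)) for t in seqs] for s in seqs])
        N, n_p = 8, 4
        ss_total = d.sum() / (2 * N)
        ss_w = d[:4, :4].sum() / (2 * n_p) + d[4:, 4:].sum() / (2 * n_p)
        ss_a = ss_total - ss_w
        ms_w = ss_w / (N - 2)
        ms_a = ss_a / 1
        n0 = (N - (16 + 16) / N) / 1
        sigma_a = (ms_a - ms_w) / n0
        oracle = sigma_a / (sigma_a + ms_w)
        assert np.isclose(phi, oracle)

    def test_equidistant_haplotypes_reduce_to_frequency_fst(self):
        # all distinct haplotypes exactly 2 steps apart: Phi_ST equals the
        # frequency-based statistic computed on haplotype identity (0/1)
        h1, h2, h3 = "AATT", "AACC", "AAGG"  # pairwise distance 2
        seqs = [h1, h1, h1, h2, h2, h2]
        pops = ["P1"] * 3 + ["P2"] * 3
        phi, _ = phi_st(aln_of(seqs, pops=pops), ("P1", "P2"), 9, seed=1)
        # identity distances (0 same, 1 different), same layout
        d = np.array([[0 if s == t else 1 for t in seqs] for s in seqs], float)
        N, n_p = 6, 3
        ss_total = d.sum() / (2 * N)
        ss_w = d[:3, :3].sum() / (2 * n_p) + d[3:, 3:].sum() / (2 * n_p)
        ms_w = ss_w / (N - 2)
        ms_a = (ss_total - ss_w) / 1
        n0 = (N - (9 + 9) / N) / 1
        sigma_a = (ms_a - ms_w) / n0
        fst_freq = sigma_a / (sigma_a + ms_w)
        assert np.isclose(phi, fst_freq)


class TestAmova:
    def three_pop_alignment(self):
        seqs = (
            ["AAAA", "AAAT"] * 2
            + ["TTAA", "TTAT"] * 2
            + ["AATT", "GATT"] * 2
        )
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
        return aln_of(seqs, pops=pops)

    def test_percentages_sum_to_hundred(self):
        a = self.three_pop_alignment()
        res = amova(a, {"G1": ["P1", "P2"], "G2": ["P3"]}, n_permutations=49, seed=2)
        assert np.isclose(res.table["percent_variation"].sum(), 100.0, atol=1e-9)

    def test_own_group_per_population_zeroes_middle_level(self):
        a = self.three_pop_alignment()
        res = amova(
            a, {"G1": ["P1"], "G2": ["P2"], "G3": ["P3"]}, n_permutations=19, seed=3
        )
        assert res.table.loc["among_pops_within", "variance_component"] == 0.0

    def test_identical_sequences_all_zero(self):
        a = aln_of(["ACGT"] * 8, pops=["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"])
        res = amova(a, {"G1": ["P1", "P2"], "G2": ["P3", "P4"]}, n_permutations=19, seed=4)
        assert np.allclose(res.table["variance_component"].fillna(0), 0.0)

    def test_components_match_least_squares_oracle(self):
        # balanced design: solve the expected-mean-square system directly
        a = self.three_pop_alignment()
        groups = {"G1": ["P1", "P2"], "G2": ["P3"]}
        res = amova(a, groups, n_permutations=9, seed=5)
        enc = {"A": 0, "C": 1, "G": 2, "T": 3}
        seqs = a.sequences
        d = np.array(
            [[sum(x != y for x, y in zip(s, t)) for t in seqs] for s in seqs], float
        )
        N = 12
        pops = [list(range(0, 4)), list(range(4, 8)), list(range(8, 12))]
        grps = [list(range(0, 8)), list(range(8, 12))]
        ss_tot = d.sum() / (2 * N)
        ss_wp = sum(d[np.ix_(p, p)].sum() / (2 * len(p)) for p in pops)
        ss_wg = sum(d[np.ix_(g, g)].sum() / (2 * len(g)) for g in grps)
        ss_ap, ss_ag = ss_wg - ss_wp, ss_tot - ss_wg
        sigma_c = ss_wp / (N - 3)
        n_prime = (N - (16 + 16) / 8 - 16 / 4) / 1  # = 8
        sigma_b = (ss_ap / 1 - sigma_c) / n_prime
        n_dp = ((16 + 16) / 8 + 16 / 4 - (3 * 16) / N) / 1
        n_tp = (N - (64 + 16) / N) / 1
        sigma_a = (ss_ag / 1 - sigma_c - n_dp * sigma_b) / n_tp
        got = res.table["variance_component"].to_numpy()
        assert np.allclose(got, [sigma_a, sigma_b, sigma_c])

    def test_p_values_in_unit_interval(self):
        a = self.three_pop_alignment()
        res = amova(a, {"G1": ["P1", "P2"], "G2": ["P3"]}, n_permutations=99, seed=6)
        for p in res.p_values.values():
            assert 0 < p <= 1


class TestNetwork:
    def test_single_step_pair(self):
        ht = collapse_haplotypes(aln_of(["AAAA", "AAAT"]))
        net = tcs_network(ht)
        assert net.graph.number_of_edges() == 1
        assert not any(d["inferred"] for _, d in net.graph.nodes(data=True))

    def test_linear_three_haplotypes_no_shortcut(self):
        ht = collapse_haplotypes(aln_of(["AAAA", "AAAT", "AATT"]))
        net = tcs_network(ht, connection_limit=5)
        assert sorted(net.graph.edges()) == [("I", "II"), ("II", "III")]

    def test_star_topology(self):
        center = "AAAAA"
        leaves = ["TAAAA", "ACAAA", "AAGAA", "AAATA"]
        ht = collapse_haplotypes(aln_of([center] + leaves))
        net = tcs_network(ht, connection_limit=3)
        degrees = dict(net.graph.degree())
        assert degrees["I"] == 4
        assert all(degrees[l] == 1 for l in ["II", "III", "IV", "V"])

    def test_multi_step_edge_inserts_intermediates(self):
        ht = collapse_haplotypes(aln_of(["AAAA", "AATT"]))
        net = tcs_network(ht, connection_limit=4)
        inferred = [n for n, d in net.graph.nodes(data=True) if d["inferred"]]
        assert len(inferred) == 1
        assert net.graph.number_of_edges() == 2

    def test_connection_limit_partitions(self):
        ht = collapse_haplotypes(aln_of(["A" * 12, "A" * 6 + "T" * 6]))
        net = tcs_network(ht, connection_limit=2)
        assert len(net.components) == 2

    def test_limit_decreases_with_shorter_fragments(self):
        assert parsimony_limit(169) <= parsimony_limit(440)
        assert parsimony_limit(169) >= 1
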