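"""Diversity statistics, neutrality tests, and Nei-Gojobori counting."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from polycub.popgen import (
    _codon_sites,
    diversity_stats,
    fu_li_tests,
    group_dnds,
    pairwise_nei_gojobori,
    tajima_d,
)
from polycub.seqio import STANDARD_CODE, Alignment


def random_alignment(rng, m, n, p_mut=0.05) -> Alignment:
    base = rng.choice(list("ACGT"), size=n)
    seqs = []
    for i in range(m):
        row = base.copy()
        hit = rng.random(n) < p_mut
        row[hit] = rng.choice(list("ACGT"), size=hit.sum())
        seqs.append("".join(row))
    return Alignment([f"s{i}" for i in range(m)], seqs)


class TestDiversityStats:
    def test_two_sequences_one_difference(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        ds = diversity_stats(Alignment(["a", "b"], [a, b]))
        assert (ds.S, ds.eta) == (1, 1)
        assert ds.k == pytest.approx(1.0)
        assert ds.pi == pytest.approx(0.01)

    def test_k_matches_all_pairs_hamming_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 8))
            aln = random_alignment(rng, m, int(rng.integers(30, 80)))
            ds = diversity_stats(aln)
            pairs = list(itertools.combinations(aln.seqs, 2))
            k_oracle = sum(
                sum(x != y for x, y in zip(s1, s2)) for s1, s2 in pairs
            ) / len(pairs)
            assert ds.k == pytest.approx(k_oracle, abs=1e-9)
            assert ds.pi == pytest.approx(ds.k / ds.n_sites, abs=1e-9)
            assert ds.S <= ds.eta

    def test_complete_deletion_drops_gapped_columns(self):
        aln = Alignment(["a", "b"], ["AC-GT", "ACNGA"])
        ds = diversity_stats(aln)
        assert ds.n_sites == 4  # the -/N column is removed entirely
        assert ds.S == 1

    def test_singleton_counting(self):
        # column 0: allele T unique to s0; column 1: 2/2 split, no singleton
        aln = Alignment(
            ["s0", "s1", "s2", "s3"],
            ["TA", "AA", "AC", "AC"],
        )
        ds = diversity_stats(aln)
        assert ds.eta == 2 and ds.eta_s == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            diversity_stats(Alignment(["a"], ["ACGT"]))


def tajima_oracle(m, S, k):
    """Direct formula with exact-rational constants, independent path."""
    a1 = sum(Fraction(1, i) for i in range(1, m))
    a2 = sum(Fraction(1, i * i) for i in range(1, m))
    b1 = Fraction(m + 1, 3 * (m - 1))
    b2 = Fraction(2 * (m * m + m + 3), 9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(m + 2) / (a1 * m) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1) * S + float(e2) * S * (S - 1)
    return (k - S / float(a1)) / math.sqrt(var)


class TestTajimaD:
    def test_no_polymorphism_undefined(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        assert tajima_d(diversity_stats(aln)) is None

    def test_matches_rational_constant_oracle(self, rng):
        for _ in range(30):
            aln = random_alignment(rng, int(rng.integers(4, 12)), 60)
            ds = diversity_stats(aln)
            if ds.S == 0:
                continue
            assert tajima_d(ds) == pytest.approx(
                tajima_oracle(ds.m, ds.S, ds.k), abs=1e-10
            )

    def test_excess_rare_variants_negative(self):
        # every mutation a singleton on a different sequence
        seqs = ["A" * 30 for _ in range(6)]
        seqs = [
            s[:i] + "T" + s[i + 1:] if i < 5 else s
            for i, s in enumerate(seqs)
        ]
        ds = diversity_stats(Alignment([f"s{i}" for i in range(6)], seqs))
        assert tajima_d(ds) < 0


class TestFuLi:
    def test_no_polymorphism_undefined(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        assert fu_li_tests(diversity_stats(aln)) == (None, None)

    def test_singleton_excess_negative_balanced_positive(self):
        m, n = 8, 60
        # all mutations singletons
        sing = ["A" * n for _ in range(m)]
        sing = [s[:i * 3] + "T" + s[i * 3 + 1:] for i, s in enumerate(sing)]
        ds_sing = diversity_stats(Alignment([f"s{i}" for i in range(m)], sing))
        assert ds_sing.eta_s == ds_sing.eta > 0
        d_sing, f_sing = fu_li_tests(ds_sing)
        # balanced: mutations shared by half the sample
        bal = []
        for i in range(m):
            s = list("A" * n)
            if i < m // 2:
                for j in range(0, 12, 3):
                    s[j] = "T"
            bal.append("".join(s))
        ds_bal = diversity_stats(Alignment([f"s{i}" for i in range(m)], bal))
        assert ds_bal.eta_s == 0
        d_bal, f_bal = fu_li_tests(ds_bal)
        assert d_sing < 0 < d_bal
        assert f_sing < 0 < f_bal

    def test_statistics_invariant_to_relabeling(self, rng):
        aln = random_alignment(rng, 8, 50)
        perm = rng.permutation(8)
        aln2 = Alignment([aln.ids[i] for i in perm], [aln.seqs[i] for i in perm])
        ds1, ds2 = diversity_stats(aln), diversity_stats(aln2)
        assert tajima_d(ds1) == pytest.approx(tajima_d(ds2))
        assert fu_li_tests(ds1) == pytest.approx(fu_li_tests(ds2))


def pathway_oracle(c1, c2, code=STANDARD_CODE):
    """All shortest paths in the single-substitution graph (BFS, independent)."""
    if c1 == c2:
        return 0.0, 0.0
    d = sum(a != b for a, b in zip(c1, c2))
    paths = []

    def extend(path):
        cur = path[-1]
        if cur == c2:
            if len(path) == d + 1:
                paths.append(path)
            return
        for pos in range(3):
            if cur[pos] != c2[pos]:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                extend(path + [nxt])

    extend([c1])
    usable = [
        p for p in paths
        if not any(code.is_stop(x) for x in p[1:-1])
    ] or paths
    syn = nsyn = 0.0
    for p in usable:
        for a, b in zip(p, p[1:]):
            if code.codon_to_aa[a] == code.codon_to_aa[b]:
                syn += 1
            else:
                nsyn += 1
    return syn / len(usable), nsyn / len(usable)


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        pN, pS, _, _ = pairwise_nei_gojobori(["ATG", "GGA"], ["ATG", "GGA"])
        assert pN == 0.0 and pS == 0.0

    def test_single_synonymous_difference(self):
        pN, pS, sitesN, sitesS = pairwise_nei_gojobori(["TTT"], ["TTC"])
        assert pN == 0.0
        assert pS * sitesS == pytest.approx(1.0)  # one synonymous change

    def test_fourfold_third_position_is_synonymous_site(self, code):
        s, n = _codon_sites("GGG", code)
        assert s == pytest.approx(1.0) and n == pytest.approx(2.0)

    def test_sites_sum_to_three(self, code):
        for codon in code.sense_codons:
            s, n = _codon_sites(codon, code)
            assert s + n == pytest.approx(3.0)

    def test_counts_match_pathway_enumeration_oracle(self, rng, code):
        sense = list(code.sense_codons)
        checked = 0
        while checked < 200:
            c1, c2 = rng.choice(sense, size=2)
            if c1 == c2:
                continue
            pN, pS, sitesN, sitesS = pairwise_nei_gojobori([c1], [c2])
            syn_o, nsyn_o = pathway_oracle(c1, c2)
            assert pS * sitesS == pytest.approx(syn_o, abs=1e-9)
            assert pN * sitesN == pytest.approx(nsyn_o, abs=1e-9)
            checked += 1

    def test_gapped_codons_skipped_pairwise(self):
        pN, pS, sitesN, sitesS = pairwise_nei_gojobori(
            ["TTT", "A-G"], ["TTC", "ATG"]
        )
        assert sitesN + sitesS == pytest.approx(3.0)  # only one codon used

    def test_group_dnds_identical_undefined_ratio(self):
        aln = Alignment(["a", "b"], ["ATGGGA", "ATGGGA"])
        res = group_dnds(aln)
        assert res.dN == 0.0 and res.dS == 0.0 and res.ratio is None

    def test_omega_recovery_from_simulated_divergence(self, code):
        """Accept-reject evolution at omega=0.2 is recovered within 0.1."""
        rng = np.random.default_rng(2024)
        sense = list(code.sense_codons)
        L, m, attempts = 2000, 4, 1000
        ancestor = [str(c) for c in rng.choice(sense, size=L)]
        seqs = []
        for _ in range(m):
            codons = list(ancestor)
            done = 0
            while done < attempts:
                i = int(rng.integers(0, L))
                pos = int(rng.integers(0, 3))
                base = "ACGT"[int(rng.integers(0, 4))]
                cur = codons[i]
                if base == cur[pos]:
                    continue
                new = cur[:pos] + base + cur[pos + 1:]
                if code.is_stop(new):
                    continue
                syn = code.codon_to_aa[new] == code.codon_to_aa[cur]
                done += 1
                if syn or rng.random() < 0.2:
                    codons[i] = new
            seqs.append("".join(codons))
        res = group_dnds(Alignment([f"l{i}" for i in range(m)], seqs), code)
        assert res.ratio == pytest.approx(0.2, abs=0.1)

    def test_group_dnds_purifying_signal(self, rng, code):
        """Mostly-synonymous divergence yields dN/dS well below 1."""
        m, L = 4, 120
        seqs = []
        for i in range(m):
            codons = [str(rng.choice(["GCA", "GCT"])) for _ in range(L)]
            seqs.append("".join(codons))
        res = group_dnds(Alignment([f"s{i}" for i in range(m)], seqs))
        assert res.dS > 0 and res.dN == 0.0
        assert res.ratio == pytest.approx(0.0)
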