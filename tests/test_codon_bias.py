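"""RSCU, ENC and CAI behaviour: examples, limits and invariances."""

from collections import Counter

import numpy as np
import pytest

from polycub.codon_bias import (
    cai,
    classify_representation,
    codon_counts,
    enc,
    expected_enc,
    group_mean_rscu,
    rscu,
    rscu_distance_table,
)
from polycub.seqio import STANDARD_CODE, CodingSequence, ReferenceUsage


@pytest.fixture(scope="module")
def uniform_ref(code):
    return ReferenceUsage.from_counts({c: 10.0 for c in code.sense_codons})


class TestRscu:
    def test_uniform_usage_gives_ones(self, code):
        counts = Counter({c: 7 for c in code.sense_codons})
        v = rscu(counts, code)
        assert all(x == pytest.approx(1.0) for x in v.values.values())

    def test_leucine_skew(self, code):
        v = rscu(Counter({"TTA": 3, "TTG": 1}), code)
        assert v["TTA"] == pytest.approx(4.5)  # 3 / (4/6)

    def test_family_sums_equal_degeneracy(self, rng, code):
        counts = Counter({c: int(rng.integers(0, 30)) for c in code.sense_codons})
        v = rscu(counts, code)
        for aa, fam in code.families.items():
            if len(fam) == 1:
                continue
            total = sum(counts[c] for c in fam)
            fam_sum = sum(v[c] for c in fam)
            if total > 0:
                assert fam_sum == pytest.approx(len(fam), abs=1e-9)
            else:
                assert fam_sum == 0.0 and aa in v.empty_families

    def test_vector_covers_59_codons(self, code):
        v = rscu(Counter({c: 1 for c in code.sense_codons}), code)
        assert len(v.values) == 59

    @pytest.mark.parametrize("value,label", [(1.7, "over"), (0.5, "under"),
                                             (1.0, "neither"), (1.6, "over"),
                                             (0.6, "under")])
    def test_representation_thresholds(self, value, label):
        from polycub.codon_bias import RSCUVector

        assert classify_representation(RSCUVector({"TTA": value}))["TTA"] == label

    def test_group_mean_and_distance(self, code):
        base = Counter({c: 5 for c in code.sense_codons})
        v1 = rscu(base + Counter({"AGA": 20}), code)
        v2 = rscu(base, code)
        mean = group_mean_rscu([v1, v2])
        assert mean["AGA"] == pytest.approx((v1["AGA"] + v2["AGA"]) / 2)
        d = rscu_distance_table(v1, v2, ["AGA", "TTA"], "X-Y")
        assert d.per_codon["AGA"] == pytest.approx(abs(v1["AGA"] - v2["AGA"]))
        assert d.avg == pytest.approx(
            (d.per_codon["AGA"] + d.per_codon["TTA"]) / 2
        )
        sym = rscu_distance_table(v2, v1, ["AGA", "TTA"], "Y-X")
        assert sym.avg == pytest.approx(d.avg)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            group_mean_rscu([])


class TestEnc:
    def test_uniform_large_usage_is_61(self, code):
        assert enc(Counter({c: 1000 for c in code.sense_codons}), code).enc == 61.0

    def test_single_codon_per_family_is_20(self, code):
        counts = Counter({fam[0]: 50 for fam in code.families.values()})
        assert enc(counts, code).enc == pytest.approx(20.0)

    def test_scale_invariance(self, rng, code):
        counts = Counter({c: int(rng.integers(100, 400)) for c in code.sense_codons})
        e1 = enc(counts, code).enc
        e10 = enc(Counter({c: 10 * n for c, n in counts.items()}), code).enc
        assert abs(e1 - e10) < 0.2

    def test_monotone_decrease_under_preference_gradient(self, code):
        """ENC falls as one codon per family absorbs more of the usage."""
        values = []
        for share in (0.25, 0.45, 0.65, 0.85):
            counts: Counter = Counter()
            for fam in code.families.values():
                if len(fam) == 1:
                    counts[fam[0]] = 1000
                    continue
                counts[fam[0]] = int(1000 * share)
                rest = int(1000 * (1 - share) / (len(fam) - 1))
                for c in fam[1:]:
                    counts[c] = rest
            values.append(enc(counts, code).enc)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ile_class_imputed_when_absent(self, code):
        counts = Counter({c: 30 for c in code.sense_codons
                          if code.codon_to_aa[c] != "I"})
        e = enc(counts, code)
        assert e.enc is not None
        assert 3 in e.class_homozygosity

    def test_undefined_when_twofold_class_empty(self, code):
        counts = Counter({c: 30 for c in code.sense_codons
                          if len(code.families[code.codon_to_aa[c]]) not in (1, 2)})
        assert enc(counts, code).enc is None

    def test_significant_bias_threshold(self, code):
        counts = Counter({fam[0]: 50 for fam in code.families.values()})
        assert enc(counts, code).significant_bias is True


class TestExpectedEnc:
    @pytest.mark.parametrize("s,value", [(0.5, 60.5), (0.0, 31.0), (0.25, 48.65)])
    def test_wright_null_curve(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestCai:
    def test_optimal_codons_give_one(self, code):
        counts = {c: 10.0 for c in code.sense_codons}
        counts["TTT"] += 50  # make Phe family non-uniform in the reference
        ref = ReferenceUsage.from_counts(counts)
        optimal = Counter()
        for fam in code.families.values():
            best = max(fam, key=lambda c: ref.w[c])
            optimal[best] = 12
        assert cai(optimal, ref, code).cai == pytest.approx(1.0)

    def test_geometric_mean_toy(self, code, uniform_ref):
        counts = {c: 4.0 for c in code.sense_codons}
        counts["TTC"] = 1.0  # w(TTC) = 0.25 within Phe
        ref = ReferenceUsage.from_counts(counts)
        value = cai(Counter({"TTT": 1, "TTC": 1}), ref, code).cai
        assert value == pytest.approx(0.5)  # sqrt(1.0 * 0.25)

    def test_length_invariance_at_fixed_proportions(self, code, uniform_ref):
        counts = {c: float(i % 5 + 1) for i, c in enumerate(code.sense_codons)}
        ref = ReferenceUsage.from_counts(counts)
        base = Counter({"TTT": 2, "TTC": 6, "GGA": 4})
        c1 = cai(base, ref, code).cai
        c2 = cai(Counter({k: 25 * v for k, v in base.items()}), ref, code).cai
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_codon_counts_skips_stops_and_ambiguity(self, code):
        seq = CodingSequence(id="x", nt="ATGNNATAAGGG")
        counts = codon_counts(seq, code)
        assert "TAA" not in counts and all("N" not in c for c in counts)
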