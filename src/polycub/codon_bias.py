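"""Codon-usage-bias statistics: RSCU, ENC, CAI and group comparisons.

RSCU (relative synonymous codon usage) is the observed codon count over
its family-uniform expectation, so 1 means no preference and the values
in a family sum to the family's degeneracy.  ENC is Wright's effective
number of codons built from per-family homozygosities, ranging from 20
(one codon per amino acid) to 61 (uniform usage).  CAI is the Sharp & Li
geometric mean of relative adaptiveness against a reference usage table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seqio import (
    STANDARD_CODE,
    CodingSequence,
    GeneticCode,
    ReferenceUsage,
)

__all__ = [
    "codon_counts",
    "RSCUVector",
    "rscu",
    "classify_representation",
    "group_mean_rscu",
    "RscuDistanceTable",
    "rscu_distance_table",
    "abundant_codons",
    "EncValue",
    "enc",
    "expected_enc",
    "CaiValue",
    "cai",
]

OVER_REPRESENTED = 1.6   # RSCU >= 1.6
UNDER_REPRESENTED = 0.6  # RSCU <= 0.6
ENC_SIGNIFICANT_BIAS = 35.0


def codon_counts(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> Counter:
    """Sense-codon counts; ambiguous codons and stops are dropped."""
    return Counter(
        c for c in seq.codons
        if all(b in "ACGT" for b in c) and not code.is_stop(c)
    )


@dataclass(frozen=True)
class RSCUVector:
    """RSCU over the 59 informative codons (sense minus ATG, TGG).

    Families entirely unused in the input get RSCU 0 for every member
    and are listed in ``empty_families``.
    """

    values: dict[str, float]
    empty_families: tuple[str, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


def rscu(counts: Counter, code: GeneticCode = STANDARD_CODE) -> RSCUVector:
    values: dict[str, float] = {}
    empty: list[str] = []
    for aa, fam in code.families.items():
        deg = len(fam)
        if deg == 1:
            continue
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            empty.append(aa)
            for c in fam:
                values[c] = 0.0
        else:
            for c in fam:
                values[c] = counts.get(c, 0) / (total / deg)
    return RSCUVector(values, tuple(sorted(empty)))


def classify_representation(v: RSCUVector) -> dict[str, str]:
    """over (RSCU >= 1.6), under (RSCU <= 0.6) or neither, per codon."""
    out = {}
    for codon, x in v.values.items():
        if x >= OVER_REPRESENTED:
            out[codon] = "over"
        elif x <= UNDER_REPRESENTED:
            out[codon] = "under"
        else:
            out[codon] = "neither"
    return out


def group_mean_rscu(vectors: list[RSCUVector]) -> RSCUVector:
    """Arithmetic per-codon mean of per-sequence RSCU vectors."""
    if not vectors:
        raise ValueError("empty group")
    codons = vectors[0].values.keys()
    mean = {
        c: sum(v.values[c] for v in vectors) / len(vectors) for c in codons
    }
    return RSCUVector(mean)


@dataclass(frozen=True)
class RscuDistanceTable:
    """Absolute differences of two group-mean RSCU vectors.

    ``avg`` is the mean of ``per_codon`` over the selected codon set;
    the table is symmetric in the pair by construction.
    """

    pair: str
    per_codon: dict[str, float]
    avg: float


def rscu_distance_table(
    mean_a: RSCUVector,
    mean_b: RSCUVector,
    codon_set: list[str],
    pair: str = "",
) -> RscuDistanceTable:
    if not codon_set:
        raise ValueError("empty codon set")
    per = {c: abs(mean_a.values[c] - mean_b.values[c]) for c in codon_set}
    return RscuDistanceTable(pair, per, sum(per.values()) / len(per))


def abundant_codons(
    group_means: dict[str, RSCUVector], threshold: float = OVER_REPRESENTED
) -> list[str]:
    """Codons whose mean RSCU reaches ``threshold`` in at least one group."""
    codons = next(iter(group_means.values())).values.keys()
    return [
        c for c in codons
        if any(v.values[c] >= threshold for v in group_means.values())
    ]


@dataclass(frozen=True)
class EncValue:
    """Wright's effective number of codons with per-class homozygosities."""

    enc: float | None
    class_homozygosity: dict[int, float]

    @property
    def significant_bias(self) -> bool | None:
        if self.enc is None:
            return None
        return self.enc < ENC_SIGNIFICANT_BIAS


def enc(counts: Counter, code: GeneticCode = STANDARD_CODE) -> EncValue:
    """Effective number of codons (Wright 1990).

    Per amino acid with usage n >= 2 the codon homozygosity is
    ``F = (n * sum p_i^2 - 1) / (n - 1)``; class averages of F feed
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, capped at 61.  If the
    three-fold class (Ile) is missing it is imputed as the mean of the
    two- and four-fold averages; any other empty class leaves ENC
    undefined.
    """
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        deg = len(fam)
        if deg == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        f_by_class[deg].append(f)

    fbar: dict[int, float] = {}
    for k, fs in f_by_class.items():
        if fs:
            fbar[k] = sum(fs) / len(fs)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(k not in fbar or fbar[k] <= 0 for k in (2, 3, 4, 6)):
        return EncValue(None, fbar)
    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return EncValue(min(value, 61.0), fbar)


def expected_enc(s: float) -> float:
    """Wright's null ENC at synonymous third-position GC fraction ``s``."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("GC3s fraction must be in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class CaiValue:
    cai: float
    n_codons_used: int


def cai(
    counts: Counter, ref: ReferenceUsage, code: GeneticCode = STANDARD_CODE
) -> CaiValue:
    """Codon adaptation index: geometric mean of w over informative codons.

    ATG, TGG and stop codons are excluded; reference pseudo-counts
    guarantee w > 0 so the log is always finite.
    """
    log_sum = 0.0
    n = 0
    for codon in code.informative_codons:
        k = counts.get(codon, 0)
        if k:
            log_sum += k * math.log(ref.w[codon])
            n += k
    if n == 0:
        raise ValueError("no informative codons")
    return CaiValue(math.exp(log_sum / n), n)


def bias_table(
    seqs: list[CodingSequence],
    ref: ReferenceUsage | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-sequence ENC, CAI and GC3s table (columns id, group, ENC, CAI, GC3s)."""
    from .composition import composition_profile

    rows = []
    for s in seqs:
        counts = codon_counts(s, code)
        e = enc(counts, code)
        row = {
            "id": s.id,
            "group": s.group or "",
            "ENC": e.enc if e.enc is not None else float("nan"),
            "CAI": cai(counts, ref, code).cai if ref is not None else float("nan"),
            "GC3s": composition_profile(s, code).pct_GC3s,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "group", "ENC", "CAI", "GC3s"])
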