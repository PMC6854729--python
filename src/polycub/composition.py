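"""Per-sequence nucleotide and codon-position composition statistics.

Two third-position conventions coexist in the codon-usage literature and
both are computed here: GC3s restricts to third positions of synonymous
codons (Met, Trp and stops excluded; the CodonW convention used for
NC plots), while GC3 runs over all sense codons (the Sueoka convention
used for neutrality plots).  Codons containing ambiguous IUPAC bases are
excluded from all codon-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import STANDARD_CODE, CodingSequence, GeneticCode

__all__ = ["CompositionProfile", "composition_profile", "composition_table"]

COMPOSITION_COLUMNS = [
    "id", "group", "A", "C", "G", "T", "AT", "GC",
    "A3s", "T3s", "G3s", "C3s", "GC3s", "AT3s",
    "GC1", "GC2", "GC3", "GC12", "AT12",
]


@dataclass(frozen=True)
class CompositionProfile:
    """All composition statistics for one coding sequence, in percent."""

    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float
    pct_AT: float
    pct_GC: float
    A3s: float
    T3s: float
    G3s: float
    C3s: float
    pct_GC3s: float
    pct_AT3s: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float
    AT12: float


def _pct_gc(bases: list[str]) -> float:
    return 100.0 * sum(b in "GC" for b in bases) / len(bases)


def composition_profile(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> CompositionProfile:
    """Compute the full composition profile of a validated CDS.

    Whole-sequence percentages run over all unambiguous bases; stop
    codons are excluded from every positional statistic.
    """
    clean = [b for b in seq.nt if b in "ACGT"]
    if not clean or not seq.codons:
        raise ValueError("no codons: empty or fully ambiguous sequence")
    n = len(clean)
    pa = 100.0 * clean.count("A") / n
    pc = 100.0 * clean.count("C") / n
    pg = 100.0 * clean.count("G") / n
    pt = 100.0 * clean.count("T") / n

    sense = [
        c for c in seq.codons
        if all(b in "ACGT" for b in c) and not code.is_stop(c)
    ]
    if not sense:
        raise ValueError("no codons: no unambiguous sense codons")

    # synonymous third positions: drop single-codon families (Met, Trp)
    syn3 = [c[2] for c in sense if code.degeneracy_class[code.codon_to_aa[c]] > 1]
    a3 = 100.0 * syn3.count("A") / len(syn3)
    t3 = 100.0 * syn3.count("T") / len(syn3)
    g3 = 100.0 * syn3.count("G") / len(syn3)
    c3 = 100.0 * syn3.count("C") / len(syn3)

    gc1 = _pct_gc([c[0] for c in sense])
    gc2 = _pct_gc([c[1] for c in sense])
    gc3 = _pct_gc([c[2] for c in sense])

    return CompositionProfile(
        pct_A=pa, pct_C=pc, pct_G=pg, pct_T=pt,
        pct_AT=pa + pt, pct_GC=pg + pc,
        A3s=a3, T3s=t3, G3s=g3, C3s=c3,
        pct_GC3s=g3 + c3, pct_AT3s=a3 + t3,
        GC1=gc1, GC2=gc2, GC3=gc3,
        GC12=(gc1 + gc2) / 2.0, AT12=(200.0 - gc1 - gc2) / 2.0,
    )


def composition_table(
    seqs: list[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """One row per sequence, columns in the fixed pipeline order."""
    rows = []
    for s in seqs:
        p = composition_profile(s, code)
        rows.append({
            "id": s.id, "group": s.group or "",
            "A": p.pct_A, "C": p.pct_C, "G": p.pct_G, "T": p.pct_T,
            "AT": p.pct_AT, "GC": p.pct_GC,
            "A3s": p.A3s, "T3s": p.T3s, "G3s": p.G3s, "C3s": p.C3s,
            "GC3s": p.pct_GC3s, "AT3s": p.pct_AT3s,
            "GC1": p.GC1, "GC2": p.GC2, "GC3": p.GC3,
            "GC12": p.GC12, "AT12": p.AT12,
        })
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)
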