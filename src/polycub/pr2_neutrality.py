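"""Parity-rule-2 coordinates and neutrality-plot regressions.

PR2 examines third-position skew inside the eight fourfold-degenerate
codon boxes (GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN): under strand
symmetry with no selection A3 = T3 and G3 = C3, placing a gene at
(0.5, 0.5).  The neutrality plot regresses GC12 on GC3 across genes;
a slope of 1 is complete neutrality (pure directional mutation
pressure) and 1 - slope is read as the contribution of selection.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .seqio import STANDARD_CODE, CodingSequence, GeneticCode

__all__ = [
    "PR2Coordinates",
    "pr2_coordinates",
    "NeutralityFit",
    "neutrality_fit",
    "FOURFOLD_BOXES",
]

# fourfold-degenerate codon boxes by first two bases; for the sixfold
# amino acids (Leu, Ser, Arg) only the fourfold sub-box enters
FOURFOLD_BOXES = ("GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT")


@dataclass(frozen=True)
class PR2Coordinates:
    """GC bias x = G3/(G3+C3) and AT bias y = A3/(A3+T3) at fourfold sites."""

    x: float | None
    y: float | None
    n_codons: int


def pr2_coordinates(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> PR2Coordinates:
    third = [
        c[2] for c in seq.codons
        if all(b in "ACGT" for b in c) and c[:2] in FOURFOLD_BOXES
    ]
    if not third:
        raise ValueError("undefined coordinates: no fourfold codons")
    a3, t3 = third.count("A"), third.count("T")
    g3, c3 = third.count("G"), third.count("C")
    x = g3 / (g3 + c3) if g3 + c3 else None
    y = a3 / (a3 + t3) if a3 + t3 else None
    return PR2Coordinates(x, y, len(third))


@dataclass(frozen=True)
class NeutralityFit:
    """OLS of GC12 on GC3 with Pearson r and its two-sided p-value."""

    slope: float | None
    intercept: float | None
    r: float
    p: float
    n: int

    @property
    def selection_contribution_pct(self) -> float | None:
        """(1 - slope) * 100, the conventional selection share."""
        if self.slope is None:
            return None
        return (1.0 - self.slope) * 100.0


def neutrality_fit(points: list[tuple[float, float]]) -> NeutralityFit:
    """Fit GC12 ~ GC3 by ordinary least squares.

    ``points`` are (GC3, GC12) pairs.  With zero variance in GC3 the
    slope is undefined and flagged as None.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if max(x) == min(x):
        return NeutralityFit(None, None, float("nan"), float("nan"), len(points))
    res = stats.linregress(x, y)
    return NeutralityFit(res.slope, res.intercept, res.rvalue, res.pvalue, len(points))
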