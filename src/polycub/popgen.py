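"""Alignment-based diversity and neutrality statistics.

Implements the classical frequency-spectrum tests on a multiple
alignment under complete deletion (every column containing a gap or
ambiguous base is discarded): segregating sites S, minimum mutation
count eta, singletons, mean pairwise differences k, per-site diversity
pi, Tajima's D, and Fu & Li's D* and F* (the no-outgroup statistics
with the corrected variance constants), plus Nei-Gojobori counting of
synonymous and nonsynonymous substitutions with Jukes-Cantor
correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

from .seqio import STANDARD_CODE, Alignment, GeneticCode

__all__ = [
    "DiversityStats",
    "diversity_stats",
    "tajima_d",
    "fu_li_tests",
    "NeutralityTests",
    "neutrality_tests",
    "pairwise_nei_gojobori",
    "DnDsResult",
    "group_dnds",
]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class DiversityStats:
    """Summary of variation in an alignment after complete deletion."""

    m: int            # sequences
    n_sites: int      # analysed columns
    S: int            # segregating (polymorphic) columns
    eta: int          # total mutations: sum over columns of (alleles - 1)
    eta_s: int        # singleton mutations
    k: float          # mean pairwise differences (count)
    pi: float         # k / n_sites


def _complete_deletion(aln: Alignment) -> list[str]:
    """Columns with only A/C/G/T in every sequence, as column strings."""
    cols = []
    for j in range(aln.n_cols):
        col = "".join(s[j] for s in aln.seqs)
        if all(b in _VALID for b in col):
            cols.append(col)
    return cols


def diversity_stats(aln: Alignment) -> DiversityStats:
    if aln.n_seqs < 2:
        raise ValueError("insufficient sequences: need m >= 2")
    m = aln.n_seqs
    cols = _complete_deletion(aln)
    n_sites = len(cols)
    S = eta = eta_s = 0
    diff_pairs_total = 0
    n_pairs = m * (m - 1) // 2
    for col in cols:
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        n_alleles = len(counts)
        if n_alleles > 1:
            S += 1
            eta += n_alleles - 1
            singles = sum(1 for v in counts.values() if v == 1)
            eta_s += min(singles, n_alleles - 1)
            same_pairs = sum(v * (v - 1) // 2 for v in counts.values())
            diff_pairs_total += n_pairs - same_pairs
    k = diff_pairs_total / n_pairs
    pi = k / n_sites if n_sites else float("nan")
    return DiversityStats(m, n_sites, S, eta, eta_s, k, pi)


def _harmonics(m: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / (i * i) for i in range(1, m))
    return a1, a2


def tajima_d(stats: DiversityStats) -> float | None:
    """Tajima's D from S and k; None when S = 0."""
    m, S, k = stats.m, stats.S, stats.k
    if S == 0:
        return None
    if m < 4:
        raise ValueError("need m >= 4 for Tajima's D")
    a1, a2 = _harmonics(m)
    b1 = (m + 1.0) / (3.0 * (m - 1.0))
    b2 = 2.0 * (m * m + m + 3.0) / (9.0 * m * (m - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2.0) / (a1 * m) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (k - S / a1) / math.sqrt(var)


def fu_li_tests(stats: DiversityStats) -> tuple[float | None, float | None]:
    """Fu & Li's D* and F* without outgroup (corrected variance constants).

    D* contrasts the total mutation count eta with the singleton count;
    F* contrasts mean pairwise differences k with the singleton count.
    Both are None when S = 0.
    """
    m, eta, eta_s, k = stats.m, stats.eta, stats.eta_s, stats.k
    if stats.S == 0:
        return None, None
    if m < 4:
        raise ValueError("need m >= 4 for Fu & Li tests")
    n = float(m)
    a, b = _harmonics(m)
    a_n1 = a + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * a - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    dn = (cn + (n - 2.0) / ((n - 1.0) ** 2)
          + (2.0 / (n - 1.0)) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2.0) - 1.0 / n))

    v_dstar = (((n / (n - 1.0)) ** 2) * b + a * a * dn
               - 2.0 * (n * a * (a + 1.0)) / ((n - 1.0) ** 2)) / (a * a + b)
    u_dstar = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v_dstar
    num_d = (n / (n - 1.0)) * eta - a * eta_s
    dstar = num_d / math.sqrt(u_dstar * eta + v_dstar * eta * eta)

    v_fstar = (dn + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
               - (2.0 / (n - 1.0)) * (4.0 * b - 6.0 + 8.0 / n)) / (a * a + b)
    u_fstar = ((n / (n - 1.0) + (n + 1.0) / (3.0 * (n - 1.0))
                - 4.0 / (n * (n - 1.0))
                + 2.0 * (n + 1.0) / ((n - 1.0) ** 2) * (a_n1 - 2.0 * n / (n + 1.0)))
               / a) - v_fstar
    num_f = k - ((n - 1.0) / n) * eta_s
    fstar = num_f / math.sqrt(u_fstar * eta + v_fstar * eta * eta)
    return dstar, fstar


@dataclass(frozen=True)
class NeutralityTests:
    tajima_d: float | None
    fu_li_dstar: float | None
    fu_li_fstar: float | None


def neutrality_tests(stats: DiversityStats) -> NeutralityTests:
    d = tajima_d(stats)
    ds, fs = fu_li_tests(stats)
    return NeutralityTests(d, ds, fs)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) synonymous/nonsynonymous counting

def _codon_sites(codon: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Per position the fraction of synonymous one-step changes is taken
    among the changes that do not create a stop codon (mutations to
    stops are disregarded); each position contributes one site, so a
    codon always contributes three sites in total.
    """
    aa = code.codon_to_aa[codon]
    syn_sites = 0.0
    for pos in range(3):
        syn = considered = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(mut):
                continue
            considered += 1
            if code.codon_to_aa[mut] == aa:
                syn += 1
        if considered:
            syn_sites += syn / considered
    return syn_sites, 3.0 - syn_sites


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) difference counts between codons.

    Averaged over all minimal substitution pathways that avoid stop
    codons at intermediate steps; if every pathway passes through a
    stop, all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt) and nxt != c2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    valid = [steps for stop, steps in paths if not stop]
    if not valid:
        valid = [steps for _, steps in paths]
    syn = nsyn = 0.0
    for steps in valid:
        for cur, nxt in steps:
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt]:
                syn += 1.0
            else:
                nsyn += 1.0
    return syn / len(valid), nsyn / len(valid)


def pairwise_nei_gojobori(
    codons1: list[str], codons2: list[str], code: GeneticCode = STANDARD_CODE
) -> tuple[float, float, float, float]:
    """(pN, pS, nonsyn_sites, syn_sites) for one aligned codon pair.

    Codons containing gaps/ambiguity in either sequence, or a stop in
    either, are skipped pairwise; site totals are the means of the two
    sequences' per-codon site counts.
    """
    if len(codons1) != len(codons2):
        raise ValueError("codon sequences differ in length")
    syn_sites = nsyn_sites = 0.0
    syn_diff = nsyn_diff = 0.0
    n_used = 0
    for a, b in zip(codons1, codons2):
        if not (set(a) <= _VALID and set(b) <= _VALID):
            continue
        if code.is_stop(a) or code.is_stop(b):
            continue
        s_a, n_a = _codon_sites(a, code)
        s_b, n_b = _codon_sites(b, code)
        syn_sites += (s_a + s_b) / 2.0
        nsyn_sites += (n_a + n_b) / 2.0
        sd, nd = _pathway_counts(a, b, code)
        syn_diff += sd
        nsyn_diff += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("zero comparable codons")
    pS = syn_diff / syn_sites if syn_sites else float("nan")
    pN = nsyn_diff / nsyn_sites if nsyn_sites else float("nan")
    return pN, pS, nsyn_sites, syn_sites


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 3/4, JC correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class DnDsResult:
    dN: float
    dS: float
    ratio: float | None
    n_pairs: int
    n_excluded: int


def group_dnds(
    aln: Alignment,
    code: GeneticCode = STANDARD_CODE,
    mean_of_ratios: bool = False,
) -> DnDsResult:
    """Group-average Nei-Gojobori dN/dS over all sequence pairs.

    Pairwise pN/pS are Jukes-Cantor corrected; the default estimate is
    the ratio of the average dN to the average dS (the MEGA group
    convention), with a mean-of-ratios variant behind a flag.  Pairs
    with a proportion >= 3/4 are excluded with a warning.
    """
    if aln.n_seqs < 2:
        raise ValueError("insufficient sequences: need m >= 2")
    if aln.n_cols % 3:
        raise ValueError("alignment length not a multiple of 3")
    codon_seqs = [
        [s[i:i + 3] for i in range(0, len(s), 3)] for s in aln.seqs
    ]
    dns, dss = [], []
    excluded = 0
    for s1, s2 in itertools.combinations(codon_seqs, 2):
        pN, pS, _, _ = pairwise_nei_gojobori(s1, s2, code)
        try:
            dns.append(_jukes_cantor(pN))
            dss.append(_jukes_cantor(pS))
        except ValueError:
            excluded += 1
            warnings.warn("pair with p >= 3/4 excluded from dN/dS")
    if not dns:
        raise ValueError("no usable pairs for dN/dS")
    dN = sum(dns) / len(dns)
    dS = sum(dss) / len(dss)
    if mean_of_ratios:
        ratios = [n / s for n, s in zip(dns, dss) if s > 0]
        ratio = sum(ratios) / len(ratios) if ratios else None
    else:
        ratio = dN / dS if dS > 0 else None
    return DnDsResult(dN, dS, ratio, len(dns), excluded)
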