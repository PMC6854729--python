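"""Seed-reproducible synthetic data with known parameters.

Two generators: (1) codon sequences drawn codon-by-codon from
per-amino-acid frequencies and within-family codon preferences, with an
optional GC3s target reached by exponentially tilting third-position
G/C; (2) neutral finite-sites alignments from the standard coalescent
with Jukes-Cantor mutation at a known scaled mutation rate theta, so
the frequency-spectrum statistics have exact null expectations
(E[S] = theta * a1, E[k] = theta).

All randomness flows through an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import yaml
from scipy.optimize import brentq

from .seqio import STANDARD_CODE, Alignment, CodingSequence, GeneticCode

__all__ = [
    "SyntheticSpec",
    "generate_codon_sequences",
    "NeutralSimSpec",
    "simulate_neutral_alignment",
]


def _uniform_prefs(code: GeneticCode) -> dict[str, dict[str, float]]:
    return {
        aa: {c: 1.0 / len(fam) for c in fam}
        for aa, fam in code.families.items()
    }


@dataclass
class SyntheticSpec:
    """Parameters for the codon-sequence generator.

    ``aa_freqs`` defaults to uniform over the 20 amino acids and
    ``codon_prefs`` to uniform within every synonymous family (the
    no-selection null of the NC plot).  ``gc3_target`` is the desired
    expected GC3s fraction; None leaves preferences untouched.
    """

    n_seqs: int = 10
    n_codons: int = 300
    seed: int = 0
    aa_freqs: dict[str, float] | None = None
    codon_prefs: dict[str, dict[str, float]] | None = None
    gc3_target: float | None = None

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        return cls(**yaml.safe_load(text))

    def resolve(self, code: GeneticCode = STANDARD_CODE):
        aa_freqs = self.aa_freqs or {aa: 1.0 / len(code.families)
                                     for aa in code.families}
        prefs = self.codon_prefs or _uniform_prefs(code)
        for name, vec in [("aa_freqs", aa_freqs), *(("codon_prefs", p) for p in prefs.values())]:
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        return aa_freqs, prefs


def _tilt_prefs(
    aa_freqs: dict[str, float],
    prefs: dict[str, dict[str, float]],
    target: float,
    code: GeneticCode,
) -> dict[str, dict[str, float]]:
    """Tilt family codon preferences by exp(lam * GC3 indicator).

    ``lam`` is solved so the expected GC3s over synonymous codons
    equals ``target``.  Raises when the target is outside the reachable
    range of the given preferences.
    """

    syn_aas = [aa for aa in prefs if code.degeneracy_class[aa] > 1]
    syn_mass = sum(aa_freqs[aa] for aa in syn_aas)

    def expected_gc3s(lam: float) -> float:
        num = 0.0
        for aa in syn_aas:
            fam = prefs[aa]
            wts = {c: p * np.exp(lam * (c[2] in "GC")) for c, p in fam.items()}
            z = sum(wts.values())
            num += aa_freqs[aa] * sum(w for c, w in wts.items() if c[2] in "GC") / z
        return num / syn_mass

    lo, hi = expected_gc3s(-40.0), expected_gc3s(40.0)
    if not (lo - 1e-9 <= target <= hi + 1e-9):
        raise ValueError(
            f"unreachable target: GC3s {target} outside [{lo:.4f}, {hi:.4f}]"
        )
    lam = brentq(lambda t: expected_gc3s(t) - target, -40.0, 40.0, xtol=1e-12)
    tilted = {}
    for aa, fam in prefs.items():
        wts = {c: p * np.exp(lam * (c[2] in "GC")) for c, p in fam.items()}
        z = sum(wts.values())
        tilted[aa] = {c: w / z for c, w in wts.items()}
    return tilted


def generate_codon_sequences(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> list[CodingSequence]:
    """Draw i.i.d. codons: amino acid first, then codon within family."""
    aa_freqs, prefs = spec.resolve(code)
    if spec.gc3_target is not None:
        prefs = _tilt_prefs(aa_freqs, prefs, spec.gc3_target, code)
    rng = np.random.default_rng(spec.seed)
    aas = sorted(aa_freqs)
    aa_p = np.array([aa_freqs[a] for a in aas])
    fam_codons = {aa: sorted(prefs[aa]) for aa in aas}
    fam_p = {aa: np.array([prefs[aa][c] for c in fam_codons[aa]]) for aa in aas}
    out = []
    for i in range(spec.n_seqs):
        drawn_aas = rng.choice(aas, size=spec.n_codons, p=aa_p)
        codons = [
            fam_codons[aa][rng.choice(len(fam_codons[aa]), p=fam_p[aa])]
            for aa in drawn_aas
        ]
        out.append(CodingSequence(id=f"syn_{i}", nt="".join(codons)))
    return out


@dataclass
class NeutralSimSpec:
    """Parameters for the neutral coalescent simulator.

    ``theta`` is the locus-wide scaled mutation rate (E[k] = theta and
    E[S] = theta * a1 under the infinite-sites approximation); the
    mutation model is finite-sites Jukes-Cantor over ``n_sites``.
    """

    m: int = 20
    n_sites: int = 1000
    theta: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.m < 2:
            raise ValueError("m must be >= 2")

    @classmethod
    def from_yaml(cls, text: str) -> "NeutralSimSpec":
        return cls(**yaml.safe_load(text))


def simulate_neutral_alignment(spec: NeutralSimSpec) -> Alignment:
    """Standard-coalescent genealogy + Poisson JC mutations over n_sites.

    The coalescent engine is msprime with haploid samples on the
    standard time scale (pairwise coalescence rate 1); mutations fall
    at total rate theta/2 per unit of scaled branch length, uniformly
    over sites, changing the base to one of the other three.
    """
    rng = np.random.default_rng(spec.seed)
    seed_anc, seed_mut = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=spec.m,
        ploidy=1,
        population_size=0.5,
        sequence_length=spec.n_sites,
        discrete_genome=True,
        random_seed=seed_anc,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=spec.theta / spec.n_sites,
        model=msprime.JC69(),
        random_seed=seed_mut,
    )
    base = rng.choice(list("ACGT"), size=spec.n_sites)
    seqs = np.tile(base, (spec.m, 1))
    for var in mts.variants():
        j = int(var.site.position)
        alleles = var.alleles
        for i, g in enumerate(var.genotypes):
            seqs[i, j] = alleles[g]
    return Alignment(
        ids=[f"sim_{i}" for i in range(spec.m)],
        seqs=["".join(row) for row in seqs],
    )
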