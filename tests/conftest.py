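"""Shared fixtures: genetic code, random CDS factories, GenBank builders."""

from __future__ import annotations

import numpy as np
import pytest

from polycub.seqio import STANDARD_CODE, CodingSequence


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def random_cds_factory(rng, code):
    """Random stop-free CDS of a given codon count."""

    sense = list(code.sense_codons)

    def make(n_codons: int, seed: int | None = None) -> CodingSequence:
        local = np.random.default_rng(seed) if seed is not None else rng
        codons = local.choice(sense, size=n_codons)
        return CodingSequence(id="rand", nt="".join(codons))

    return make


def genbank_record(seq: str, location: str, codon_start: int = 1,
                   accession: str = "TEST00000001") -> str:
    """Render a minimal GenBank flat file with one CDS feature."""
    lines = [
        f"LOCUS       {accession:<16}{len(seq):>12} bp    DNA     linear   VRL 01-JAN-2000",
        "DEFINITION  synthetic test record.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
        f"     CDS             {location}",
        f"                     /codon_start={codon_start}",
        '                     /product="large T antigen"',
        "ORIGIN",
    ]
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def make_genbank():
    return genbank_record


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]
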