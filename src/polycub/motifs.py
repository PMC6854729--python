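"""Translation, degenerate-motif scanning and domain sub-CDS extraction.

The LXCXE pentapeptide (Rb-family binding) and the DnaJ / superfamily-3
helicase domains of the polyomavirus large T antigen are located by
1-based inclusive protein coordinates; domain coordinates are consumed
from a tabulated annotation file rather than recomputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import STANDARD_CODE, CodingSequence, GeneticCode

__all__ = [
    "MotifHit",
    "DomainAnnotation",
    "translate_cds",
    "scan_motif",
    "extract_domain_cds",
    "read_domain_table",
]


class PrematureStopError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    aa_start: int  # 1-based inclusive
    aa_end: int
    peptide: str


@dataclass(frozen=True)
class DomainAnnotation:
    seq_id: str
    domain_name: str  # DnaJ or helicase
    aa_start: int     # 1-based inclusive
    aa_end: int

    @property
    def nt_length(self) -> int:
        return 3 * (self.aa_end - self.aa_start + 1)


def translate_cds(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> str:
    """Standard-code translation; trailing stop dropped, internal stop raises."""
    codons = seq.codons
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    protein = []
    for i, c in enumerate(codons):
        if any(b not in "ACGT" for b in c):
            protein.append("X")
            continue
        aa = code.codon_to_aa[c]
        if aa == "*":
            raise PrematureStopError(f"premature stop at codon {i + 1}")
        protein.append(aa)
    return "".join(protein)


def scan_motif(protein: str, pattern: str = "LxCxE") -> list[MotifHit]:
    """All (possibly overlapping) matches of a degenerate peptide pattern.

    ``x`` (either case) matches any residue; other letters match
    themselves.  Coordinates are 1-based inclusive, reported left to
    right.
    """
    regex = "".join("." if ch in "xX" else re.escape(ch.upper()) for ch in pattern)
    hits = []
    for m in re.finditer(f"(?=({regex}))", protein):
        start = m.start() + 1
        hits.append(MotifHit(pattern, start, start + len(pattern) - 1, m.group(1)))
    return hits


def extract_domain_cds(
    seq: CodingSequence, ann: DomainAnnotation
) -> CodingSequence:
    """Nucleotide sub-CDS spanning protein residues aa_start..aa_end."""
    n_codons = len(seq.codons)
    if not (1 <= ann.aa_start <= ann.aa_end <= n_codons):
        raise ValueError(
            f"invalid domain: {ann.aa_start}..{ann.aa_end} outside 1..{n_codons}"
        )
    nt = seq.nt[3 * (ann.aa_start - 1):3 * ann.aa_end]
    return CodingSequence(
        id=f"{seq.id}|{ann.domain_name}",
        nt=nt,
        accession=seq.accession,
        group=seq.group,
    )


def read_domain_table(text: str) -> list[DomainAnnotation]:
    """Parse the domain-annotation TSV (columns id, accession, domain, aa_start, aa_end, nt_length).

    Every row is checked against the identity
    ``3 * (aa_end - aa_start + 1) == nt_length``; a failing row raises
    rather than being silently corrected.
    """
    anns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        vid, acc, domain = fields[0], fields[1], fields[2]
        start, end = int(fields[3]), int(fields[4])
        ann = DomainAnnotation(seq_id=acc, domain_name=domain,
                               aa_start=start, aa_end=end)
        if len(fields) > 5 and fields[5]:
            if ann.nt_length != int(fields[5]):
                raise ValueError(
                    f"inconsistent domain row for {vid}/{acc} {domain}: "
                    f"3*(end-start+1)={ann.nt_length} != {fields[5]}"
                )
        anns.append(ann)
    return anns
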