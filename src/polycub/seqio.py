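"""Sequence and reference-table I/O.

Reads GenBank flat files (spliced CDS extraction honouring ``join``,
``complement`` and ``codon_start``), plain and aligned FASTA, Kazusa-style
codon usage tables, and the TSV side tables (host-group assignments,
domain coordinates) that drive the pipeline.  The internal nucleotide
alphabet is DNA; RNA input is normalised on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneticCode",
    "CodingSequence",
    "ReferenceUsage",
    "CdsReport",
    "STANDARD_CODE",
    "read_genbank_cds",
    "read_fasta_alignment",
    "read_fasta",
    "write_fasta",
    "read_reference_usage",
    "read_group_table",
    "validate_cds",
]

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

HOST_GROUPS = frozenset("AFHMP")


class FeatureNotFoundError(KeyError):
    """No CDS feature matched the selector."""


class MalformedLocationError(ValueError):
    """Feature coordinates fall outside the record."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with synonymous-family structure.

    ``families`` partitions the sense codons by encoded amino acid;
    six-codon amino acids (Leu, Ser, Arg) are kept as single six-fold
    families, following the CodonW convention used throughout codon
    usage analysis.
    """

    table_id: int
    codon_to_aa: dict[str, str]  # 64 codons -> aa letter or '*'
    families: dict[str, tuple[str, ...]]  # aa -> sense codons
    degeneracy_class: dict[str, int]  # aa -> 1,2,3,4 or 6

    @classmethod
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: table.forward_table.get(c, "*") for c in CODONS}
        families: dict[str, list[str]] = {}
        for codon in CODONS:
            aa = codon_to_aa[codon]
            if aa != "*":
                families.setdefault(aa, []).append(codon)
        fams = {aa: tuple(cods) for aa, cods in families.items()}
        deg = {aa: len(cods) for aa, cods in fams.items()}
        return cls(table_id, codon_to_aa, fams, deg)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != "*")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] == "*")

    @property
    def informative_codons(self) -> tuple[str, ...]:
        """Sense codons excluding the single-codon families (ATG, TGG)."""
        return tuple(
            c for c in self.sense_codons
            if self.degeneracy_class[self.codon_to_aa[c]] > 1
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


STANDARD_CODE = GeneticCode.from_table_id(1)


@dataclass
class CodingSequence:
    """One extracted coding sequence, codonised.

    ``group`` is the host group (A avian, F fish, H human, M non-primate
    mammal, P non-human primate) or None when unassigned.
    """

    id: str
    nt: str
    accession: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.nt = _normalize_nt(self.nt)
        if self.group is not None and self.group not in HOST_GROUPS:
            raise ValueError(f"unknown host group {self.group!r}")

    @property
    def codons(self) -> list[str]:
        n = len(self.nt) - len(self.nt) % 3
        return [self.nt[i:i + 3] for i in range(0, n, 3)]

    def __len__(self) -> int:
        return len(self.nt)


def _normalize_nt(nt: str) -> str:
    return nt.upper().replace("U", "T")


@dataclass(frozen=True)
class ReferenceUsage:
    """Reference codon usage and Sharp & Li relative adaptiveness w.

    ``w[c] = count(c) / max(count over synonyms of c)``; zero counts are
    replaced with a 0.5 pseudo-count before computing w so log w is
    always finite.
    """

    counts: dict[str, float]
    w: dict[str, float]

    @classmethod
    def from_counts(
        cls, counts: dict[str, float], code: GeneticCode = STANDARD_CODE,
        pseudo: float = 0.5,
    ) -> "ReferenceUsage":
        adj = {
            c: (counts[c] if counts[c] > 0 else pseudo)
            for c in code.sense_codons
        }
        w: dict[str, float] = {}
        for cods in code.families.values():
            top = max(adj[c] for c in cods)
            for c in cods:
                w[c] = adj[c] / top
        return cls(dict(counts), w)


@dataclass(frozen=True)
class CdsReport:
    """Validation report for one coding sequence (report-only, no raise)."""

    id: str
    length_ok: bool
    internal_stop_positions: tuple[int, ...]
    ambiguity_count: int

    @property
    def ok(self) -> bool:
        return self.length_ok and not self.internal_stop_positions


def read_genbank_cds(
    record: str | io.TextIOBase,
    selector: Callable | None = None,
    *,
    group: str | None = None,
) -> CodingSequence:
    """Extract the spliced CDS from a GenBank flat file.

    ``selector`` is a predicate over Biopython ``SeqFeature`` objects; by
    default the first (typically only annotated) CDS feature is taken.
    ``join``/``complement`` location operators and ``codon_start`` are
    honoured; coordinates are 1-based inclusive in the flat file and
    validated against the record length.
    """
    handle = io.StringIO(record) if isinstance(record, str) else record
    rec: SeqRecord = SeqIO.read(handle, "genbank")
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if selector is not None:
        cds_feats = [f for f in cds_feats if selector(f)]
    if not cds_feats:
        raise FeatureNotFoundError("feature not found: no CDS matched selector")
    feat = cds_feats[0]
    if int(feat.location.start) < 0 or int(feat.location.end) > len(rec.seq):
        raise MalformedLocationError(
            f"malformed location: {feat.location} outside record of "
            f"length {len(rec.seq)}"
        )
    nt = str(feat.location.extract(rec.seq))
    codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
    if codon_start > 1:
        nt = nt[codon_start - 1:]
    return CodingSequence(id=rec.id, nt=nt, accession=rec.id, group=group)


@dataclass
class Alignment:
    """An ordered set of equal-length sequences."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("not an alignment: ragged sequence lengths")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))


def read_fasta(text: str | io.TextIOBase) -> list[tuple[str, str]]:
    handle = io.StringIO(text) if isinstance(text, str) else text
    return [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]


def read_fasta_alignment(text: str | io.TextIOBase) -> Alignment:
    """Read an aligned FASTA; ragged records raise ``not an alignment``."""
    pairs = read_fasta(text)
    return Alignment([p[0] for p in pairs], [p[1] for p in pairs])


def write_fasta(records: Iterable[tuple[str, str]], handle) -> None:
    own = isinstance(handle, str)
    out = open(handle, "w") if own else handle
    try:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            out,
            "fasta",
        )
    finally:
        if own:
            out.close()


def read_reference_usage(
    text: str, code: GeneticCode = STANDARD_CODE
) -> ReferenceUsage:
    """Parse a Kazusa Codon Usage Database style table.

    The format is whitespace-separated groups of ``codon frequency
    (count)`` or ``codon frequency`` fields laid out four codons per
    line; RNA codons are normalised to DNA.  All 64 codons must be
    present.
    """
    counts: dict[str, float] = {}
    tokens = text.replace("(", " ").replace(")", " ").split()
    i = 0
    while i < len(tokens):
        tok = _normalize_nt(tokens[i])
        if len(tok) == 3 and all(b in "ACGT" for b in tok):
            # codon followed by per-1000 frequency and optionally a count
            if i + 2 < len(tokens) and _is_number(tokens[i + 1]) and _is_number(tokens[i + 2]):
                counts[tok] = float(tokens[i + 2])
                i += 3
            elif i + 1 < len(tokens) and _is_number(tokens[i + 1]):
                counts[tok] = float(tokens[i + 1])
                i += 2
            else:
                i += 1
        else:
            i += 1
    missing = [c for c in CODONS if c not in counts]
    if missing:
        raise ValueError(f"incomplete table: missing codons {missing[:5]}...")
    return ReferenceUsage.from_counts(counts, code)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_group_table(text: str) -> dict[str, dict[str, str]]:
    """Read the TSV of host-group assignments (columns id, accession, group).

    Returns a map accession -> {"id": ..., "group": ...}.
    """
    table: dict[str, dict[str, str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "id":
            continue
        vid, acc, grp = parts[0], parts[1], parts[2]
        if grp not in HOST_GROUPS:
            raise ValueError(f"unknown host group {grp!r} for {acc}")
        table[acc] = {"id": vid, "group": grp}
    return table


def validate_cds(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> CdsReport:
    """Report length, internal-stop and ambiguity problems (never raises)."""
    length_ok = len(seq.nt) % 3 == 0
    codons = seq.codons
    internal = tuple(
        i + 1
        for i, c in enumerate(codons[:-1])
        if all(b in "ACGT" for b in c) and code.is_stop(c)
    )
    ambig = sum(1 for b in seq.nt if b not in "ACGT")
    return CdsReport(seq.id, length_ok, internal, ambig)
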