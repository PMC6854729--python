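"""Access to the packaged reference tables.

The package ships three small text tables: the host-group assignment of
the 86 polyomavirus reference sequences, the DnaJ/helicase domain
coordinates with their LXCXE motif positions, and a human reference
codon-usage table for CAI.
"""

from __future__ import annotations

from importlib import resources

from .motifs import DomainAnnotation, read_domain_table
from .seqio import ReferenceUsage, read_group_table, read_reference_usage

__all__ = [
    "load_host_groups",
    "load_domain_annotations",
    "load_lxcxe_table",
    "load_human_reference_usage",
]


def _read(name: str) -> str:
    return (resources.files("polycub") / "data" / name).read_text()


def load_host_groups() -> dict[str, dict[str, str]]:
    """Accession -> {id, group} for the 86 reference genomes."""
    return read_group_table(_read("host_groups.tsv"))


def load_domain_annotations() -> list[DomainAnnotation]:
    """DnaJ and helicase protein coordinates (validated on load)."""
    return read_domain_table(_read("domains.tsv"))


def load_lxcxe_table() -> list[dict[str, str | int]]:
    """Tabulated LXCXE motif positions and peptides."""
    rows = []
    for line in _read("lxcxe_motifs.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        vid, acc, start, end, pep = line.split("\t")
        rows.append({
            "id": vid, "accession": acc,
            "aa_start": int(start), "aa_end": int(end), "peptide": pep,
        })
    return rows


def load_human_reference_usage() -> ReferenceUsage:
    """Bundled Homo sapiens codon-usage reference for CAI."""
    return read_reference_usage(_read("homo_sapiens_codon_usage.txt"))
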