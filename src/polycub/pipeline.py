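"""Orchestration of the full per-region, per-group analysis.

Given coding sequences (GenBank flat files or a CDS FASTA), host-group
assignments and domain coordinates, runs every stage — composition,
ENC/CAI, RSCU with group means and pairwise distances, PR2, neutrality
regressions, correspondence analysis, alignment population statistics
and motif scanning — and writes fixed-schema TSVs plus a run manifest.
Missing inputs skip their stage with a logged reason, never silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coa import correspondence_analysis
from .codon_bias import (
    abundant_codons,
    bias_table,
    cai,
    codon_counts,
    enc,
    group_mean_rscu,
    rscu,
    rscu_distance_table,
)
from .composition import composition_profile, composition_table
from .datasets import (
    load_domain_annotations,
    load_host_groups,
    load_human_reference_usage,
)
from .motifs import extract_domain_cds, scan_motif, translate_cds
from .popgen import diversity_stats, group_dnds, neutrality_tests
from .pr2_neutrality import neutrality_fit, pr2_coordinates
from .seqio import (
    STANDARD_CODE,
    CodingSequence,
    read_fasta,
    read_fasta_alignment,
    read_genbank_cds,
    read_group_table,
    read_reference_usage,
)

log = logging.getLogger("polycub")

REGIONS = ("LT-Ag", "DnaJ", "helicase")
GROUPS = ("A", "F", "H", "M", "P")


@dataclass
class PipelineConfig:
    out_dir: Path
    genbank_dir: Path | None = None
    cds_fasta: Path | None = None
    groups_tsv: Path | None = None       # default: packaged table
    domains_tsv: Path | None = None      # default: packaged table
    ref_usage: Path | None = None        # default: packaged human table
    alignments_dir: Path | None = None
    regions: tuple[str, ...] = REGIONS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("out_dir", "genbank_dir", "cds_fasta", "groups_tsv",
                    "domains_tsv", "ref_usage", "alignments_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    """Render floats at 5 significant digits for byte-stable diffs."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda x: "" if pd.isna(x) else f"{x:.5g}"
            )
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    _fmt(df).to_csv(path, sep="\t", index=False)


def _is_ltag_cds(feature) -> bool:
    quals = " ".join(
        v.lower() for key in ("product", "gene", "note")
        for v in feature.qualifiers.get(key, [])
    )
    return "large t" in quals or "lt-ag" in quals or "ltag" in quals


def load_sequences(cfg: PipelineConfig) -> list[CodingSequence]:
    """Load CDS from GenBank files or FASTA and attach host groups."""
    groups = (
        read_group_table(cfg.groups_tsv.read_text())
        if cfg.groups_tsv else load_host_groups()
    )
    seqs: list[CodingSequence] = []
    if cfg.genbank_dir is not None:
        for path in sorted(cfg.genbank_dir.glob("*.gb*")):
            try:
                cds = read_genbank_cds(path.read_text(), _is_ltag_cds)
            except KeyError:
                cds = read_genbank_cds(path.read_text())  # fall back: first CDS
            meta = groups.get(cds.accession)
            if meta:
                cds.id, cds.group = meta["id"], meta["group"]
            seqs.append(cds)
    elif cfg.cds_fasta is not None:
        for rid, nt in read_fasta(cfg.cds_fasta.read_text()):
            meta = groups.get(rid)
            seqs.append(CodingSequence(
                id=meta["id"] if meta else rid, nt=nt, accession=rid,
                group=meta["group"] if meta else None,
            ))
    else:
        raise ValueError("no sequence input: set genbank_dir or cds_fasta")
    return sorted(seqs, key=lambda s: s.id)


def region_sequences(
    seqs: list[CodingSequence], region: str, cfg: PipelineConfig
) -> list[CodingSequence]:
    if region == "LT-Ag":
        return seqs
    from .motifs import read_domain_table

    anns = (
        read_domain_table(cfg.domains_tsv.read_text())
        if cfg.domains_tsv else load_domain_annotations()
    )
    by_acc = {a.seq_id: a for a in anns if a.domain_name == region}
    out = []
    for s in seqs:
        ann = by_acc.get(s.accession)
        if ann is None:
            continue
        out.append(extract_domain_cds(s, ann))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "polycub_version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "inputs": {},
        "stages": {},
    }
    for name in ("genbank_dir", "cds_fasta", "groups_tsv", "domains_tsv",
                 "ref_usage", "alignments_dir"):
        p = getattr(cfg, name)
        if p is not None and Path(p).is_file():
            digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            manifest["inputs"][name] = {"path": str(p), "sha256": digest}
        elif p is not None:
            manifest["inputs"][name] = {"path": str(p)}

    try:
        seqs = load_sequences(cfg)
    except ValueError as exc:
        log.error("sequence loading failed: %s", exc)
        manifest["stages"]["load"] = f"failed: {exc}"
        raise

    ref = (
        read_reference_usage(Path(cfg.ref_usage).read_text())
        if cfg.ref_usage else load_human_reference_usage()
    )

    for region in cfg.regions:
        rseqs = region_sequences(seqs, region, cfg)
        tag = region.replace("-", "")
        if not rseqs:
            log.warning("region %s: no sequences, skipped", region)
            manifest["stages"][f"{region}"] = "skipped: no sequences"
            continue
        _run_region(rseqs, region, tag, ref, out, manifest)

    _run_popgen(cfg, out, manifest)
    _run_motifs(seqs, out, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_region(rseqs, region, tag, ref, out: Path, manifest) -> None:
    code = STANDARD_CODE
    _write(composition_table(rseqs), out / f"composition_{tag}.tsv")

    bias = bias_table(rseqs, ref)
    _write(bias, out / f"enc_cai_{tag}.tsv")
    summary = (
        bias[bias.group != ""]
        .groupby("group")[["ENC", "CAI", "GC3s"]]
        .agg(["mean", "min", "max"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    _write(summary.reset_index(), out / f"enc_cai_summary_{tag}.tsv")

    vectors = {s.id: rscu(codon_counts(s, code), code) for s in rseqs}
    codons = sorted(next(iter(vectors.values())).values)
    mat = pd.DataFrame(
        [[vectors[s.id].values[c] for c in codons] for s in rseqs],
        index=[s.id for s in rseqs], columns=codons,
    )
    mat.insert(0, "group", [s.group or "" for s in rseqs])
    _write(mat.reset_index(names="id"), out / f"rscu_{tag}.tsv")

    by_group: dict[str, list] = {}
    for s in rseqs:
        if s.group:
            by_group.setdefault(s.group, []).append(vectors[s.id])
    means = {g: group_mean_rscu(v) for g, v in sorted(by_group.items())}
    if means:
        gm = pd.DataFrame(
            [[m.values[c] for c in codons] for m in means.values()],
            index=list(means), columns=codons,
        )
        _write(gm.reset_index(names="group"), out / f"rscu_group_means_{tag}.tsv")
        if len(means) >= 2:
            # default distance-table set; fall back to all codons when no
            # codon reaches the over-representation threshold in any group
            codon_set = abundant_codons(means) or codons
            rows = []
            glist = list(means)
            for i, ga in enumerate(glist):
                for gb in glist[i + 1:]:
                    d = rscu_distance_table(
                        means[ga], means[gb], codon_set, f"{ga}-{gb}"
                    )
                    rows.append({
                        "pair": d.pair,
                        **{c: d.per_codon[c] for c in codon_set},
                        "Avg": d.avg,
                    })
            _write(pd.DataFrame(rows), out / f"rscu_distances_{tag}.tsv")

    pr2_rows = []
    for s in rseqs:
        c = pr2_coordinates(s, code)
        pr2_rows.append({
            "id": s.id, "group": s.group or "",
            "x": c.x if c.x is not None else float("nan"),
            "y": c.y if c.y is not None else float("nan"),
        })
    _write(pd.DataFrame(pr2_rows), out / f"pr2_{tag}.tsv")

    comp = {s.id: composition_profile(s, code) for s in rseqs}
    fits = []
    groups_here = sorted({s.group for s in rseqs if s.group})
    for gname, members in [("All", rseqs)] + [
        (g, [s for s in rseqs if s.group == g]) for g in groups_here
    ]:
        pts = [(comp[s.id].GC3, comp[s.id].GC12) for s in members]
        if len(pts) < 2:
            log.warning("neutrality %s/%s: <2 points, skipped", region, gname)
            continue
        f = neutrality_fit(pts)
        fits.append({
            "group": gname,
            "slope": f.slope if f.slope is not None else float("nan"),
            "intercept": f.intercept if f.intercept is not None else float("nan"),
            "r": f.r, "p": f.p, "n": f.n,
        })
    _write(pd.DataFrame(fits), out / f"neutrality_{tag}.tsv")

    res = correspondence_analysis(
        mat[codons].to_numpy(), row_ids=list(mat.index), col_ids=codons
    )
    n_axes = min(4, res.row_coords.shape[1])
    rc = pd.DataFrame(
        res.row_coords[:, :n_axes],
        columns=[f"axis{i + 1}" for i in range(n_axes)],
    )
    rc.insert(0, "id", res.row_ids)
    rc.insert(1, "group", [
        next((s.group or "" for s in rseqs if s.id == rid), "")
        for rid in res.row_ids
    ])
    _write(rc, out / f"coa_rows_{tag}.tsv")
    cc = pd.DataFrame(
        res.col_coords[:, :n_axes],
        columns=[f"axis{i + 1}" for i in range(n_axes)],
    )
    cc.insert(0, "codon", res.col_ids)
    _write(cc, out / f"coa_columns_{tag}.tsv")
    _write(
        pd.DataFrame({
            "axis": np.arange(1, len(res.inertia) + 1),
            "inertia": res.inertia,
            "inertia_pct": res.inertia_pct,
        }),
        out / f"coa_inertia_{tag}.tsv",
    )
    manifest["stages"][region] = "ok"


def _run_popgen(cfg: PipelineConfig, out: Path, manifest) -> None:
    if cfg.alignments_dir is None or not Path(cfg.alignments_dir).is_dir():
        reason = "skipped: alignments_dir not provided"
        log.warning("popgen %s", reason)
        manifest["stages"]["popgen"] = reason
        return
    rows = []
    for path in sorted(Path(cfg.alignments_dir).glob("*.fasta")):
        stem = path.stem
        region, _, group = stem.rpartition("_")
        aln = read_fasta_alignment(path.read_text())
        if aln.n_seqs < 2:
            log.warning("popgen %s: <2 sequences, skipped", stem)
            continue
        ds = diversity_stats(aln)
        row = {
            "region": region or stem, "group": group, "m": ds.m,
            "n": ds.n_sites, "S": ds.S, "eta": ds.eta,
            "k": ds.k, "pi": ds.pi,
            "TajimaD": float("nan"), "FuLiDstar": float("nan"),
            "FuLiFstar": float("nan"), "dNdS": float("nan"),
        }
        if ds.m >= 4 and ds.S > 0:
            nt = neutrality_tests(ds)
            row["TajimaD"] = nt.tajima_d
            row["FuLiDstar"] = nt.fu_li_dstar
            row["FuLiFstar"] = nt.fu_li_fstar
        if aln.n_cols % 3 == 0:
            try:
                dnds = group_dnds(aln)
                if dnds.ratio is not None:
                    row["dNdS"] = dnds.ratio
            except ValueError as exc:
                log.warning("popgen %s: dN/dS undefined (%s)", stem, exc)
        rows.append(row)
    if rows:
        _write(pd.DataFrame(rows), out / "popgen.tsv")
        manifest["stages"]["popgen"] = "ok"
    else:
        manifest["stages"]["popgen"] = "skipped: no usable alignments"


def _run_motifs(seqs, out: Path, manifest) -> None:
    rows = []
    for s in seqs:
        try:
            protein = translate_cds(s)
        except ValueError as exc:
            log.warning("motif %s: %s", s.id, exc)
            continue
        for hit in scan_motif(protein, "LxCxE"):
            rows.append({
                "id": s.id, "pattern": hit.pattern,
                "aa_start": hit.aa_start, "aa_end": hit.aa_end,
                "peptide": hit.peptide,
                "encoding_nt": s.nt[3 * (hit.aa_start - 1):3 * hit.aa_end],
            })
    _write(
        pd.DataFrame(
            rows, columns=["id", "pattern", "aa_start", "aa_end",
                           "peptide", "encoding_nt"],
        ),
        out / "motifs.tsv",
    )
    manifest["stages"]["motifs"] = "ok"
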