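#!/usr/bin/env python
"""One-time download of the 86 polyomavirus RefSeq GenBank records.

Fetches every accession in the packaged host-group table from NCBI
E-utilities and stores the flat files under data/refseq/, where the
reference-data acceptance tests and scripts/acceptance.py expect them.
Requires network access; all downstream computation is offline.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

from polycub.datasets import load_host_groups

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "refseq"


def fetch_batch(accessions: list[str]) -> str:
    params = urllib.parse.urlencode({
        "db": "nuccore",
        "id": ",".join(accessions),
        "rettype": "gb",
        "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=120) as resp:
        return resp.read().decode()


def split_records(text: str) -> list[str]:
    records = []
    current: list[str] = []
    for line in text.splitlines():
        current.append(line)
        if line.strip() == "//":
            records.append("\n".join(current) + "\n")
            current = []
    return records


def record_version(record: str) -> str | None:
    for line in record.splitlines():
        if line.startswith("VERSION"):
            return line.split()[1]
    return None


def main() -> int:
    accessions = sorted(load_host_groups())
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    missing = [a for a in accessions if not (OUT_DIR / f"{a}.gb").exists()]
    print(f"{len(missing)} of {len(accessions)} records to fetch", file=sys.stderr)
    for i in range(0, len(missing), 20):
        batch = missing[i:i + 20]
        text = fetch_batch(batch)
        for record in split_records(text):
            version = record_version(record)
            if version in batch:
                (OUT_DIR / f"{version}.gb").write_text(record)
        print(f"fetched {min(i + 20, len(missing))}/{len(missing)}", file=sys.stderr)
        time.sleep(0.5)  # NCBI rate courtesy
    still = [a for a in accessions if not (OUT_DIR / f"{a}.gb").exists()]
    if still:
        print(f"WARNING: {len(still)} records not retrieved: {still}", file=sys.stderr)
        return 1
    print(f"all {len(accessions)} records in {OUT_DIR}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
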