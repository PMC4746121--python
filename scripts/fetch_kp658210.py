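#!/usr/bin/env python
"""Fetch the deposited CnmeGV genome (GenBank accession KP658210).

The record is ~150 kB and is not bundled with the package; this script
downloads it once (network required) into scratch/KP658210.gb, where
the accession-based acceptance tests and the reproduction workflow
expect it:

    python scripts/fetch_kp658210.py
    python -m pytest tests/test_acceptance.py -k deposited

With the record in place, a full annotation report of the deposited
genome can be produced with:

    gvannot annotate scratch/KP658210.gb -o results/kp658210/
"""

from pathlib import Path
from urllib.request import urlopen

URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
       "?db=nuccore&id=KP658210&rettype=gbwithparts&retmode=text")
DEST = Path(__file__).resolve().parent.parent / "scratch" / "KP658210.gb"


def main() -> None:
    DEST.parent.mkdir(exist_ok=True)
    print(f"fetching KP658210 from NCBI efetch ...")
    data = urlopen(URL, timeout=60).read()
    if b"LOCUS" not in data[:200]:
        raise SystemExit("unexpected response; not a GenBank flat file")
    DEST.write_bytes(data)
    print(f"wrote {len(data)} bytes to {DEST}")


if __name__ == "__main__":
    main()
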