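#!/usr/bin/env python
"""One-time fetch of the 13 deposited Dendrobium ITS records.

Downloads the GenBank flat files for the study accessions from NCBI
efetch and stores them at data/genbank_its.gb.  Requires network access;
everything downstream (tests, pipeline) then runs offline.  Never invoked
by the test suite itself.
"""

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "MK522197", "MK522210", "MK522215", "MK522222", "MK522234", "MK522238",
    "MK522249",  # section Formosae
    "MK522193", "MK522232", "MK522235", "MK522257", "MK522261", "MK522262",
    # section Chrysotoxae
]

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={ids}&rettype=gbwithparts&retmode=text")


def main() -> int:
    out = Path(__file__).resolve().parent.parent / "data" / "genbank_its.gb"
    out.parent.mkdir(parents=True, exist_ok=True)
    url = EFETCH.format(ids=",".join(ACCESSIONS))
    print(f"fetching {len(ACCESSIONS)} records from NCBI ...", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=60) as resp:
        text = resp.read().decode()
    if "LOCUS" not in text:
        print("unexpected efetch response; nothing written", file=sys.stderr)
        return 1
    out.write_text(text)
    print(f"wrote {out} ({len(text)} bytes)", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
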