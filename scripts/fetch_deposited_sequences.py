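"""Optional helper: download the deposited anti-Cas9 clone sequences.

Fetches GenBank records PP869893-PP869943 (the campaign's 51 deposited
nanobody DNA sequences) via NCBI E-utilities and writes them as a GenBank
flat file for use with ``nbpanel census``.  Requires network access; no
part of the package or test suite depends on this script.

    python scripts/fetch_deposited_sequences.py --out deposited.gb
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"PP{n}" for n in range(869893, 869944)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="deposited.gb")
    parser.add_argument("--batch", type=int, default=20)
    args = parser.parse_args()

    chunks = [ACCESSIONS[i : i + args.batch] for i in range(0, len(ACCESSIONS), args.batch)]
    with open(args.out, "w") as fh:
        for chunk in chunks:
            query = urllib.parse.urlencode(
                {"db": "nuccore", "id": ",".join(chunk), "rettype": "gb", "retmode": "text"}
            )
            with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as resp:
                fh.write(resp.read().decode())
            time.sleep(0.4)  # NCBI rate limit
    print(f"wrote {len(ACCESSIONS)} records to {args.out}")


if __name__ == "__main__":
    main()
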