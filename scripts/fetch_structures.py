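#!/usr/bin/env python
"""Download the STING structures used for pore profiling from the PDB.

Fetches 6NT5 (apo human STING), 8IK3 (cGAMP-bound human STING) and 7SII
(C53-blocked STING) as mmCIF into data/structures/. Needs network access;
the analysis itself runs fully offline once the files are present.

Usage: python scripts/fetch_structures.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

CODES = ["6nt5", "8ik3", "7sii"]
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    failures = 0
    for code in CODES:
        out = DEST / f"{code}.cif"
        if out.exists():
            print(f"{out} already present")
            continue
        url = f"https://files.rcsb.org/download/{code.upper()}.cif"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                out.write_bytes(resp.read())
            print(f"fetched {url} -> {out}")
        except Exception as err:
            failures += 1
            print(f"FAILED to fetch {url}: {err}", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
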