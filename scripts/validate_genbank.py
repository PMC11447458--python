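#!/usr/bin/env python
"""Optional online validation against the published GenBank records.

Downloads the quail rDNA repeat unit (OK523374) and the annotated
chicken unit (MG967540) from NCBI, runs boundary transfer and the
compositional statistics, and prints the recovered region lengths, GC
percentages and gene identities for comparison with the published
values. Requires network access; the offline test suite never calls
this script.

Usage:
    python scripts/validate_genbank.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys

from Bio import Entrez, SeqIO

from rdnaunit import (
    Feature,
    RegionType,
    ReferenceUnit,
    SequenceRecord,
    gc_content,
    pairwise_identity,
    transfer_boundaries,
)

QUAIL_ACC = "OK523374"
CHICKEN_ACC = "MG967540"

# feature-type mapping from GenBank annotation vocabulary
_TYPE_HINTS = {
    "18S": RegionType.R18S,
    "5.8S": RegionType.R5_8S,
    "28S": RegionType.R28S,
    "ITS1": RegionType.ITS1,
    "ITS2": RegionType.ITS2,
}


def fetch(acc: str):
    with Entrez.efetch(db="nucleotide", id=acc, rettype="gb", retmode="text") as h:
        return SeqIO.read(h, "genbank")


def to_reference(gb) -> ReferenceUnit:
    rec = SequenceRecord(id=gb.id, seq=str(gb.seq).upper())
    feats = []
    for f in gb.features:
        label = " ".join(
            f.qualifiers.get("product", []) + f.qualifiers.get("note", []) + f.qualifiers.get("standard_name", [])
        )
        for key, rtype in _TYPE_HINTS.items():
            if key in label:
                feats.append(
                    Feature(region_type=rtype, start=int(f.location.start), end=int(f.location.end))
                )
                break
    return ReferenceUnit(record=rec, features=feats)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default="rdnaunit@example.org")
    args = ap.parse_args()
    Entrez.email = args.email

    try:
        quail_gb = fetch(QUAIL_ACC)
        chicken_gb = fetch(CHICKEN_ACC)
    except Exception as exc:  # noqa: BLE001
        sys.exit(f"download failed (network required): {exc}")

    quail = SequenceRecord(id=quail_gb.id, seq=str(quail_gb.seq).upper())
    print(f"{QUAIL_ACC}: {len(quail)} bp (published total: 21166)")

    ref = to_reference(chicken_gb)
    print(f"{CHICKEN_ACC}: {len(ref.record)} bp, {len(ref.features)} usable features")
    feats = transfer_boundaries(quail, ref)
    for f in sorted(feats, key=lambda f: f.start):
        sub = quail.seq[f.start : f.end]
        gc = gc_content(sub.replace("N", "")) if sub else float("nan")
        print(f"  {f.region_type.value:8s} [{f.start:6d},{f.end:6d}) len={f.length:5d} GC={gc:5.1f}%")

    ref_map = {f.region_type: f for f in ref.features}
    tgt_map = {f.region_type: f for f in feats}
    for g in (RegionType.R18S, RegionType.R5_8S, RegionType.R28S):
        if g in ref_map and g in tgt_map:
            ident = pairwise_identity(
                quail.seq[tgt_map[g].start : tgt_map[g].end],
                ref.record.seq[ref_map[g].start : ref_map[g].end],
            )
            print(f"  identity {g.value}: {ident:.1f}%")


if __name__ == "__main__":
    main()
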