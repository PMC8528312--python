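#!/usr/bin/env python
"""Reproduction experiment on the E. coli MG1655 galK coding sequence.

This check needs a real sequence that is deliberately not bundled with the
package: download the galK CDS (e.g. from NCBI gene b0757, genome
U00096.3) as FASTA and pass it with --cds. The script runs the designer at
all three stringency levels and, with --sweep, over a small configuration
grid (SD mismatch tolerance, allowed start codons), reporting for each
configuration the number of candidate overlaps and whether a candidate
covering ~41% of galK with a perfect-consensus motif and zero amino-acid
changes exists. The published design run found 9 candidates, one of them
exactly such a 41% zero-change candidate; the original configuration is
not fully specified, so expect agreement only somewhere in the sweep.

Usage: python scripts/galk_reproduction.py --cds galK.fasta [--sweep]
"""

from __future__ import annotations

import argparse
import itertools
import json

from riboverlap.design import MotifSpec, RibosorConfig, Stringency, design
from riboverlap.seqcore import read_cds_file


def summarize(cds, config):
    cands = design(cds, config)
    best41 = [
        c
        for c in cands
        if abs(c.overlap_fraction - 0.41) < 0.02
        and c.sd_mismatches == 0
        and c.aa_changes_made == 0
        and c.aa_changes_remaining == 0
    ]
    return {
        "n_candidates": len(cands),
        "candidates": [
            {
                "start_nt": c.start_nt,
                "frame": c.frame,
                "overlap_fraction": round(c.overlap_fraction, 3),
                "sd_mismatches": c.sd_mismatches,
                "aa_changes_made": c.aa_changes_made,
                "aa_changes_remaining": c.aa_changes_remaining,
                "frame_stop_free": c.frame_stop_free,
            }
            for c in cands
        ],
        "has_41pct_perfect_zero_change": bool(best41),
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cds", required=True, help="FASTA/GenBank with the galK CDS")
    ap.add_argument("--sweep", action="store_true", help="sweep motif configurations")
    ap.add_argument("--out", default=None, help="optional JSON output path")
    args = ap.parse_args()

    cds = read_cds_file(args.cds)[0]
    report = {"cds_id": cds.id, "length_nt": len(cds), "runs": []}

    if args.sweep:
        grid = itertools.product(
            (0, 1),  # max SD mismatches
            (frozenset({"ATG"}), frozenset({"ATG", "GTG", "TTG"})),
            (Stringency.S0, Stringency.S1, Stringency.S2plus),
        )
    else:
        grid = [(1, frozenset({"ATG"}), s) for s in
                (Stringency.S0, Stringency.S1, Stringency.S2plus)]

    for max_mm, starts, stringency in grid:
        config = RibosorConfig(
            motif=MotifSpec(max_sd_mismatches=max_mm, start_codons=starts),
            stringency=stringency,
        )
        run = {
            "max_sd_mismatches": max_mm,
            "start_codons": sorted(starts),
            "stringency": stringency.value,
        }
        run.update(summarize(cds, config))
        del run["candidates"]
        report["runs"].append(run)
        print(
            f"mm={max_mm} starts={'/'.join(sorted(starts))} "
            f"stringency={stringency.value}: "
            f"{run['n_candidates']} candidates, "
            f"41% perfect zero-change: {run['has_41pct_perfect_zero_change']}"
        )

    if args.out:
        with open(args.out, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")


if __name__ == "__main__":
    main()
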