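#!/usr/bin/env python
"""Precision and recall of the screen against a replicate-backed standard.

Two analyses: (1) the worked example with the published aggregate counts —
a 26-pair >=2-of-4 standard, 20 calls, 18 confirmed; (2) the simulated
replicates, where the last replicate is held out and scored against the
standard built from the others.  The report goes to results/validation/.
"""

import argparse
from pathlib import Path

from chiscreen.validation import (
    ScreenReplicateSet,
    build_standard,
    precision_recall,
    read_replicate_edges,
    write_replicate_edges,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.outdir / "validation"
    out.mkdir(parents=True, exist_ok=True)

    standard = {("a", f"g{i}") for i in range(26)}
    called = {("a", f"g{i}") for i in range(18)} | {("b", f"g{i}") for i in range(2)}
    report = precision_recall(called, standard)
    print("worked example (26-pair standard, 20 calls, 18 confirmed):")
    print(f"  precision {report.precision:.0%}   recall {report.recall:.0%}")

    rep_dir = args.outdir / "synthetic_screen" / "replicates"
    if rep_dir.exists():
        reps = [read_replicate_edges(p) for p in sorted(rep_dir.glob("*.tsv"))]
        held_out, rest = reps[-1], reps[:-1]
        std = build_standard(ScreenReplicateSet(tuple(rest), min_support=2))
        write_replicate_edges(std, out / "standard.tsv")
        rep_report = precision_recall(held_out, std)
        with (out / "validation.txt").open("w") as fh:
            for key in ("n_standard", "n_called", "n_overlap"):
                fh.write(f"{key}\t{getattr(rep_report, key)}\n")
            fh.write(f"precision\t{rep_report.precision:.4f}\n")
            fh.write(f"recall\t{rep_report.recall:.4f}\n")
        print(f"\nsynthetic replicates ({len(reps)} screens, >=2 support):")
        print(f"  standard {rep_report.n_standard} pairs; held-out screen called "
              f"{rep_report.n_called}, overlap {rep_report.n_overlap}")
        print(f"  precision {rep_report.precision:.0%}   recall {rep_report.recall:.0%}"
              f"  (detection rate planted at 70%)")
    else:
        print("\n(no synthetic replicates found; run 01_simulate_screen.py first)")


if __name__ == "__main__":
    main()
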