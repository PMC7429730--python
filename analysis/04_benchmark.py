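#!/usr/bin/env python
"""Benchmark the measure pipeline against the published Angola tables.

Recomputes all 16 summary measures from the packaged subgroup table and
diffs each against the published measure table; the run fails (exit 3)
if any point estimate deviates by more than the tolerance.
"""

import argparse
import sys
from pathlib import Path

from anc_equity import reproduce_paper_benchmark
from anc_equity.pipeline import BENCHMARK_TOLERANCE


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tolerance", type=float, default=BENCHMARK_TOLERANCE)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    report = reproduce_paper_benchmark(tolerance=args.tolerance)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out_dir / "benchmark_report.csv", index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    ok = report["within_tolerance"].all()
    print(f"\nmax |diff| = {report['abs_diff'].max():.4f}; "
          f"{int(report['within_tolerance'].sum())}/{len(report)} within "
          f"±{args.tolerance}")
    if not ok:
        sys.exit(3)


if __name__ == "__main__":
    main()
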