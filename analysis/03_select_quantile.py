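#!/usr/bin/env python
"""Select the outermost quantile per strip against per-sapling boundaries.

For every sapling a minimal-area polynomial frontier (degree chosen by
AIC/BIC) is fitted to its branch tips; each strip-level quantile curve is
evaluated at the sapling's DBH and crown ratio on the fine relative-depth
grid and the closest quantile is selected.  Writes results/selection/ and
prints both strip-level summary rules (mean of per-sapling quantiles and
the aggregate-distance argmin).
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from saplingcrown.pipeline import run_select

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default=str(ROOT / "results" / "data"))
    ap.add_argument("--params", default=str(ROOT / "results" / "fit" / "params.json"))
    ap.add_argument("--out", default=str(ROOT / "results" / "selection"))
    ap.add_argument("--max-degree", type=int, default=6)
    args = ap.parse_args()

    path = run_select(args.data, args.params, args.out, max_degree=args.max_degree)
    obj = json.loads(path.read_text())
    print(f"wrote {path}")
    for strip, entry in obj.items():
        taus = [v["best_tau"] for v in entry["per_sapling"].values()]
        degrees = Counter(entry["frontier_degrees"].values())
        print(f"  {strip}: mean outermost quantile {entry['strip_tau_mean']:.2f}, "
              f"aggregate argmin {entry['strip_tau_argmin']:.2f} "
              f"({len(taus)} saplings; frontier degrees {dict(sorted(degrees.items()))})")


if __name__ == "__main__":
    main()
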