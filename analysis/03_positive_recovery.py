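#!/usr/bin/env python
"""Power to detect an injected positively selected double substitution.

Boosts acceptance of the NN change TTT->GCT (Phe->Ala) twentyfold under
strong background purifying selection (f_nonsyn = 0.1) and measures how
often the pipeline calls it positive after Bonferroni correction across
replicate datasets.  Detection is limited by the null-side double counts:
the matched NM1 window for this signature is rare in random coding sequence,
so single replicates sit near the corrected significance threshold.

Writes results/positive_recovery.json.
"""

import argparse
import json
from pathlib import Path

from doublesub.studies import run_positive_recovery

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-datasets", type=int, default=20)
    args = ap.parse_args()

    out = run_positive_recovery(seed=args.seed, n_datasets=args.n_datasets)
    OUT.mkdir(exist_ok=True)
    (OUT / "positive_recovery.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"boosted change: {out['change']}")
    print(f"called positive in {100 * out['recovery_rate']:.0f}% of {out['n_datasets']} replicates")
    print("calls:", ", ".join(out["calls"]))


if __name__ == "__main__":
    main()
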