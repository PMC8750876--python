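#!/usr/bin/env python
"""Colocalization posterior recovery and FDR calibration: shared- and
distinct-causal region recovery rates at z ~ 8, and the realized family error
of the q <= 0.10 rule under the global null. Writes results/coloc_fdr.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cytomr import experiments
from cytomr.simulate import derive_seed

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    s = args.seed

    shared = experiments.coloc_recovery(True, n_reps=200, z_scale=8.0,
                                        seed=derive_seed(s, "cl1"))
    distinct = experiments.coloc_recovery(False, n_reps=200, z_scale=8.0,
                                          seed=derive_seed(s, "cl2"))
    fdr = experiments.fdr_null_realization(n_reps=2000, m=100,
                                           seed=derive_seed(s, "fdr"))
    rows = [
        {"experiment": "coloc_shared_pp>0.8_rate", "value": shared["rate"],
         "n": 200, "target": ">= 0.90"},
        {"experiment": "coloc_shared_mean_pp", "value": shared["mean_pp"],
         "n": 200, "target": ""},
        {"experiment": "coloc_distinct_dominant_rate", "value": distinct["rate"],
         "n": 200, "target": ">= 0.90"},
        {"experiment": "bh_global_null_any_rejection_rate", "value": fdr,
         "n": 2000, "target": "<= 0.10 (+MC)"},
    ]
    print(f"coloc: shared-causal regions call pp_shared > 0.8 in "
          f"{shared['rate']:.0%} (mean pp {shared['mean_pp']:.3f}); "
          f"distinct-causal regions favour two variants in {distinct['rate']:.0%}")
    print(f"BH q <= 0.10 under a global null of 100 tests rejects anything in "
          f"{fdr:.1%} of 2000 families (bound 10%)")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "coloc_fdr.tsv", sep="\t", index=False)
    print(f"table written to {out / 'coloc_fdr.tsv'}")


if __name__ == "__main__":
    main()
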