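#!/usr/bin/env python
"""Preprocess the simulated volatilomes into model-ready stimuli.

Runs the fixed chain per condition — control-based exclusion (one-sided
Wilcoxon, p < 0.05), per-sample geometric-mean normalization, Box-Cox
(lambda = 0.014) + Pareto scaling — then maps both conditions onto one
shared 0-5 log-dose scale.  Writes dose matrices and exclusion reports
under <outdir>/processed/.
"""

import argparse
from pathlib import Path

from hostscent import preprocess as pp
from hostscent import synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--lmbda", type=float, default=0.014)
    args = ap.parse_args()

    processed = {}
    for cond in ("intact", "sliced"):
        ds = synthetic.read_dataset(args.outdir / "data" / cond)
        processed[cond] = pp.preprocess(ds, alpha=args.alpha,
                                        lmbda=args.lmbda)

    # one stimulus scale shared across the paired conditions
    lo = min(p.flags["minmax"][0] for p in processed.values())
    hi = max(p.flags["minmax"][1] for p in processed.values())
    out = args.outdir / "processed"
    out.mkdir(parents=True, exist_ok=True)
    for cond, proc in processed.items():
        dose, _ = pp.to_dose_scale(proc.transformed, proc.detection,
                                   minmax=(lo, hi))
        proc.dose = dose
        dose.to_csv(out / f"dose_{cond}.csv")
        proc.detection.to_csv(out / f"detection_{cond}.csv")
        proc.exclusions.to_csv(out / f"exclusions_{cond}.tsv", sep="\t",
                               index=False)
        print(f"{cond}: {dose.shape[1]} retained compounds, "
              f"{len(proc.exclusions)} excluded "
              f"({(proc.exclusions['reason'] == 'control_dominated').sum()} "
              f"control-dominated); dose anchors ({lo:.3f}, {hi:.3f})")


if __name__ == "__main__":
    main()
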