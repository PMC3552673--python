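#!/usr/bin/env python
"""Generate the working synthetic study and write its file set.

Emulates the profiled design — a 1-day block at 0/9/27/45 uM Cd2+ and a
13-day block at 0/4.5/9/27 uM, one array per condition — with 2,000 genes,
2% dose-induced and 2% dose-repressed genes per block (half of them shared
between blocks), and one planted 8-gene co-regulated module.  Writes
expression/calls/design/annotation/truth under results/study/ plus a short
truth summary.

Run:  python analysis/01_simulate_study.py [--seed 1]
"""

import argparse
from pathlib import Path

from cdtox import SimulationConfig, simulate_study
from cdtox.synthetic_data import write_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    study = simulate_study(cfg)
    outdir = ROOT / "results" / "study"
    paths = write_study(study, outdir)

    truth = study.truth
    print(f"wrote {len(paths)} files under {outdir}")
    print(f"genes: {cfg.n_genes}; samples: {study.expression.signal.shape[1]}")
    for b in ("block1", "block2"):
        cls = truth[f"class_{b}"].value_counts()
        print(f"{b}: {cls.get('positive', 0)} induced, {cls.get('negative', 0)} repressed")
    print(f"shared responders: {int(truth['shared'].sum())}")
    print(f"module genes: {int((truth['module_id'] >= 0).sum())}")


if __name__ == "__main__":
    main()
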