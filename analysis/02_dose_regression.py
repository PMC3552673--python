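#!/usr/bin/env python
"""Per-block dose-response regression on the simulated study.

Fits per-gene OLS of log2 signal on Cd2+ concentration within each exposure
block, writes the per-probe tables (slope, t, Pr(>|t|), BH q), the P-value
histograms, and — because the study is simulated — a confusion matrix of the
P < 0.01 selections against the generator's truth table.

Run after 01_simulate_study.py:  python analysis/02_dose_regression.py
"""

import argparse
from pathlib import Path

import pandas as pd

from cdtox import (
    bh_fdr,
    fit_dose_regression,
    pvalue_histogram,
    read_expression,
    select_genes,
)

ROOT = Path(__file__).resolve().parents[1]


def confusion(selected: set, truth_class: pd.Series, direction: str) -> dict:
    actual = set(truth_class.index[truth_class == direction])
    universe = set(truth_class.index)
    tp = len(selected & actual)
    fp = len(selected - actual)
    fn = len(actual - selected)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "regression")
    args = ap.parse_args()

    study = read_expression(
        args.study / "expression.tsv", args.study / "calls.tsv", args.study / "design.csv"
    )
    truth = pd.read_csv(args.study / "truth.tsv", sep="\t", index_col="probe")
    args.out.mkdir(parents=True, exist_ok=True)

    for block, tag in ((1.0, "block1"), (13.0, "block2")):
        res = fit_dose_regression(study, block, scale="log2")
        res = res.assign(q=bh_fdr(res))
        res.rename(columns={"p": "Pr(>|t|)"}).to_csv(
            args.out / f"regression_{tag}.tsv", sep="\t", float_format="%.6g"
        )
        pvalue_histogram(res, 20).to_csv(
            args.out / f"pvalue_hist_{tag}.tsv", sep="\t", index=False
        )
        n05 = (res["p"] < 0.05).sum()
        print(f"{tag}: {len(res)} present probes; {n05} with P < 0.05 "
              f"({(res['q'] < 0.05).sum()} pass BH q < 0.05)")
        rows = []
        for direction in ("positive", "negative"):
            sel = set(select_genes(res, 0.01, direction).ids)
            cm = confusion(sel, truth.loc[res.index, f"class_{tag}"], direction)
            rows.append({"direction": direction, "n_selected": len(sel), **cm})
            print(f"  {direction} @ P<0.01: {len(sel)} selected; "
                  f"sensitivity {cm['sensitivity']:.2f}, FPR {cm['fpr']:.4f}")
        pd.DataFrame(rows).to_csv(
            args.out / f"confusion_{tag}.tsv", sep="\t", index=False
        )


if __name__ == "__main__":
    main()
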