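#!/usr/bin/env python
"""Druggability triage: descriptors, RO5, weighted QED, NP-likeness.

Reads results/data/molecules.csv (2500 labelled panel molecules), keeps the
first 2000 labels as "observed" NP-likeness, trains the random-forest
imputer on them (85/15 split, 150 trees, depth 80), imputes the remaining
500, and compares metric distributions across nested compound sets.  Writes
druggability.csv, evaluation.json and set_summary.csv under results/.

Run after 01: python analysis/05_druggability.py [--seed 0]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pipermine.druggability import (
    ImputerConfig,
    impute_np_likeness,
    records_table,
    score_compounds,
    train_np_imputer,
    compare_sets,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    out = ROOT / "results"

    table = pd.read_csv(out / "data" / "molecules.csv")
    structures = dict(zip(table.compound_key, table.smiles))
    observed = dict(
        zip(table.compound_key[:2000], table.np_likeness[:2000])
    )
    records, skipped = score_compounds(structures, observed)
    print(f"computed descriptors for {len(records)} molecules "
          f"({len(skipped)} unparseable)")

    labeled = [
        (r.descriptors, r.np_likeness)
        for r in records if r.np_likeness is not None
    ]
    imputer = train_np_imputer(labeled, ImputerConfig(random_seed=args.seed))
    ev = imputer.evaluation
    print(f"imputer validation: R^2 = {ev.r_squared:.4f}, "
          f"MSE = {ev.mse:.4f} ({ev.n_train} train / {ev.n_valid} valid)")

    records, imputed_fraction = impute_np_likeness(imputer, records)
    print(f"{100 * imputed_fraction:.2f}% of scores are imputed")

    records_table(records).round(6).to_csv(
        out / "druggability.csv", index=False
    )
    (out / "evaluation.json").write_text(json.dumps({
        "r_squared": round(ev.r_squared, 4),
        "mse": round(ev.mse, 4),
        "n_train": ev.n_train,
        "n_valid": ev.n_valid,
        "imputed_fraction": round(imputed_fraction, 4),
    }, indent=2, sort_keys=True) + "\n")

    keys = [r.compound_key for r in records]
    sets = {
        "whole_panel": keys,
        "observed_np": keys[:2000],
        "imputed_np": keys[2000:],
        "ro5_clean": [r.compound_key for r in records
                      if r.ro5_violations == 0],
    }
    summary = compare_sets(records, sets)
    summary.round(6).to_csv(out / "set_summary.csv", index=False)
    for _, row in summary.iterrows():
        print(f"  {row['set']:12s} n={int(row['n']):4d} "
              f"median wQED {row['wqed_median']:.3f}, "
              f"{100 * row['ro5_zero']:.1f}% with zero RO5 violations")


if __name__ == "__main__":
    main()
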