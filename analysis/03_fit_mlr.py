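#!/usr/bin/env python
"""Best-subset MLR on the reference set (100/21 split) with QSAR validation
statistics, compared against the frozen published equation."""

import argparse
from pathlib import Path

import pandas as pd

from sunqsar import read_compound_table, random_split, best_subset_search, q2_loo, evaluate_test
from sunqsar.mlr import PUBLISHED_MODEL

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--input", type=Path, default=Path("results/reference_synthetic.csv"))
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

ds = read_compound_table(args.input)
ds = random_split(ds, {"train": 100 / len(ds), "test": 1 - 100 / len(ds)},
                  seed=args.seed)
res = best_subset_search(ds, kmin=2, kmax=6, split="train")
model = res.best_model
model.stats.q2_loo = q2_loo(ds, subset=model.names, split="train")
rmse = evaluate_test(model, ds, split="test")

args.outdir.mkdir(parents=True, exist_ok=True)
res.to_frame().to_csv(args.outdir / "subset_search.csv", index=False)
(args.outdir / "mlr_model.json").write_text(model.to_json())

s = model.stats
print(f"best subset: {model.names}")
print(f"n={s.n} k={s.k}  R2={s.r2:.3f}  R2_adj={s.r2_adj:.3f}  "
      f"Q2={s.q2_loo:.3f}  F={s.f_stat:.1f}  RMSE_pred={rmse:.2f}")
rows = [{"descriptor": "(intercept)", "fitted": model.intercept,
         "published": PUBLISHED_MODEL.intercept}]
rows += [{"descriptor": n, "fitted": model.coef[n][0],
          "published": PUBLISHED_MODEL.coef.get(n, (float("nan"),))[0]}
         for n in model.names]
tbl = pd.DataFrame(rows)
tbl.to_csv(args.outdir / "mlr_coefficients.csv", index=False)
print(tbl.round(4).to_string(index=False))
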