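#!/usr/bin/env python
"""Fit the 99% PCA applicability-domain ellipse on the reference set and
classify the 16 sunscreens; exports the PC1/PC2 scatter."""

import argparse
from pathlib import Path

from sunqsar import load_sunscreens, read_compound_table
from sunqsar.applicability import classify, fit_ad, plot_ad, verdicts_frame

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--reference", type=Path, default=Path("results/reference_synthetic.csv"))
parser.add_argument("--coverage", type=float, default=0.99)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

reference = read_compound_table(args.reference)
sunscreens = load_sunscreens()
model = fit_ad(reference, coverage=args.coverage)
verdicts = classify(model, sunscreens)

args.outdir.mkdir(parents=True, exist_ok=True)
frame = verdicts_frame(verdicts).sort_values("distance", ascending=False)
frame.to_csv(args.outdir / "ad_verdicts.csv", index=False)
plot_ad(model, reference, verdicts, path=args.outdir / "ad_pca.png")

print(f"PC1/PC2 explain {model.explained_variance[:2].sum():.0%} of the "
      "standardized descriptor variance")
print(frame.round(3).to_string(index=False))
outside = frame[~frame["inside"]]["id"].tolist()
print(f"\noutside the {args.coverage:.0%} reference ellipse: {outside}")
print("predictions for these compounds extrapolate beyond the reference "
      "chemistry and should be treated with caution")
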