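#!/usr/bin/env python
"""Slope-parallelism selection of biomarker-related texture features.

For every (ROI, biomarker, channel variant, feature) combination the
across-RE series at BS 1 are compared by the ANCOVA slope-equality test;
a feature is "related" to a biomarker when the slopes are parallel
(p > 0.05) and the pooled slope is significantly non-zero.  Writes
results/selection.csv and a summary-matrix text file, and prints which
channel/feature combinations track the exercise-effect biomarkers.
"""

import argparse
from pathlib import Path

import pandas as pd

from equitherm.stats import format_selection_matrix, select_related


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    features = pd.read_csv(args.out / "features.csv")
    biomarkers = pd.read_csv(args.out / "study" / "biomarkers.csv")
    texture = features[features.channel != "IRT"]

    sel = select_related(texture, biomarkers, alpha=args.alpha,
                         alpha_nonzero=args.alpha)
    sel.to_csv(args.out / "selection.csv", index=False)
    matrix = format_selection_matrix(sel)
    (args.out / "selection_matrix.txt").write_text(matrix)

    per_model = (
        sel.assign(model=sel.channel.str.split(".").str[0])
        .groupby(["model", "biomarker"]).size().unstack()
    )
    print("pairs evaluated per color model and biomarker "
          "(528 expected per cell):")
    print(per_model.to_string())
    related = sel[sel.related]
    print(f"\n{len(related)} related pairs out of {len(sel)} "
          f"({100 * len(related) / len(sel):.2f}%)")
    if len(related):
        top = (related.groupby(["channel", "feature"]).size()
               .sort_values(ascending=False).head(12))
        print("\nmost frequently selected channel/feature combinations:")
        print(top.to_string())
    print("\nsummary matrix:")
    print(matrix)

    # conventional measures for contrast: Tmax/Taver series rarely run
    # parallel to the cumulative biomarkers
    irt = features[features.channel == "IRT"]
    if len(irt):
        sel_irt = select_related(irt, biomarkers, alpha=args.alpha)
        n_rel = int(sel_irt.related.sum())
        print(f"conventional IRT measures: {n_rel}/{len(sel_irt)} "
              "(biomarker, measure) pairs related")


if __name__ == "__main__":
    main()
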