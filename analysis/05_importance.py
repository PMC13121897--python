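#!/usr/bin/env python
"""Stage 5: variable importance by predictive pseudo-R^2 partitioning.

For each fitted model: baseline pseudo-R^2 (squared correlation of observed
responses with median posterior predictions), per-predictor drops when each
term is neutralized, group totals (intrinsic / trophic / anthropogenic /
landscape / refuge / random), and interaction marginal-effect grids at the
moderator's quartiles.
"""

import json
from pathlib import Path

import pandas as pd

from wolfmove.inference import marginal_effects, variance_partition
from wolfmove.model import PosteriorFit

OUT = Path("results/analysis")


def main():
    modeling = pd.read_csv(OUT / "modeling_records.csv")
    for response in ("daily_distance", "net_displacement", "straightness"):
        fit = PosteriorFit.load(OUT / "fits" / f"{response}.npz")
        vp = variance_partition(fit, modeling)
        vp.table.to_csv(OUT / f"variance_partition_{response}.csv", index=False)
        with open(OUT / f"variance_groups_{response}.json", "w") as fh:
            json.dump({"baseline_pseudo_r2": vp.baseline_pseudo_r2, "group_pct": vp.group_pct}, fh, indent=2)
        top = vp.table.sort_values("raw_drop", ascending=False).head(3)
        print(f"\n== {response}: baseline pseudo-R^2 {vp.baseline_pseudo_r2:.3f}")
        print("   group %:", {k: round(v, 1) for k, v in vp.group_pct.items()})
        print("   top contributors:", ", ".join(f"{t} ({p:.1f}%)" for t, p in zip(top['term'], top['pct_contribution'])))
        for pair in (("pop_density", "settlement_density"), ("primary_road", "refuge_dim1")):
            me = marginal_effects(fit, pair, modeling, n_grid=15)
            me.to_csv(OUT / f"marginal_{response}_{pair[0]}_x_{pair[1]}.csv", index=False)


if __name__ == "__main__":
    main()
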