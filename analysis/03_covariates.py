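#!/usr/bin/env python
"""Stage 3: landscape covariates inside 1-km influence areas.

Buffers each daily track by 1 km and extracts population and settlement
kernel densities, road-class densities, mean TRI and the five refuge pattern
metrics; reduces the correlated refuge metrics to two PCA dimensions; and
assembles the modeling records (covariates + attributes + reproductive
period + 1x1-km grid cell).
"""

from pathlib import Path

import pandas as pd

from wolfmove.landscape import extract_covariates_for_track, load_layers
from wolfmove.model import assign_grid_cells, assign_period, refuge_pca
from wolfmove.trajectories import filter_complete, segment_days

OUT = Path("results/analysis")


def main():
    fixes = pd.read_csv(OUT / "synthetic" / "fixes.csv")
    attributes = pd.read_csv(OUT / "synthetic" / "attributes.csv")
    layers = load_layers(OUT / "landscape").prepare()
    kept, _ = filter_complete(segment_days(fixes))
    rows = [extract_covariates_for_track(t.track_id, t.x, t.y, layers) for t in kept]
    covariates = pd.DataFrame(rows)
    pca = refuge_pca(covariates)
    print("refuge PCA variance explained:", [round(v, 3) for v in pca.variance_explained])
    print(pca.loadings.round(2))
    covariates = pd.concat([covariates, pca.scores], axis=1)
    metrics = pd.read_csv(OUT / "track_metrics.csv")
    records = metrics.merge(covariates, on="track_id").merge(attributes, on="individual_id")
    records["period"] = [assign_period(d) for d in pd.to_datetime(records["track_date"])]
    records["grid_cell_id"] = assign_grid_cells(records)
    records.to_csv(OUT / "covariate_records.csv", index=False)
    print(f"covariate records: {len(records)} "
          f"({records['grid_cell_id'].nunique()} grid cells)")


if __name__ == "__main__":
    main()
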