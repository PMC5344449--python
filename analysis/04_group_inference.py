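#!/usr/bin/env python
"""Group inference: median-registered channel stats, voxel clusters, and the
dual significance criterion.

Reads the per-subject channel contrasts and MNI coordinates written by
03_first_level.py.  For each contrast: registers subjects to the group
median channel coordinates, runs the channel-wise one-tailed t-tests
(p < 0.05 flags), interpolates the aligned contrasts to the default 4 mm
cortical grid, computes the one-sample group t-map, extracts 18-connected
clusters at voxel p < 0.001 with the 70-voxel extent criterion, and labels
findings "significant" (cluster criterion AND a corresponding flagged
channel) or "active" (channel support only).

Writes results/group/{channels,clusters,findings}_<contrast>.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nirstroop.geometry import (default_analysis_grid, default_probe_layout,
                                interpolation_weights, register_to_median)
from nirstroop.group import (channelwise_t, dual_criterion, group_t_map,
                             threshold_and_cluster)

ROOT = Path(__file__).resolve().parents[1]
FIRST = ROOT / "results" / "first_level"
OUT = ROOT / "results" / "group"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contrasts = pd.read_csv(FIRST / "channel_contrasts.tsv", sep="\t")
    coords = pd.read_csv(FIRST / "channel_coords_mni.tsv", sep="\t")

    subjects = sorted(contrasts["subject"].unique())
    n_chan = contrasts["channel"].max()
    coord_arr = np.stack([
        coords[coords.subject == s].sort_values("channel")[["x", "y", "z"]]
        .to_numpy() for s in subjects])

    grid = default_analysis_grid(default_probe_layout())
    for preset in ("I>C", "G>C"):
        tag = preset.replace(">", "gt")
        values = np.stack([
            contrasts[(contrasts.subject == s)
                      & (contrasts.contrast == preset)]
            .sort_values("channel")["value"].to_numpy() for s in subjects])
        aligned, median_coords = register_to_median(coord_arr, values)

        stats = channelwise_t(aligned)
        weights = interpolation_weights(median_coords, grid)
        tmap = group_t_map(aligned @ weights.T, grid)
        clusters, labels = threshold_and_cluster(tmap, return_labels=True)
        findings = dual_criterion(clusters, labels, grid, stats,
                                  median_coords)

        stats.to_csv(OUT / f"channels_{tag}.tsv", sep="\t", index=False)
        clusters.clusters.to_csv(OUT / f"clusters_{tag}.tsv", sep="\t",
                                 index=False)
        findings.to_csv(OUT / f"findings_{tag}.tsv", sep="\t", index=False)

        print(f"\n{preset} (n={len(subjects)}, {n_chan} channels, "
              f"{grid.n_masked} voxels):")
        print(f"  flagged channels (p<0.05): "
              f"{sorted(stats[stats.flagged]['channel'])}")
        for _, f in findings.iterrows():
            print(f"  {f['label']:12s} cluster of {f['size']} voxels, "
                  f"peak t={f['peak_t']:.2f} at "
                  f"({f['peak_x']:.0f}, {f['peak_y']:.0f}, {f['peak_z']:.0f}), "
                  f"channels {f['channels']}")


if __name__ == "__main__":
    main()
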