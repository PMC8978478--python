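"""Map potholes and molehills in the simulated cohort.

Builds the cohort mean/SD reference and the white-matter mask (mean FA > 0.2),
z-transforms every subject, detects contiguous clusters with all voxels at
|z| > 2 (26-connectivity), and counts them at the 25/50/100/200 mm^3
minimum-volume ladder, globally and per tract.  Prints the per-subject count
summary that is the phenotype of the association analyses.
"""

from pathlib import Path

import pandas as pd

from analysis_config import CONFIG, RUN_DIR
from potholes.pipeline import LAYOUT, stage_clusters, stage_reference, stage_zmap


def main() -> None:
    stage_reference(CONFIG, RUN_DIR)
    stage_zmap(CONFIG, RUN_DIR)
    stage_clusters(CONFIG, RUN_DIR)
    counts = pd.read_csv(RUN_DIR / LAYOUT["counts"], sep="\t")
    summary = (
        counts.groupby(["polarity", "min_volume_mm3"])["count"]
        .agg(["median", "mean"])
        .round(2)
    )
    print("per-subject anomaly counts by minimum cluster volume:")
    print(summary.to_string())
    tract = pd.read_csv(RUN_DIR / LAYOUT["tract_counts"], sep="\t")
    busiest = (
        tract[(tract.min_volume_mm3 == 25.0)]
        .groupby("tract")["count"].sum().sort_values(ascending=False).head(5)
    )
    print("\nbusiest tracts (> 25 mm^3 clusters, cohort total):")
    print(busiest.to_string())


if __name__ == "__main__":
    main()
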