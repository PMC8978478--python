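"""Run the FDR-corrected association suites.

Three regression families on the per-subject anomaly counts: the descriptive
sex/age suite (16 tests, mutually adjusted), the polygenic-score suite
(8 tests: 2 polarities x 4 volume thresholds, adjusted for age, sex, and 10
genetic PCs), and the post hoc per-tract suite (17 tests, handedness-adjusted
in lateralized tracts).  Each family is Benjamini-Hochberg corrected over its
own p-values.  Prints the molehill rows, where the simulation plants a true
positive score effect.
"""

import pandas as pd

from analysis_config import CONFIG, RUN_DIR
from potholes.pipeline import LAYOUT, stage_associate


def main() -> None:
    stage_associate(CONFIG, RUN_DIR)
    prs = pd.read_csv(RUN_DIR / LAYOUT["assoc_prs"], sep="\t")
    cols = ["polarity", "min_volume_mm3", "beta", "se", "delta_r2", "p", "q"]
    print("polygenic-score suite (8 tests, FDR within suite):")
    print(prs[cols].round(4).to_string(index=False))
    tract = pd.read_csv(RUN_DIR / LAYOUT["assoc_tract"], sep="\t")
    top = tract.sort_values("p").head(3)
    print("\ntract suite: smallest-p tracts of 17 "
          "(molehills, > 25 mm^3 clusters):")
    print(top[["scope", "beta", "se", "p", "q", "handedness_adjusted"]]
          .round(4).to_string(index=False))
    desc = pd.read_csv(RUN_DIR / LAYOUT["assoc_descriptive"], sep="\t")
    sig = (desc.q < 0.05).sum()
    print(f"\ndescriptive sex/age suite: {sig} of {len(desc)} tests with q < 0.05")


if __name__ == "__main__":
    main()
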