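"""Compute the polygenic score and its exclusion sensitivity variants.

Scores each subject as the dosage-weighted sum of GWAS effect sizes over
variants with discovery p < 0.01 (strict), then recomputes it (a) without the
rs3135388 tag variant and (b) without the whole MHC region
(chr6:25-35 Mb, half-open), the two sensitivity analyses of the genetic
model.  Writes the primary standardized score for the association stage and
prints how many variants each variant of the score retains.
"""

import pandas as pd

from analysis_config import CONFIG, RUN_DIR
from potholes import PRSConfig, compute_prs, select_variants
from potholes.io import read_table, write_table
from potholes.pipeline import LAYOUT, stage_prs
from potholes.prs import MHC_REGION


def main() -> None:
    stage_prs(CONFIG, RUN_DIR)  # primary score -> prs/scores.tsv
    weights = read_table(RUN_DIR / LAYOUT["weights"])
    dosages = read_table(RUN_DIR / LAYOUT["dosages"], index_col=0)
    variants = {
        "primary (P_T < 0.01)": PRSConfig(),
        "no rs3135388": PRSConfig(exclude_ids=("rs3135388",)),
        "no MHC region": PRSConfig(exclude_ids=("rs3135388",),
                                   exclude_regions=(MHC_REGION,)),
    }
    rows = []
    for name, cfg in variants.items():
        selected = select_variants(weights, cfg)
        score = compute_prs(dosages, selected, cfg)
        rows.append({"score": name, "n_variants": score.n_variants_used,
                     "raw_mean": score.raw.mean(), "raw_sd": score.raw.std(ddof=1)})
        if name.startswith("no MHC"):
            out = score.scores.copy()
            out["n_variants_used"] = score.n_variants_used
            write_table(out, RUN_DIR / "prs/scores_no_mhc.tsv", index=True)
    print(pd.DataFrame(rows).round(3).to_string(index=False))
    print(f"\nprimary standardized score -> {RUN_DIR / LAYOUT['scores']}")


if __name__ == "__main__":
    main()
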