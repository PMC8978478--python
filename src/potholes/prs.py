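"""Thresholded additive polygenic risk score (PRS).

The score for subject *i* is the additive sum over selected variants *j* of
``dosage_ij * effect_j``, where selection keeps variants with discovery GWAS
p-value strictly below a threshold ``P_T`` (default 0.01) and applies optional
exclusions: explicit variant ids (e.g. rs3135388, the HLA-DRB1*15:01 tag) and
genomic regions given as half-open ``[start, end)`` intervals (default MHC
exclusion region chr6:25-35 Mb — a conventional boundary, configurable).

LD clumping/pruning is out of scope: weights are assumed pre-pruned, and
dosages pre-harmonized to the weights' effect allele.  Scores are standardized
to mean 0 / SD 1 over the analyzed subjects by default, so downstream betas
are per SD of genetic risk ("scaled" betas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEIGHT_COLUMNS = ["ID", "CHR", "BP", "BETA", "P"]

#: Conventional extended-MHC bounds; the region most often excluded in MS PRS
#: sensitivity analyses.
MHC_REGION = ("6", 25_000_000, 35_000_000)


@dataclass
class PRSConfig:
    p_threshold: float = 0.01
    exclude_ids: tuple[str, ...] = ()
    exclude_regions: tuple[tuple[str, int, int], ...] = ()  # half-open [start, end)
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        for chrom, start, end in self.exclude_regions:
            if not start < end:
                raise ValueError(
                    f"exclude region {chrom}:{start}-{end} must have start < end"
                )


@dataclass
class ScoreSet:
    scores: pd.DataFrame  # index: subject id; columns: raw, standardized
    n_variants_used: int
    config: PRSConfig = field(repr=False, default_factory=PRSConfig)

    @property
    def raw(self) -> pd.Series:
        return self.scores["raw"]

    @property
    def standardized(self) -> pd.Series:
        return self.scores["standardized"]


def _validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    missing = set(WEIGHT_COLUMNS) - set(weights.columns)
    if missing:
        raise ValueError(f"weights table missing columns {sorted(missing)}")
    if weights["ID"].duplicated().any():
        dupes = weights.loc[weights["ID"].duplicated(), "ID"].tolist()
        raise ValueError(f"duplicate variant ids in weights: {dupes[:5]}")
    p = weights["P"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("weight p-values must lie in (0, 1]")
    return weights


def select_variants(weights: pd.DataFrame, config: PRSConfig) -> pd.DataFrame:
    """Variants passing the strict p-value filter and all exclusions.

    Keeps rows with ``P < p_threshold`` (strict: p exactly at the threshold is
    excluded), id not in ``exclude_ids``, and position outside every excluded
    half-open region.  An empty selection is allowed (the caller sees it via
    the returned frame's length).
    """
    weights = _validate_weights(weights)
    keep = weights["P"].to_numpy(dtype=float) < config.p_threshold
    if config.exclude_ids:
        keep &= ~weights["ID"].isin(config.exclude_ids).to_numpy()
    for chrom, start, end in config.exclude_regions:
        in_region = (
            (weights["CHR"].astype(str) == str(chrom))
            & (weights["BP"].astype(int) >= start)
            & (weights["BP"].astype(int) < end)
        ).to_numpy()
        keep &= ~in_region
    return weights.loc[keep].reset_index(drop=True)


def compute_prs(
    dosages: pd.DataFrame, selected: pd.DataFrame, config: PRSConfig | None = None
) -> ScoreSet:
    """Additive score over the selected variants.

    ``dosages`` is subjects x variants (values in [0, 2], columns = variant
    ids); ``selected`` is the output of :func:`select_variants`.
    """
    config = config or PRSConfig()
    ids = selected["ID"].tolist()
    missing = [v for v in ids if v not in dosages.columns]
    if missing:
        raise ValueError(f"dosage matrix missing variant columns: {missing[:10]}")
    d = dosages[ids].to_numpy(dtype=float)
    if d.size and (d.min() < 0 or d.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    raw = d @ selected["BETA"].to_numpy(dtype=float) if ids else np.zeros(len(dosages))
    out = pd.DataFrame({"raw": raw}, index=dosages.index)
    if config.standardize:
        sd = out["raw"].std(ddof=1)
        if len(ids) and sd == 0:
            raise ValueError("raw scores have zero variance; cannot standardize")
        out["standardized"] = (
            (out["raw"] - out["raw"].mean()) / sd if sd > 0 else 0.0
        )
    else:
        out["standardized"] = np.nan
    return ScoreSet(scores=out, n_variants_used=len(ids), config=config)
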