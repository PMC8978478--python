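"""Association suite: OLS regressions of anomaly counts with FDR correction.

The outcome of every model is a per-subject anomaly count (potholes or
molehills surviving one minimum-volume threshold, globally or within one
tract); the exposure is sex, age, or the standardized polygenic score.  Counts
are analyzed with ordinary least squares, not a count-family GLM, so betas are
in count units per exposure unit ("scaled" beta = count units per SD of
genetic risk); a Poisson-family option exists for sensitivity checks.

Effect size is reported as dR2 — the increment in R^2 of the full model over
the model with the exposure dropped, fitted on identical rows (listwise
deletion of missing values).  Each suite is corrected with Benjamini-Hochberg
FDR over exactly its own family of p-values: 16 tests for the descriptive
sex/age suite (2 exposures x 2 polarities x 4 size thresholds), 8 for the
polygenic-score suite (2 x 4), and 17 for the post hoc tract suite.  In the
tract suite, handedness enters as a covariate only for lateralized (left or
right) tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import TractAtlas, UNASSIGNED
from .clusters import DEFAULT_VOLUME_THRESHOLDS, POLARITIES

#: Covariates of the genetic models: age at scan, sex, first 10 genetic PCs.
PRS_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]


@dataclass
class AssociationResult:
    exposure: str
    beta: float
    se: float
    delta_r2: float
    p_value: float
    n: int
    q_value: float | None = None


def fit_linear(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    exposure_name: str | None = None,
    family: str = "ols",
) -> AssociationResult:
    """One regression: beta/SE/p for the exposure plus dR2 vs the reduced model.

    Rows with any missing value (outcome, exposure, or covariate) are dropped
    listwise before fitting; both the full and the exposure-dropped model use
    the identical remaining rows.  ``family="poisson"`` fits a Poisson GLM
    instead (sensitivity only; dR2 is then reported as NaN).
    """
    exposure_name = exposure_name or (exposure.name if exposure.name else "exposure")
    df = pd.DataFrame({"__y": outcome, exposure_name: exposure})
    if covariates is not None:
        if exposure_name in covariates.columns:
            raise ValueError(f"exposure {exposure_name!r} duplicated in covariates")
        df = df.join(covariates, how="inner")
    df = df.dropna()
    n = len(df)
    x_cols = [exposure_name] + (list(covariates.columns) if covariates is not None else [])
    if n <= len(x_cols) + 1:
        raise ValueError(f"n={n} too small for {len(x_cols) + 1} parameters")
    for col in x_cols:
        if df[col].nunique() < 2:
            raise ValueError(f"column {col!r} is constant after listwise deletion")
    if df["__y"].nunique() < 2:
        # Degenerate outcome (e.g. every subject has zero clusters at a large
        # volume threshold): no association is measurable; report a null
        # result rather than NaNs so suite-level FDR stays well-defined.
        return AssociationResult(
            exposure=exposure_name, beta=0.0, se=float("nan"), delta_r2=0.0,
            p_value=1.0, n=n,
        )
    y = df["__y"].to_numpy(dtype=float)
    X_full = sm.add_constant(df[x_cols].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(f"rank-deficient design matrix (columns {x_cols})")
    if family == "poisson":
        res = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
        return AssociationResult(
            exposure=exposure_name,
            beta=float(res.params[1]),
            se=float(res.bse[1]),
            delta_r2=float("nan"),
            p_value=float(res.pvalues[1]),
            n=n,
        )
    full = sm.OLS(y, X_full).fit()
    if covariates is not None and len(covariates.columns):
        X_red = sm.add_constant(df[list(covariates.columns)].to_numpy(dtype=float))
        reduced = sm.OLS(y, X_red).fit()
        r2_reduced = reduced.rsquared
    else:
        r2_reduced = 0.0
    delta_r2 = max(full.rsquared - r2_reduced, 0.0)  # clip tiny negative round-off
    return AssociationResult(
        exposure=exposure_name,
        beta=float(full.params[1]),
        se=float(full.bse[1]),
        delta_r2=float(delta_r2),
        p_value=float(full.pvalues[1]),
        n=n,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _counts_wide(counts: pd.DataFrame) -> pd.DataFrame:
    """Long (subject, polarity, min_volume_mm3, count) -> wide, one outcome/col."""
    required = {"subject", "polarity", "min_volume_mm3", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    wide = counts.pivot_table(
        index="subject", columns=["polarity", "min_volume_mm3"], values="count",
        aggfunc="sum",
    )
    return wide


def _suite_frame(results: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(results)
    out["q"] = fdr_bh(out["p"].to_numpy())
    return out


def run_global_suite(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    scores: pd.Series | None = None,
    suite: str = "prs",
    thresholds: tuple[float, ...] = DEFAULT_VOLUME_THRESHOLDS,
    extra_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Global count regressions with FDR over the suite's own family.

    ``suite="prs"``: standardized score vs each of the 8 global outcomes
    (2 polarities x 4 size thresholds), adjusted for age, sex, 10 PCs; FDR
    over those 8 p-values.  ``suite="descriptive"``: sex adjusted for age and
    age adjusted for sex, on the same 8 outcomes; FDR over the 16 p-values.
    ``extra_covariates`` (e.g. ``("maternal_education",)``) are added to every
    model for sensitivity analyses.

    ``counts`` is the long per-subject table (columns: subject, polarity,
    min_volume_mm3, count); ``covariates`` is indexed by subject id.
    """
    wide = _counts_wide(counts)
    common = wide.index.intersection(covariates.index)
    if suite == "prs":
        if scores is None:
            raise ValueError("the prs suite requires a score series")
        common = common.intersection(scores.index)
    if len(common) < 2:
        raise ValueError(
            f"subject ids of counts/covariates/scores barely overlap (n={len(common)})"
        )
    wide = wide.loc[common]
    cov = covariates.loc[common]

    results = []
    for polarity in POLARITIES:
        for threshold in thresholds:
            y = wide[(polarity, threshold)]
            if suite == "prs":
                plans = [("prs", scores.loc[common], PRS_COVARIATES)]
            elif suite == "descriptive":
                plans = [("sex", cov["sex"], ["age"]), ("age", cov["age"], ["sex"])]
            else:
                raise ValueError(f"unknown suite {suite!r}")
            for name, exposure, cov_names in plans:
                cov_names = list(cov_names) + list(extra_covariates)
                res = fit_linear(
                    y, exposure.rename(name), cov[cov_names], exposure_name=name
                )
                results.append(
                    {
                        "exposure": name,
                        "polarity": polarity,
                        "min_volume_mm3": threshold,
                        "scope": "global",
                        "beta": res.beta,
                        "se": res.se,
                        "delta_r2": res.delta_r2,
                        "p": res.p_value,
                        "n": res.n,
                    }
                )
    return _suite_frame(results)


def run_tract_suite(
    tract_counts: pd.DataFrame,
    covariates: pd.DataFrame,
    scores: pd.Series,
    atlas: TractAtlas,
    polarity: str = "molehill",
    threshold: float = 25.0,
    allow_missing_handedness: bool = False,
) -> pd.DataFrame:
    """Post hoc per-tract score regressions, FDR over the tracts tested.

    One model per named tract (the unassigned bucket is not a tract and is
    not tested) for one polarity at one minimum-volume threshold.  Handedness
    is added as a covariate for left/right tracts only; midline tracts use
    the base covariate set.

    ``tract_counts`` is the long table with columns subject, label, polarity,
    min_volume_mm3, count.
    """
    required = {"subject", "label", "polarity", "min_volume_mm3", "count"}
    if not required.issubset(tract_counts.columns):
        raise ValueError(f"tract count table must have columns {sorted(required)}")
    lateralized = [
        lab for lab in atlas.label_ids if atlas.laterality_of(lab) in ("left", "right")
    ]
    if lateralized and "handedness" not in covariates.columns:
        if not allow_missing_handedness:
            raise ValueError(
                "covariates lack a 'handedness' column but the atlas has "
                f"{len(lateralized)} lateralized tracts; pass "
                "allow_missing_handedness=True to proceed without the adjustment"
            )
        lateralized = []

    sel = tract_counts[
        (tract_counts["polarity"] == polarity)
        & (tract_counts["min_volume_mm3"] == threshold)
        & (tract_counts["label"] != UNASSIGNED)
    ]
    wide = sel.pivot_table(index="subject", columns="label", values="count",
                           aggfunc="sum")
    common = wide.index.intersection(covariates.index).intersection(scores.index)
    wide, cov = wide.loc[common], covariates.loc[common]

    name_of = {int(r.label): str(r.name) for r in atlas.names.itertuples()}
    results = []
    for lab in atlas.label_ids:
        cov_names = PRS_COVARIATES + (["handedness"] if lab in lateralized else [])
        res = fit_linear(
            wide[lab], scores.loc[common].rename("prs"), cov[cov_names],
            exposure_name="prs",
        )
        results.append(
            {
                "exposure": "prs",
                "polarity": polarity,
                "min_volume_mm3": threshold,
                "scope": name_of[lab],
                "label": lab,
                "handedness_adjusted": lab in lateralized,
                "beta": res.beta,
                "se": res.se,
                "delta_r2": res.delta_r2,
                "p": res.p_value,
                "n": res.n,
            }
        )
    return _suite_frame(results)
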