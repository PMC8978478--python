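"""Tract-atlas assignment: localize clusters within labeled white-matter tracts.

An atlas is an integer label volume on the cohort grid (0 = background) plus a
table naming each label and flagging its laterality (left / right / midline);
any user-supplied labeled parcellation on the cohort grid works, e.g. a
resampled JHU white-matter atlas.  Clusters are assigned to tracts either by
*plurality* (the label owning the most cluster voxels; ties to the lowest
label id; no overlap -> unassigned), which keeps tract counts an exact
decomposition of the global counts, or by *any_overlap* (every label touched),
which double-counts spanning clusters.

The module also ships a 17-label toy atlas — one midline corpus-callosum-like
slab plus 8 left/right tract pairs — matching the 17-tract layout of the
association suite, for fully synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import Cluster, filter_by_min_volume
from .geometry import Geometry

UNASSIGNED = 0  # background label doubles as the "unassigned" bucket key

ASSIGNMENT_RULES = ("plurality", "any_overlap")


@dataclass
class TractAtlas:
    labels: np.ndarray  # 3-D int grid, 0 = background
    names: pd.DataFrame  # columns: label, name, laterality
    geometry: Geometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.geometry.shape:
            raise ValueError(
                f"atlas shape {self.labels.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        required = {"label", "name", "laterality"}
        if not required.issubset(self.names.columns):
            raise ValueError(f"names table must have columns {sorted(required)}")
        present = set(np.unique(self.labels)) - {0}
        named = set(self.names["label"].astype(int))
        missing = present - named
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in volume but unnamed")
        bad_lat = set(self.names["laterality"]) - {"left", "right", "midline"}
        if bad_lat:
            raise ValueError(f"invalid laterality values: {sorted(bad_lat)}")

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.names["label"].astype(int))

    def laterality_of(self, label: int) -> str:
        row = self.names.loc[self.names["label"] == label, "laterality"]
        return str(row.iloc[0])


def assign_cluster(
    cluster: Cluster, atlas: TractAtlas, rule: str = "plurality"
) -> int | list[int]:
    """Tract label(s) for one cluster.

    plurality -> single label id (``UNASSIGNED`` if the cluster lies entirely
    in background); any_overlap -> sorted list of all overlapped labels.
    """
    if rule not in ASSIGNMENT_RULES:
        raise ValueError(f"rule must be one of {ASSIGNMENT_RULES}, got {rule!r}")
    under = atlas.labels[tuple(cluster.voxels.T)]
    under = under[under != 0]
    if rule == "any_overlap":
        return sorted(int(v) for v in np.unique(under))
    if under.size == 0:
        return UNASSIGNED
    values, counts = np.unique(under, return_counts=True)
    best = counts == counts.max()
    return int(values[best].min())  # tie -> lowest label id


def tract_count_table(
    clusters: list[Cluster],
    atlas: TractAtlas,
    thresholds: tuple[float, ...],
    rule: str = "plurality",
) -> pd.DataFrame:
    """Counts per tract x polarity x minimum-volume threshold for one subject.

    Rows cover every named tract plus an "unassigned" row (label 0).  Under
    the plurality rule, summing counts over tracts and unassigned reproduces
    the subject's global count profile exactly.
    """
    rows = []
    labels = [UNASSIGNED] + atlas.label_ids
    name_of = {UNASSIGNED: "unassigned"} | {
        int(r.label): str(r.name) for r in atlas.names.itertuples()
    }
    for threshold in thresholds:
        surviving = filter_by_min_volume(clusters, threshold)
        tally: dict[tuple[int, str], int] = {}
        for c in surviving:
            assigned = assign_cluster(c, atlas, rule=rule)
            hit = [assigned] if rule == "plurality" else (assigned or [UNASSIGNED])
            for lab in hit:
                tally[(lab, c.polarity)] = tally.get((lab, c.polarity), 0) + 1
        for lab in labels:
            for polarity in ("pothole", "molehill"):
                rows.append(
                    {
                        "label": lab,
                        "tract": name_of[lab],
                        "polarity": polarity,
                        "min_volume_mm3": threshold,
                        "count": tally.get((lab, polarity), 0),
                    }
                )
    return pd.DataFrame(rows)


def toy_atlas_names() -> pd.DataFrame:
    """Label table of the 17-tract toy atlas: one midline + 8 left/right pairs."""
    pairs = [
        "corticospinal tract",
        "anterior thalamic radiation",
        "superior longitudinal fasciculus",
        "inferior longitudinal fasciculus",
        "uncinate fasciculus",
        "cingulum bundle",
        "internal capsule",
        "external capsule",
    ]
    rows = [{"label": 1, "name": "corpus callosum", "laterality": "midline"}]
    label = 2
    for name in pairs:
        for side in ("left", "right"):
            rows.append({"label": label, "name": f"{name} ({side})", "laterality": side})
            label += 1
    return pd.DataFrame(rows)
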