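"""Assembly of the fixed-order topological feature vector.

For an N-region atlas the vector has ``7 + 3N`` entries (277 for the
90-region AAL atlas): the AUC over the sparsity grid of the seven global
metrics (Cp, Lp, gamma, lambda, sigma, Eloc, Eglob) followed by three
nodal blocks (degree, betweenness, efficiency), each in atlas region
order.  Feature names are "global:<metric>" or "<metric>:<region>" and
the name order is a pure function of the atlas label list, so vectors
from different subjects are guaranteed to align.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from braintopo.connectome import SparsityGrid
from braintopo.topology import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    ThresholdedMetricCurves,
    auc_over_grid,
)


def feature_names(region_labels: list[str]) -> list[str]:
    """The canonical feature-name order for a given atlas."""
    names = [f"global:{m}" for m in GLOBAL_METRIC_NAMES]
    for metric in NODAL_METRIC_NAMES:
        names.extend(f"{metric}:{label}" for label in region_labels)
    return names


def parse_feature_name(name: str) -> tuple[str, str | None]:
    """Split a feature name into (metric, region); region is None for globals."""
    metric, _, rest = name.partition(":")
    if metric == "global":
        return rest, None
    return metric, rest


@dataclass(frozen=True)
class TopoFeatureVector:
    """One subject's named topological feature vector."""

    values: np.ndarray
    names: list[str]
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != len(self.names):
            raise ValueError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def assemble_features(
    curves: ThresholdedMetricCurves, subject_id: str, group: str
) -> TopoFeatureVector:
    """Integrate every metric curve into its AUC scalar, in canonical order."""
    grid: SparsityGrid = curves.grid
    labels = curves.region_labels
    n = len(labels)
    values: list[float] = []
    for j, _ in enumerate(GLOBAL_METRIC_NAMES):
        curve = [g.as_tuple()[j] for g in curves.global_metrics]
        values.append(auc_over_grid(curve, grid))
    for metric in NODAL_METRIC_NAMES:
        per_region = np.array([getattr(m, _nodal_attr(metric)) for m in
                               curves.nodal_metrics])  # thresholds x regions
        for r in range(n):
            values.append(auc_over_grid(per_region[:, r], grid))
    return TopoFeatureVector(
        values=np.array(values),
        names=feature_names(list(labels)),
        subject_id=subject_id,
        group=group,
    )


def _nodal_attr(metric: str) -> str:
    return {"degree": "degree", "betweenness": "betweenness",
            "efficiency": "efficiency"}[metric]


@dataclass(frozen=True)
class FeatureTable:
    """Cohort feature matrix: subjects x features plus id and group columns."""

    matrix: np.ndarray
    names: list[str]
    subject_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if m.shape[0] != len(self.subject_ids) or m.shape[0] != len(self.groups):
            raise ValueError("row count must match subject ids and groups")
        if m.shape[1] != len(self.names):
            raise ValueError("column count must match feature names")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def labels01(self, positive_group: str = "A") -> np.ndarray:
        """Binary label vector: 1 for the positive (patient) group."""
        return np.array([1 if g == positive_group else 0 for g in self.groups])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"feature table missing required column {col!r}")
        names = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            matrix=df[names].to_numpy(dtype=float),
            names=names,
            subject_ids=df["subject_id"].astype(str).tolist(),
            groups=df["group"].astype(str).tolist(),
        )


def feature_table(vectors: list[TopoFeatureVector]) -> FeatureTable:
    """Stack per-subject vectors, refusing any name-order mismatch."""
    if not vectors:
        raise ValueError("cannot build a feature table from an empty cohort")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError(
                f"feature-name mismatch between {vectors[0].subject_id} "
                f"and {v.subject_id}"
            )
    return FeatureTable(
        matrix=np.vstack([v.values for v in vectors]),
        names=list(names),
        subject_ids=[v.subject_id for v in vectors],
        groups=[v.group for v in vectors],
    )
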