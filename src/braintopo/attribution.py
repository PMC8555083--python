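"""Backward weight-propagation feature attribution.

Starting from layer l4 of the fine-tuned stack, each node's contribution
is the (normalized) sum of absolute weights connecting it to the layer
above; the highest-contributing nodes whose summed contributions exceed
50% of the layer total are retained, and the calculation is propagated
backward through W3 and W2 down to the input layer l1, where every raw
feature is scored against the retained l2 set (no cut at l1).  The top
raw features, mapped to their (metric, region) names, form the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from braintopo.atlas import full_region_names
from braintopo.features import parse_feature_name
from braintopo.sae import SaeModel

_METRIC_DISPLAY = {
    "degree": "Nodal degree",
    "betweenness": "Nodal betweenness",
    "efficiency": "Nodal efficiency",
}


@dataclass(frozen=True)
class ContributionReport:
    kept_nodes: dict[str, list[int]]
    feature_contributions: np.ndarray
    feature_names: list[str]
    top_features: list[tuple[str, float]]

    def __post_init__(self) -> None:
        c = self.feature_contributions
        if np.any(c < 0):
            raise ValueError("contributions must be non-negative")
        if abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("raw-feature contributions must sum to 1")


def layer_contributions(
    w: np.ndarray, kept_next: list[int] | np.ndarray, mode: str = "abs"
) -> np.ndarray:
    """Contribution of each upstream node: summed |weights| into the kept
    downstream set, normalized to sum to 1 across the layer.

    ``mode="sq"`` uses squared weights instead of absolute values.
    """
    w = np.asarray(w, dtype=float)
    kept_next = np.asarray(kept_next, dtype=int)
    if kept_next.size == 0:
        raise ValueError("kept_next must be non-empty")
    if kept_next.max() >= w.shape[0] or kept_next.min() < 0:
        raise ValueError("kept_next indexes rows of w")
    restricted = w[kept_next, :]
    if mode == "abs":
        raw = np.abs(restricted).sum(axis=0)
    elif mode == "sq":
        raw = (restricted**2).sum(axis=0)
    else:
        raise ValueError(f"unknown contribution mode {mode!r}")
    total = raw.sum()
    if total == 0:
        raise ValueError("restricted weight matrix is all zero (degenerate model)")
    return raw / total


def select_over_half(contributions: np.ndarray) -> list[int]:
    """Minimal descending prefix of nodes whose summed contribution > 0.5.

    Ties are broken by node index (stable sort), so the selection is
    deterministic.
    """
    c = np.asarray(contributions, dtype=float)
    order = np.argsort(-c, kind="stable")
    cum = np.cumsum(c[order])
    n_keep = int(np.searchsorted(cum, 0.5, side="right")) + 1
    n_keep = min(n_keep, c.size)
    return sorted(int(i) for i in order[:n_keep])


def backward_propagate_contributions(
    model: SaeModel,
    feature_names: list[str],
    top_k: int = 10,
    mode: str = "abs",
    seed_from_label_layer: bool = False,
) -> ContributionReport:
    """Propagate contributions from l4 back to the raw features.

    The pass seeds at l4 by scoring its nodes through W4 against the
    whole bottleneck l5 (or, with ``seed_from_label_layer``, against the
    label layer's positive-class weights folded into l5 first), then
    alternates the >50% retention rule and the contribution formula
    through W3 and W2; the l1 scores use the kept l2 set without a cut.
    """
    model.validate()
    if len(feature_names) != model.weights[0].shape[1]:
        raise ValueError("feature_names must match the input layer width")
    n_stack = len(model.weights)  # W1..W4 for the 5-layer stack
    kept: dict[str, list[int]] = {}
    if seed_from_label_layer:
        if model.label_weight is None:
            raise ValueError("model has no retained label layer")
        lab = layer_contributions(model.label_weight[1:2, :], [0], mode=mode)
        kept_next = select_over_half(lab)
        kept[f"l{n_stack + 1}"] = kept_next
    else:
        kept_next = list(range(model.weights[-1].shape[0]))
        kept[f"l{n_stack + 1}"] = kept_next
    # walk W4, W3, W2 with the >50% cut; W1 scores all raw features
    for i in range(n_stack - 1, 0, -1):
        contrib = layer_contributions(model.weights[i], kept_next, mode=mode)
        kept_next = select_over_half(contrib)
        if not kept_next:
            raise ValueError(f"empty kept set at layer l{i + 1}")
        kept[f"l{i + 1}"] = kept_next
    raw = layer_contributions(model.weights[0], kept_next, mode=mode)
    order = np.argsort(-raw, kind="stable")
    top = [(feature_names[int(i)], float(raw[int(i)])) for i in
           order[: min(top_k, raw.size)]]
    return ContributionReport(
        kept_nodes=kept,
        feature_contributions=raw,
        feature_names=list(feature_names),
        top_features=top,
    )


def format_report(report: ContributionReport) -> pd.DataFrame:
    """Three-column table: topological property, brain region, contribution.

    Nodal metrics display as "Nodal <metric>" with the region's full
    anatomical name and hemisphere; global metrics display as "Global"
    with an em-dash region.  Contributions are rounded to 4 decimals.
    """
    names = full_region_names()
    rows = []
    for feat, value in report.top_features:
        metric, region = parse_feature_name(feat)
        if region is None:
            rows.append(("Global", "—", round(value, 4)))
        else:
            display = names.get(region)
            if display is None:
                base, _, hemi = region.rpartition(".")
                display = f"{base or region} {hemi}".strip()
            rows.append((_METRIC_DISPLAY.get(metric, metric), display,
                         round(value, 4)))
    return pd.DataFrame(
        rows, columns=["topological_property", "brain_region", "contribution"]
    )
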