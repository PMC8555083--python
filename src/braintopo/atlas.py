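"""Region-label tables for network nodes.

Ships the 90-region AAL cortical/subcortical parcellation (45 bilateral
pairs, ``<abbr>.L`` / ``<abbr>.R``) used to name nodal features, plus a
mapping to full anatomical names for human-readable reports.
"""

from __future__ import annotations

import csv
from importlib import resources

_AAL90 = "aal90_labels.tsv"


def _read_label_table(name: str) -> list[dict[str, str]]:
    ref = resources.files("braintopo.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_atlas_labels() -> list[str]:
    """Return the 90 AAL region labels (abbreviation.hemisphere) in atlas order."""
    return [row["label"] for row in _read_label_table(_AAL90)]


def full_region_names() -> dict[str, str]:
    """Map each region label to its full anatomical name with hemisphere suffix."""
    return {row["label"]: row["full_name"] for row in _read_label_table(_AAL90)}
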