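"""Cross-validated classification of the two groups from topology features.

Runs the two-stage pipeline -- stacked-autoencoder dimensionality
reduction fitted per training fold, then a linear SVM with its C chosen
by nested 5-fold grid search -- under stratified 10-fold outer CV, and
reports balanced accuracy, sensitivity and specificity.
"""

import argparse
import json
from pathlib import Path

from braintopo.features import FeatureTable
from braintopo.io import RunConfig, write_json
from braintopo.pipeline import classify_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--features",
        type=Path,
        default=ROOT / "scratch" / "analysis" / "features.tsv",
    )
    args = parser.parse_args()

    cfg = RunConfig(seed=args.seed)
    table = FeatureTable.from_tsv(args.features)
    result = classify_features(table, cfg)
    out = ROOT / "results" / "classification.json"
    write_json({**result.summary(), "n_subjects": table.n_subjects}, out)
    print(
        f"balanced accuracy {100 * result.mean_balanced_accuracy:.1f}% "
        f"(sensitivity {100 * result.mean_sensitivity:.1f}%, "
        f"specificity {100 * result.mean_specificity:.1f}%) "
        f"over {cfg.k_outer}-fold CV -> {out}"
    )


if __name__ == "__main__":
    main()
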