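"""Which (metric, region) features drive the classifier?

Fine-tunes one interpretation SAE on the full cohort, then runs the
backward weight-propagation pass: starting from l4, keep the nodes
holding > 50% of each layer's absolute-weight contribution, walk back to
the input layer, and rank the raw features.  Reports the top 10 with
anatomical names, and checks how many of the planted effect regions they
recover.
"""

import argparse
import json
from pathlib import Path

from braintopo.attribution import backward_propagate_contributions, format_report
from braintopo.classify import fit_interpretation_model
from braintopo.features import FeatureTable, parse_feature_name
from braintopo.io import RunConfig
from braintopo.pipeline import sae_config_from_run

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
    model, _ = fit_interpretation_model(
        table.matrix, table.labels01(), sae_config_from_run(cfg)
    )
    report = backward_propagate_contributions(model, table.names)

    region_labels = [n.split(":", 1)[1] for n in table.names[7:97]]
    top_regions = {
        region_labels.index(r)
        for f, _ in report.top_features
        for _, r in [parse_feature_name(f)]
        if r is not None
    }
    planted = set(cfg.effect_regions)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table_out = format_report(report)
    table_out.to_csv(results / "attribution.tsv", sep="\t", index=False)
    (results / "attribution.json").write_text(
        json.dumps(
            {
                "top_features": report.top_features,
                "kept_nodes": report.kept_nodes,
                "planted_regions": sorted(planted),
                "planted_regions_in_top10": sorted(top_regions & planted),
            },
            indent=2,
        )
    )
    print(table_out.to_string(index=False))
    print(
        f"\nplanted effect regions recovered in top-10: "
        f"{len(top_regions & planted)}/{len(planted)}"
    )


if __name__ == "__main__":
    main()
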