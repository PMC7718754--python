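#!/usr/bin/env python
"""Score the whole study against its planted ground truth.

Summarises the recovery metrics of the finished demo run (sharing
pattern, Mb abundances, occupancy conservation, family ages) and runs
the standalone validation fixtures: clustering vs the exhaustive
all-vs-all oracle, the four-age molecular-clock recovery, read-pair
proximity sensitivity, and the enrichment calibration. Writes
results/validation.json.
"""

import argparse
import json
import logging
from pathlib import Path

from repeatscape import experiments, pipeline


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--outdir", type=Path, default=Path("results/run"))
    p.add_argument("--seed", type=int, default=11)
    p.add_argument("--out", type=Path, default=Path("results/validation.json"))
    args = p.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    pipeline.run(pipeline.demo_config(args.seed), args.outdir)  # no-op if complete

    summary = {}
    demo = experiments.demo_recovery_metrics(args.outdir)
    summary["demo"] = demo
    print(f"sharing pattern exact: {demo['sharing_exact']}")
    print(f"worst abundance error: {demo['max_abundance_rel_error']:+.1%}")
    print(f"occupancy conservation residual: {demo['conservation_residual']:.2e}")
    print(f"worst family-age error: {demo['max_age_rel_error']:+.1%}")

    oracle = experiments.clustering_oracle_experiment(args.seed)
    summary["clustering_oracle"] = oracle
    print(f"clustering equals brute force on {oracle['n_reads']} reads: {oracle['partitions_equal']}")

    clock = experiments.clock_experiment(args.seed)
    summary["clock"] = {k: v for k, v in clock.items() if k != "consensus_ages"}
    summary["clock"]["consensus_ages"] = {
        k: list(v) for k, v in clock["consensus_ages"].items()
    }
    print(
        f"clock recovery 0.5-5 My: worst {clock['max_consensus_rel_error']:+.1%}; "
        f"LTR-pair slope {clock['pair_regression_slope']:.3f}"
    )

    rp = experiments.proximity_readpair_experiment(args.seed)
    summary["readpair"] = rp
    print(
        f"read-pair proximity: {rp['n_recovered']}/{rp['n_planted_detectable']} planted "
        f"insertions recovered, {rp['false_positive_hits_on_isolated_genes']} false hits"
    )

    null = experiments.enrichment_null_experiment(args.seed)
    summary["enrichment_null"] = null
    print(f"enrichment null calibration: {null['fdr_fraction']:.4f} of terms at q<0.05")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
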