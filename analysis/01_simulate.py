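"""Simulate the discovery cohort and the two-arm trial table."""

import argparse
from pathlib import Path

from brcaness import DiscoverySimConfig, TrialSimConfig, simulate_discovery, simulate_trial
from brcaness.io import write_annotation, write_expression, write_trial


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_discovery(DiscoverySimConfig(seed=args.seed))
    write_expression(cohort.expr, args.out / "discovery_raw.tsv")
    write_annotation(cohort.label, cohort.expr.batch, args.out / "discovery_anno.tsv")
    print(f"discovery cohort: {cohort.expr.n_genes} genes x {cohort.expr.n_samples} samples, "
          f"{int(cohort.label.sum())} reference-positive")

    trial = simulate_trial(TrialSimConfig(seed=args.seed))
    write_trial(trial, args.out / "trial.tsv")
    print(f"trial table: {len(trial)} patients, "
          f"{(trial.biomarker == 'positive').sum()} biomarker-positive")


if __name__ == "__main__":
    main()
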