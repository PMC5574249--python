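"""Evaluate the biomarker in the two-arm trial: per-arm Fisher tests,
biomarker x treatment interaction, baseline characteristics, combined-subset
odds ratio."""

import argparse
from pathlib import Path

from brcaness import evaluate_trial
from brcaness.io import read_trial, write_report
from brcaness.trial import combined_subset_or, tn_subset_or


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    trial = read_trial(args.out / "trial.tsv")
    report = evaluate_trial(trial)
    or_combined, gain = combined_subset_or(trial)
    report["combined_subset"] = {
        "odds_ratio": or_combined,
        "tn_only_odds_ratio": tn_subset_or(trial),
        "prevalence_gain": gain,
    }
    write_report(report, args.out / "evaluation.json")

    for arm, r in report["arms"].items():
        print(f"{arm}: OR = {r['odds_ratio']:.2f}, Fisher p = {r['fisher_p']:.4f}")
    for name, r in report["interaction"].items():
        if "p" in r:
            print(f"interaction ({name}): LR = {r['lr_stat']:.2f}, p = {r['p']:.4f}")
    print(f"combined subset: OR = {or_combined:.2f} "
          f"(TN-only {report['combined_subset']['tn_only_odds_ratio']:.2f}), "
          f"prevalence gain {100 * gain:.1f}%")


if __name__ == "__main__":
    main()
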