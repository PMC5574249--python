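"""Score the discovery samples with the saved signature model and tabulate
the agreement with the reference label."""

import argparse
from pathlib import Path

from brcaness import ConfusionMatrix, SignatureModel, confusion_metrics, score_matrix
from brcaness.io import read_annotation, read_expression, write_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    model = SignatureModel.from_json(args.out / "model.json")
    norm = read_expression(args.out / "discovery_norm.tsv")
    anno = read_annotation(args.out / "discovery_anno.tsv")

    scores = score_matrix(model, norm)
    scores.to_csv(args.out / "calls.tsv", sep="\t", float_format="%.17g")

    call = scores["call"]
    lab = anno["label"].loc[call.index]
    cm = ConfusionMatrix(
        tp=int((call & (lab == 1)).sum()),
        fn=int((~call & (lab == 1)).sum()),
        fp=int((call & (lab == 0)).sum()),
        tn=int((~call & (lab == 0)).sum()),
    )
    sens, spec, acc = confusion_metrics(cm)
    write_report(
        {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
         "sensitivity": sens, "specificity": spec, "accuracy": acc},
        args.out / "discovery_confusion.json",
    )
    print(f"counts tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}; "
          f"sensitivity {100 * sens:.1f}%, specificity {100 * spec:.1f}%, "
          f"accuracy {100 * acc:.1f}%")


if __name__ == "__main__":
    main()
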