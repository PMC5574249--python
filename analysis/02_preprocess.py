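"""Normalize the raw discovery matrix (log transform, quantile normalization,
low-signal flagging, kNN imputation, batch adjustment)."""

import argparse
from pathlib import Path

from brcaness.io import read_annotation, read_expression, write_expression
from brcaness.preprocess import preprocess_chain


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    anno = read_annotation(args.out / "discovery_anno.tsv")
    raw = read_expression(args.out / "discovery_raw.tsv", batch=anno["batch"])
    norm = preprocess_chain(raw)
    write_expression(norm, args.out / "discovery_norm.tsv")
    print(f"normalized matrix: {norm.n_genes} genes x {norm.n_samples} samples, "
          f"no missing values: {not norm.values.isna().any().any()}")


if __name__ == "__main__":
    main()
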