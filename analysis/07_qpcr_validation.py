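"""2^-ddCt relative expression from the Ct table and concordance of qPCR
fold changes with the RNA-seq hybrid-vs-female-parent fold changes."""

import argparse
from pathlib import Path

from kheterosis import io
from kheterosis.qpcr import concordance, relative_expression


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--de", default="results/de")
    ap.add_argument("--out", default="results/qpcr")
    ap.add_argument("--rnaseq-table", default="classifier_G70xGDH11_H_vs_P1.tsv")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    ct = io.read_ct_table(Path(args.inputs) / "ct.tsv")
    ratios = relative_expression(ct, test_sample="hybrid", control_sample="parent")
    io.write_tsv(ratios, out / "ratios.tsv")
    print(f"2^-ddCt ratios for {len(ratios)} genes "
          f"(range {ratios['ratio'].min():.3f} .. {ratios['ratio'].max():.3f})")

    rnaseq = io.read_tsv(Path(args.de) / args.rnaseq_table, index_col=0)["log2fc"]
    sign_agree, rho = concordance(ratios["log2_ratio"].to_dict(), rnaseq.to_dict())
    print(f"concordance with RNA-seq: sign agreement {sign_agree:.2f}, "
          f"Spearman rho {rho:.3f}")


if __name__ == "__main__":
    main()
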