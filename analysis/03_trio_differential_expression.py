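"""Trio differential expression for both crosses.

Normalizes the joint count matrix (median-of-ratios), builds virtual
mid-parent samples per cross, and runs the four NB Wald contrasts
(hybrid vs each parent, hybrid vs mid-parent, parent vs parent). Two call
sets are written per contrast: significance-only calls feeding the pattern
classifier, and DEG calls at p <= 0.05 and |log2FC| >= 1 for the funnel
counts.
"""

import argparse
from pathlib import Path

from kheterosis import io
from kheterosis.de import call_degs, normalize, trio_contrasts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--out", default="results/de")
    ap.add_argument("--p-max", type=float, default=0.05)
    ap.add_argument("--lfc-min", type=float, default=1.0)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cm = normalize(io.read_counts(Path(args.inputs) / "counts.tsv"))
    designs = io.read_design(Path(args.inputs) / "design.tsv")
    for design in designs:
        tables = trio_contrasts(cm, design, p_max=args.p_max, lfc_min=0.0)
        for contrast, table in tables.items():
            degs = call_degs(table, p_max=args.p_max, lfc_min=args.lfc_min)
            io.write_tsv(table, out / f"classifier_{design.hybrid_id}_{contrast}.tsv")
            io.write_tsv(degs, out / f"degs_{design.hybrid_id}_{contrast}.tsv")
            up, down = (degs["call"] == "up").sum(), (degs["call"] == "down").sum()
            print(f"{design.hybrid_id} {contrast}: {len(degs)} tested, "
                  f"{up} up, {down} down at p<={args.p_max}, |log2FC|>={args.lfc_min}")


if __name__ == "__main__":
    main()
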