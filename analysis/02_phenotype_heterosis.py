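"""Mid-parent heterosis of K+ content per hybrid and timepoint, and the
strong/weak hybrid screen at the sequencing timepoint (day 70)."""

import argparse
from pathlib import Path

from kheterosis import io
from kheterosis.phenotype import compute_mph, screen_hybrids


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--out", default="results/phenotype")
    ap.add_argument("--timepoint", type=int, default=70)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    records = io.read_phenotype(Path(args.inputs) / "phenotype.tsv")
    mph = compute_mph(records)
    io.write_heterosis(mph, out / "mph.tsv")
    for r in mph:
        if r.timepoint == args.timepoint:
            print(f"{r.hybrid} ({r.trait}) day {r.timepoint}: "
                  f"F1={r.f1_mean:.3f} MP={r.mp:.3f} MPH={r.mph_percent:.2f}%")
    strongest, weakest = screen_hybrids(mph, args.timepoint)
    print(f"screen at day {args.timepoint}: strongest={strongest}, weakest={weakest}")


if __name__ == "__main__":
    main()
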