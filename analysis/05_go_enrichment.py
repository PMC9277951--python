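"""GO over-representation of the overdominant pattern gene sets against the
whole-matrix background, Bonferroni-controlled, plus the intersection of the
strong cross's up-overdominant set with the weak cross's dominant
(non-overdominant) set."""

import argparse
from pathlib import Path

import pandas as pd

from kheterosis import io
from kheterosis.enrichment import enrich, intersect_sets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--patterns", default="results/patterns")
    ap.add_argument("--out", default="results/enrichment")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    annotation = io.read_annotation(Path(args.inputs) / "annotation.tsv")
    counts = io.read_counts(Path(args.inputs) / "counts.tsv")
    background = sorted(set(annotation) & set(counts.gene_ids))
    print(f"background: {len(background)} annotated genes in the count matrix")

    pattern_dir = Path(args.patterns)
    sets: dict[str, dict[str, list[str]]] = {}
    for path in sorted(pattern_dir.glob("patterns_*.tsv")):
        hybrid = path.stem.split("_", 1)[1]
        assignments = io.read_tsv(path, index_col=0)
        sets[hybrid] = {
            cat: assignments.index[assignments["category"] == cat].tolist()
            for cat in ("dominant", "overdominant_down", "overdominant_up")
        }
        for cat in ("overdominant_up", "overdominant_down"):
            genes = sorted(set(sets[hybrid][cat]) & set(background))
            table = enrich(genes, annotation, background)
            io.write_tsv(table, out / f"enrich_{hybrid}_{cat}.tsv", index=False)
            sig = table[table["p_bonferroni"] <= args.alpha]
            print(f"{hybrid} {cat}: {len(genes)} genes, {len(table)} terms tested, "
                  f"{len(sig)} enriched at Bonferroni p<={args.alpha}")

    hybrids = sorted(sets)
    if len(hybrids) >= 2:
        strong, weak = hybrids[0], hybrids[1]
        common = intersect_sets(sets[strong]["overdominant_up"], sets[weak]["dominant"])
        pd.Series(common, name="gene_id").to_csv(out / "intersection_genes.txt",
                                                 index=False, header=False)
        print(f"intersection of {strong} up-overdominant with {weak} dominant: "
              f"{len(common)} genes")


if __name__ == "__main__":
    main()
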