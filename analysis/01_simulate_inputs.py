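"""Generate every pipeline input with planted ground truth.

Two parent-parent-hybrid crosses are simulated: a strong-heterosis cross
G70xGDH11 (planted overdominant share of non-additive genes 0.70) and a
weak-heterosis cross K326xGDH11 (planted share 0.57), sharing one gene
universe. Also written: a K+ phenotype time series with planted mid-parent
heterosis of 9.93% (strong) and 3.98% (weak) at day 70 plus an 8.40% biomass
MPH for the strong cross, a toy GO annotation enriched in the strong cross's
planted up-overdominant genes, a toy homology-hit table for seven K+
channel/transporter families, and a toy qPCR Ct table for nine genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from kheterosis import io
from kheterosis.de import CountMatrix, TrioDesign
from kheterosis.simulate import (
    SimulationConfig,
    default_pattern_proportions,
    simulate_ct_table,
    simulate_go_annotation,
    simulate_homology_hits,
    simulate_phenotype,
    simulate_trio_counts,
)

STRONG, WEAK = "G70xGDH11", "K326xGDH11"

K_FAMILIES = {
    "AT_KAT1": "KAT/AKT", "AT_AKT2": "KAT/AKT", "AT_GORK": "GORK",
    "AT_TPK1": "TPK", "AT_TPC1": "TPC", "AT_NHX1": "NHX",
    "AT_KEA3": "KEA", "AT_CIPK5": "CBL/CIPK",
}


def weak_pattern_proportions() -> dict[str, float]:
    """Same null/additive load as the default mixture, but a 0.57
    overdominant share of non-additive genes."""
    props = {"null": 0.70, "P1": 0.03, "P2": 0.03}
    for p in ("P3", "P4", "P5", "P6"):
        props[p] = 0.24 * 0.43 / 4
    for p in ("P7", "P8", "P9", "P10", "P11", "P12"):
        props[p] = 0.24 * 0.57 / 6
    return props


def simulate_cross(name: str, proportions: dict, n_genes: int, seed: int):
    cfg = SimulationConfig(n_genes=n_genes, pattern_proportions=proportions, seed=seed)
    cm, design, truth = simulate_trio_counts(cfg)
    renamed = {s: f"{name}_{s}" for s in cm.sample_ids}
    cm = CountMatrix(cm.counts.rename(columns=renamed))
    design = TrioDesign(
        hybrid_id=name,
        samples={role: [renamed[s] for s in ids] for role, ids in design.samples.items()},
    )
    return cm, design, truth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=6000)
    ap.add_argument("--out", default="results/inputs")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    meta = io.provenance(seed=args.seed)

    cm_s, design_s, truth_s = simulate_cross(
        STRONG, default_pattern_proportions(), args.n_genes, args.seed
    )
    cm_w, design_w, truth_w = simulate_cross(
        WEAK, weak_pattern_proportions(), args.n_genes, args.seed + 1
    )
    counts = pd.concat([cm_s.counts, cm_w.counts], axis=1)
    io.write_counts(CountMatrix(counts), out / "counts.tsv", meta=meta)
    io.write_design([design_s, design_w], out / "design.tsv", meta=meta)
    io.write_truth(truth_s, out / f"truth_{STRONG}.tsv", meta=meta)
    io.write_truth(truth_w, out / f"truth_{WEAK}.tsv", meta=meta)
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples (2 trios)")

    records = simulate_phenotype(
        genotypes=["G70", "GDH11", "K326", STRONG, WEAK],
        timepoints=[50, 60, 70, 80, 90],
        target_mph={STRONG: 9.93, WEAK: 3.98},
        noise_sd=0.03,
        seed=args.seed,
    )
    records += simulate_phenotype(
        genotypes=["G70", "GDH11", STRONG],
        timepoints=[70],
        target_mph={STRONG: 8.40},
        noise_sd=0.0,
        seed=args.seed + 2,
        trait="biomass",
        parent_value_range=(60.0, 90.0),
    )
    io.write_phenotype(records, out / "phenotype.tsv", meta=meta)
    print(f"phenotype: {len(records)} records, planted day-70 K+ MPH "
          f"{STRONG}=9.93% {WEAK}=3.98%, biomass MPH 8.40%")

    od_up = [t.gene_id for t in truth_s if t.true_pattern in ("P10", "P11", "P12")]
    annotation = simulate_go_annotation(
        gene_ids=list(counts.index),
        n_terms=150,
        enriched_term_fraction=0.05,
        target_set=od_up,
        seed=args.seed,
    )
    io.write_annotation(annotation, out / "annotation.tsv", meta=meta)
    print(f"annotation: {sum(len(v) for v in annotation.values())} gene-term pairs, "
          f"{len(od_up)} target genes for enriched terms")

    hits, qlen, fam_map = simulate_homology_hits(K_FAMILIES, n_subjects=26, seed=args.seed)
    hits.to_csv(out / "blast.tsv", sep="\t", header=False, index=False)
    io.write_two_column(qlen, out / "qlen.tsv", ("query_id", "length"))
    io.write_two_column(fam_map, out / "family_map.tsv", ("query_id", "family"))
    print(f"homology: {len(hits)} hits over 26 subjects, {len(set(fam_map.values()))} families")

    import math
    picked = [t for t in truth_s if t.true_pattern != "null"][:9]
    gene_lfc = {t.gene_id: math.log2(t.mu_hybrid / t.mu_female) for t in picked}
    ct = simulate_ct_table(gene_lfc, seed=args.seed)
    io.write_ct_table(ct, out / "ct.tsv", meta=meta)
    print(f"qPCR: Ct table for {len(gene_lfc)} target genes + reference")


if __name__ == "__main__":
    main()
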