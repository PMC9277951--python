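"""Run the whole pipeline in one shot through the orchestration layer,
writing per-stage TSVs and one machine-readable summary JSON."""

import argparse
import json
import logging
from pathlib import Path

from kheterosis.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--out", default="results/pipeline")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--skip", nargs="*", default=[])
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")

    inputs = Path(args.inputs)
    config = PipelineConfig(
        out_dir=args.out,
        counts_path=str(inputs / "counts.tsv"),
        design_path=str(inputs / "design.tsv"),
        phenotype_path=str(inputs / "phenotype.tsv"),
        annotation_path=str(inputs / "annotation.tsv"),
        blast_path=str(inputs / "blast.tsv"),
        qlen_path=str(inputs / "qlen.tsv"),
        family_map_path=str(inputs / "family_map.tsv"),
        ct_path=str(inputs / "ct.tsv"),
        seed=args.seed,
    )
    summary = run_pipeline(config, skip=set(args.skip))
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
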