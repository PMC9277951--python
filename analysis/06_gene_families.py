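"""Identify K+ channel/transporter family members from the homology-hit
table under the stringent thresholds (E-value < 1e-25, identity > 30%,
query coverage > 30%, all strict)."""

import argparse
from pathlib import Path

from kheterosis import io
from kheterosis.family import assign_families, filter_hits, read_blast6


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--out", default="results/families")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    inputs = Path(args.inputs)
    hits = read_blast6(inputs / "blast.tsv")
    qlen = io.read_qlen(inputs / "qlen.tsv")
    fam_map = io.read_family_map(inputs / "family_map.tsv")
    kept = filter_hits(hits, qlen)
    families = assign_families(kept, fam_map)
    io.write_tsv(kept, out / "hits_filtered.tsv", index=False)
    io.write_tsv(families, out / "families.tsv", index=False)
    # candidate ids for external sequence retrieval / tree building
    families["subject_id"].to_csv(out / "candidate_ids.txt", index=False, header=False)
    print(f"{len(kept)}/{len(hits)} hits pass the stringent thresholds")
    print(f"{len(families)} subject sequences assigned to "
          f"{families['family'].nunique()} families:")
    for fam, n in families["family"].value_counts().sort_index().items():
        print(f"  {fam}: {n}")


if __name__ == "__main__":
    main()
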