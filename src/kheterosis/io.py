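"""TSV readers and writers for every pipeline artifact, with provenance
headers.

All tables are plain tab-separated text. Writers prepend ``# key: value``
comment lines (version, config hash, seed) that every reader skips, so each
writer/reader pair round-trips.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .de import CountMatrix, TrioDesign, ROLES
from .phenotype import HeterosisResult, PhenotypeRecord
from .simulate import PlantedTruth


class IOError_(ValueError):
    """Raised for malformed input tables."""


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping (order-insensitive)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance(seed: int | None = None, cfg_hash: str | None = None) -> dict[str, str]:
    meta = {"version": __version__}
    if cfg_hash is not None:
        meta["config_hash"] = cfg_hash
    if seed is not None:
        meta["seed"] = str(seed)
    return meta


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- counts and design -------------------------------------------------------

def write_counts(cm: CountMatrix, path, meta: Mapping[str, str] | None = None) -> None:
    write_tsv(cm.counts, path, meta=meta)


def read_counts(path) -> CountMatrix:
    df = read_tsv(path, index_col=0)
    df.index.name = "gene_id"
    return CountMatrix(df)


def write_design(designs: Sequence[TrioDesign], path, meta: Mapping[str, str] | None = None) -> None:
    rows = []
    for d in designs:
        for role in ROLES:
            for i, sid in enumerate(d.samples[role], start=1):
                rows.append((sid, d.hybrid_id, role, i))
    df = pd.DataFrame(rows, columns=["sample_id", "genotype", "role", "replicate"])
    write_tsv(df, path, meta=meta, index=False)


def read_design(path) -> list[TrioDesign]:
    df = read_tsv(path)
    required = {"sample_id", "genotype", "role", "replicate"}
    if not required <= set(df.columns):
        raise IOError_(f"design table needs columns {sorted(required)}")
    designs = []
    for genotype, sub in df.groupby("genotype", sort=True):
        samples = {
            role: sub.loc[sub["role"] == role].sort_values("replicate")["sample_id"].tolist()
            for role in ROLES
        }
        designs.append(TrioDesign(hybrid_id=str(genotype), samples=samples))
    return designs


def write_truth(truth: Sequence[PlantedTruth], path, meta: Mapping[str, str] | None = None) -> None:
    df = pd.DataFrame(
        [(t.gene_id, t.true_pattern, t.mu_female, t.mu_male, t.mu_hybrid) for t in truth],
        columns=["gene_id", "true_pattern", "mu_female", "mu_male", "mu_hybrid"],
    )
    write_tsv(df, path, meta=meta, index=False)


def read_truth(path) -> list[PlantedTruth]:
    # keep_default_na=False: the literal pattern label "null" must survive
    df = read_tsv(path, keep_default_na=False)
    df[["mu_female", "mu_male", "mu_hybrid"]] = df[
        ["mu_female", "mu_male", "mu_hybrid"]
    ].astype(float)
    return [
        PlantedTruth(r.gene_id, r.true_pattern, r.mu_female, r.mu_male, r.mu_hybrid)
        for r in df.itertuples(index=False)
    ]


# -- phenotype ---------------------------------------------------------------

def write_phenotype(records: Sequence[PhenotypeRecord], path, meta: Mapping[str, str] | None = None) -> None:
    """Wide phenotype table: genotype, female_parent, male_parent, timepoint,
    trait, rep1..repK (K = largest replicate count; short rows left blank)."""
    k = max(len(r.replicate_values) for r in records)
    rows = []
    for r in records:
        reps = list(r.replicate_values) + [np.nan] * (k - len(r.replicate_values))
        rows.append((r.genotype, r.female_parent or "", r.male_parent or "", r.timepoint, r.trait, *reps))
    cols = ["genotype", "female_parent", "male_parent", "timepoint", "trait"] + [
        f"rep{i + 1}" for i in range(k)
    ]
    write_tsv(pd.DataFrame(rows, columns=cols), path, meta=meta, index=False)


def read_phenotype(path) -> list[PhenotypeRecord]:
    df = read_tsv(path, keep_default_na=True)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise IOError_("phenotype table has no rep1..repK columns")
    records = []
    for row in df.itertuples(index=False):
        vals = [getattr(row, c) for c in rep_cols]
        vals = [v for v in vals if pd.notna(v)]
        female = getattr(row, "female_parent", None)
        male = getattr(row, "male_parent", None)
        records.append(
            PhenotypeRecord(
                genotype=str(row.genotype),
                timepoint=int(row.timepoint),
                trait=str(row.trait),
                replicate_values=vals,
                female_parent=None if pd.isna(female) or female == "" else str(female),
                male_parent=None if pd.isna(male) or male == "" else str(male),
            )
        )
    return records


def write_heterosis(results: Sequence[HeterosisResult], path, meta: Mapping[str, str] | None = None) -> None:
    df = pd.DataFrame(
        [(r.hybrid, r.timepoint, r.trait, r.f1_mean, r.mp, r.mph_percent) for r in results],
        columns=["hybrid", "timepoint", "trait", "f1_mean", "mp", "mph_percent"],
    )
    write_tsv(df, path, meta=meta, index=False)


def read_heterosis(path) -> list[HeterosisResult]:
    df = read_tsv(path)
    return [
        HeterosisResult(
            str(r.hybrid), int(r.timepoint), r.f1_mean, r.mp, r.mph_percent, str(r.trait)
        )
        for r in df.itertuples(index=False)
    ]


# -- annotation --------------------------------------------------------------

def write_annotation(annotation: Mapping[str, Iterable[str]], path, meta: Mapping[str, str] | None = None) -> None:
    rows = [(g, t) for g in sorted(annotation) for t in sorted(annotation[g])]
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path, meta=meta, index=False)


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column (gene, term) TSV, or GAF-like rows where columns 2 and 5
    carry the gene and term. Header lines starting with # or ! are skipped."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if len(fields) >= 5:
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                raise IOError_(f"annotation line has {len(fields)} column(s): {line!r}")
            if gene == "gene_id":  # header of the two-column layout
                continue
            annotation.setdefault(gene, set()).add(term)
    return annotation


def read_parent_map(path) -> dict[str, set[str]]:
    df = read_tsv(path, header=None, names=["term_id", "parent_id"])
    df = df[df["term_id"] != "term_id"]
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.term_id), set()).add(str(r.parent_id))
    return out


# -- homology / qPCR ---------------------------------------------------------

def read_qlen(path) -> dict[str, int]:
    df = read_tsv(path, header=None, names=["query_id", "length"])
    df = df[df["query_id"] != "query_id"]
    return {str(r.query_id): int(r.length) for r in df.itertuples(index=False)}


def read_family_map(path) -> dict[str, str]:
    df = read_tsv(path, header=None, names=["query_id", "family"])
    df = df[df["query_id"] != "query_id"]
    return {str(r.query_id): str(r.family) for r in df.itertuples(index=False)}


def write_two_column(mapping: Mapping, path, columns: tuple[str, str]) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=list(columns))
    write_tsv(df, path, index=False)


def write_ct_table(ct: pd.DataFrame, path, meta: Mapping[str, str] | None = None) -> None:
    write_tsv(ct, path, meta=meta, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    df["is_reference"] = df["is_reference"].astype(bool)
    return df
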