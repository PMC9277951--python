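"""End-to-end orchestration: phenotype -> differential expression ->
expression patterns -> GO enrichment -> gene families -> qPCR concordance.

Each stage reads/writes plain TSV with a provenance header (package version,
config hash, seed) and contributes a block to one machine-readable summary
JSON. Stages can be skipped by name; a failing stage aborts the run with the
stage named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io
from .de import normalize, trio_contrasts, call_degs
from .enrichment import enrich, intersect_sets
from .family import assign_families, filter_hits, read_blast6
from .patterns import classify_genes, deg_union, summarize_patterns
from .phenotype import compute_mph, screen_hybrids
from .qpcr import concordance, relative_expression

log = logging.getLogger("kheterosis")

STAGES = ("phenotype", "de", "patterns", "enrichment", "family", "qpcr")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for one pipeline run.

    ``lfc_min`` governs DEG funnel counts; ``classifier_lfc_min`` the calls
    fed to the pattern classifier (significance-only by default, because the
    mid-parent and matched-parent sub-effects of a planted parental fold
    change sit at half its magnitude).
    """

    out_dir: str = "results/pipeline"
    counts_path: str | None = None
    design_path: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    blast_path: str | None = None
    qlen_path: str | None = None
    family_map_path: str | None = None
    ct_path: str | None = None
    ct_test_sample: str = "hybrid"
    ct_control_sample: str = "parent"
    timepoint: int = 70
    p_max: float = 0.05
    lfc_min: float = 1.0
    classifier_lfc_min: float = 0.0
    use_adjusted: bool = False
    bonferroni_alpha: float = 0.05
    evalue_max: float = 1e-25
    identity_min: float = 30.0
    coverage_min: float = 30.0
    seed: int = 0

    def hash(self) -> str:
        return io.config_hash(asdict(self))


def run_pipeline(config: PipelineConfig, skip: set[str] | frozenset[str] = frozenset()) -> dict:
    """Run every configured stage and write ``summary.json`` plus per-stage
    TSVs under ``config.out_dir``. Returns the summary dict.

    A stage also counts as skipped when its inputs are not configured.
    Deterministic given config + seed: the pipeline itself draws no random
    numbers, so identical inputs give byte-identical summaries.
    """
    unknown = set(skip) - set(STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stage(s) in skip: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = io.provenance(seed=config.seed, cfg_hash=config.hash())
    summary: dict = {"provenance": dict(meta)}

    de_tables_by_trio: dict[str, dict[str, pd.DataFrame]] = {}
    funnel_by_trio: dict[str, dict[str, pd.DataFrame]] = {}
    pattern_genes: dict[str, dict[str, list[str]]] = {}
    cm = None

    # -- phenotype ----------------------------------------------------------
    if "phenotype" not in skip and config.phenotype_path:
        try:
            records = io.read_phenotype(config.phenotype_path)
            mph = compute_mph(records)
            io.write_heterosis(mph, out / "mph.tsv", meta=meta)
            strongest, weakest = screen_hybrids(mph, config.timepoint)
            at_t = {
                r.hybrid: r.mph_percent
                for r in mph
                if r.timepoint == config.timepoint and r.trait == "k_content_percent"
            }
            summary["phenotype"] = {
                "n_hybrids": len({r.hybrid for r in mph}),
                "timepoint": config.timepoint,
                "mph_percent": {h: round(v, 4) for h, v in sorted(at_t.items())},
                "strongest": strongest,
                "weakest": weakest,
            }
            biomass = {
                r.hybrid: round(r.mph_percent, 4)
                for r in mph
                if r.timepoint == config.timepoint and r.trait == "biomass"
            }
            if biomass:
                summary["phenotype"]["biomass_mph_percent"] = dict(sorted(biomass.items()))
            log.info("phenotype: %d hybrids, strongest %s, weakest %s", len(at_t), strongest, weakest)
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise PipelineError("phenotype", str(e)) from e

    # -- differential expression -------------------------------------------
    if "de" not in skip and config.counts_path and config.design_path:
        try:
            cm = normalize(io.read_counts(config.counts_path))
            designs = io.read_design(config.design_path)
            de_block: dict = {"size_factors": {s: round(f, 6) for s, f in cm.size_factors.items()}}
            for design in designs:
                tables = trio_contrasts(
                    cm, design, p_max=config.p_max,
                    lfc_min=config.classifier_lfc_min, use_adjusted=config.use_adjusted,
                )
                de_tables_by_trio[design.hybrid_id] = tables
                funnel_by_trio[design.hybrid_id] = {}
                counts_block = {}
                for contrast, table in tables.items():
                    funnel = call_degs(
                        table, p_max=config.p_max, lfc_min=config.lfc_min,
                        use_adjusted=config.use_adjusted,
                    )
                    funnel_by_trio[design.hybrid_id][contrast] = funnel
                    io.write_tsv(
                        funnel[["contrast", "log2fc", "stat", "p", "padj", "call"]],
                        out / f"de_{design.hybrid_id}_{contrast}.tsv", meta=meta,
                    )
                    counts_block[contrast] = {
                        "tested": int(len(funnel)),
                        "up": int((funnel["call"] == "up").sum()),
                        "down": int((funnel["call"] == "down").sum()),
                    }
                    log.info(
                        "de %s %s: %d tested, %d up, %d down", design.hybrid_id,
                        contrast, counts_block[contrast]["tested"],
                        counts_block[contrast]["up"], counts_block[contrast]["down"],
                    )
                de_block[design.hybrid_id] = counts_block
            summary["de"] = de_block
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("de", str(e)) from e

    # -- expression patterns ------------------------------------------------
    if "patterns" not in skip and de_tables_by_trio:
        try:
            block = {}
            for hybrid_id, tables in de_tables_by_trio.items():
                gate = deg_union(funnel_by_trio[hybrid_id])
                assignments = classify_genes(tables, deg_gate=gate)
                io.write_tsv(assignments, out / f"patterns_{hybrid_id}.tsv", meta=meta)
                psum = summarize_patterns(assignments)
                block[hybrid_id] = psum.as_dict()
                pattern_genes[hybrid_id] = {
                    cat: assignments.index[assignments["category"] == cat].tolist()
                    for cat in ("additive", "dominant", "overdominant_down", "overdominant_up")
                }
                frac = psum.overdominant_fraction_of_nonadditive
                log.info(
                    "patterns %s: overdominant share of non-additive = %s",
                    hybrid_id, "NA" if frac is None else f"{100 * frac:.2f}%",
                )
            summary["patterns"] = block
        except Exception as e:  # noqa: BLE001
            raise PipelineError("patterns", str(e)) from e

    # -- GO enrichment -------------------------------------------------------
    if "enrichment" not in skip and config.annotation_path and pattern_genes:
        try:
            annotation = io.read_annotation(config.annotation_path)
            if cm is not None:
                background = sorted(set(annotation) & set(cm.gene_ids))
            else:
                background = sorted(annotation)
            block = {"background_size": len(background)}
            for hybrid_id, sets in pattern_genes.items():
                for cat in ("overdominant_up", "overdominant_down"):
                    genes = sorted(set(sets[cat]) & set(background))
                    if not genes:
                        continue
                    table = enrich(genes, annotation, background)
                    io.write_tsv(
                        table, out / f"enrich_{hybrid_id}_{cat}.tsv", meta=meta, index=False
                    )
                    sig = table[table["p_bonferroni"] <= config.bonferroni_alpha]
                    block[f"{hybrid_id}_{cat}"] = {
                        "set_size": len(genes),
                        "tested_terms": int(len(table)),
                        "significant_terms": int(len(sig)),
                        "top_terms": sig["term_id"].head(5).tolist(),
                    }
            trios = sorted(pattern_genes)
            if len(trios) >= 2:
                strong, weak = trios[0], trios[1]
                common = intersect_sets(
                    pattern_genes[strong]["overdominant_up"],
                    pattern_genes[weak]["dominant"],
                )
                pd.Series(common, name="gene_id").to_csv(
                    out / "intersection_genes.txt", index=False, header=False
                )
                block["intersection"] = {
                    "strong_up_overdominant_x_weak_dominant": len(common)
                }
            summary["enrichment"] = block
        except Exception as e:  # noqa: BLE001
            raise PipelineError("enrichment", str(e)) from e

    # -- gene families -------------------------------------------------------
    if (
        "family" not in skip
        and config.blast_path and config.qlen_path and config.family_map_path
    ):
        try:
            hits = read_blast6(config.blast_path)
            qlen = io.read_qlen(config.qlen_path)
            fam_map = io.read_family_map(config.family_map_path)
            kept = filter_hits(
                hits, qlen, evalue_max=config.evalue_max,
                identity_min=config.identity_min, coverage_min=config.coverage_min,
            )
            families = assign_families(kept, fam_map)
            io.write_tsv(kept, out / "hits_filtered.tsv", meta=meta, index=False)
            io.write_tsv(families, out / "families.tsv", meta=meta, index=False)
            summary["family"] = {
                "hits_in": int(len(hits)),
                "hits_kept": int(len(kept)),
                "subjects_assigned": int(len(families)),
                "per_family": {
                    f: int(n) for f, n in families["family"].value_counts().sort_index().items()
                },
            }
            log.info("family: %d/%d hits kept, %d subjects", len(kept), len(hits), len(families))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("family", str(e)) from e

    # -- qPCR ---------------------------------------------------------------
    if "qpcr" not in skip and config.ct_path:
        try:
            ct = io.read_ct_table(config.ct_path)
            ratios = relative_expression(ct, config.ct_test_sample, config.ct_control_sample)
            io.write_tsv(ratios, out / "qpcr_ratios.tsv", meta=meta)
            block = {"n_genes": int(len(ratios))}
            first = next(iter(de_tables_by_trio), None)
            if first is not None:
                rnaseq = de_tables_by_trio[first]["H_vs_P1"]["log2fc"]
                shared = sorted(set(ratios.index) & set(rnaseq.index))
                if len(shared) >= 3:
                    sign_agree, rho = concordance(
                        ratios["log2_ratio"].to_dict(), rnaseq.to_dict()
                    )
                    block["concordance"] = {
                        "n_shared": len(shared),
                        "sign_agreement": round(sign_agree, 4),
                        "spearman_rho": round(rho, 4),
                    }
            summary["qpcr"] = block
        except Exception as e:  # noqa: BLE001
            raise PipelineError("qpcr", str(e)) from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
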