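"""End-to-end orchestration: filter -> DE -> proximity -> overlap ->
association -> enrichment over a two-dataset study, with a manifest of
parameters, seeds, and per-stage row counts.

Genes and HERVs are filtered and tested separately, each feature class
with its own Jaccard threshold, per dataset. The proximity, overlap,
association and enrichment stages then integrate across datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from hervlink import associate, de, enrich, filtering, overlap, proximity
from hervlink.annotations import AnnotationSet, write_annotation, read_annotation
from hervlink.counts import CountMatrix, read_counts, write_counts
from hervlink.genesets import GeneSetCollection, read_gmt, write_gmt
from hervlink.simulate import SimulationConfig, simulate_study


@dataclass
class PipelineConfig:
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    de: de.DEConfig = field(default_factory=de.DEConfig)
    proximity: proximity.ProximityConfig = field(default_factory=proximity.ProximityConfig)
    overlap: overlap.OverlapConfig = field(default_factory=overlap.OverlapConfig)
    association: associate.AssociationConfig = field(default_factory=associate.AssociationConfig)
    enrichment: enrich.EnrichmentConfig = field(default_factory=enrich.EnrichmentConfig)
    # Jaccard threshold scan for genes; plain presence filter for the sparse
    # HERV matrices where the scan is degenerate (see filtering module)
    filter_method: dict = field(
        default_factory=lambda: {"genes": "jaccard", "hervs": "presence"}
    )
    seed: int = 20210427


@dataclass
class PipelineResult:
    de_results: dict  # (dataset, feature_class) -> DataFrame
    de_summaries: dict
    filter_results: dict
    proximity_records: dict  # dataset -> list[ProximityRecord] for DE HERVs
    intersection_tallies: dict
    distance_tests: dict
    herv_overlap: overlap.OverlapTestResult
    gene_overlap: overlap.OverlapTestResult
    fisher_hervs: overlap.FisherResult
    correlations: dict
    pair_associations: pd.DataFrame
    enrichment_results: dict
    manifest: dict


def run_pipeline(
    ann: AnnotationSet,
    counts: dict[str, dict[str, CountMatrix]],
    gene_sets: GeneSetCollection,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    datasets = sorted(counts)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "filter": asdict(cfg.filter),
            "de": asdict(cfg.de),
            "proximity": asdict(cfg.proximity),
            "overlap": asdict(cfg.overlap),
            "association": asdict(cfg.association),
            "enrichment": asdict(cfg.enrichment),
        },
        "stages": {},
    }

    # --- filter + DE per dataset and feature class -------------------------
    filter_results: dict = {}
    de_results: dict = {}
    de_summaries: dict = {}
    for d in datasets:
        for cls in ("genes", "hervs"):
            cm = counts[d][cls]
            sf = filtering.size_factors(cm)  # on the full matrix, pre-filter
            if cfg.filter_method.get(cls, "jaccard") == "presence":
                fres = filtering.presence_filter(cm, cfg.filter)
            else:
                fres = filtering.jaccard_threshold(cm, cfg.filter)
            kept = filtering.apply_filter(cm, fres)
            dres = de.nb_de_test(kept, sf, cfg.de)
            filter_results[(d, cls)] = fres
            de_results[(d, cls)] = dres
            de_summaries[(d, cls)] = de.summarize_de(dres, cfg.de.alpha)
            manifest["stages"][f"filter_de:{d}:{cls}"] = {
                "n_input": cm.shape[0],
                "n_retained": len(fres.retained_ids),
                "s_star": fres.s_star,
                "n_de": de_summaries[(d, cls)]["n_de"],
            }

    def de_ids(d, cls):
        res = de_results[(d, cls)]
        return set(res.index[res["is_de"]])

    def expressed_ids(d, cls):
        return set(filter_results[(d, cls)].retained_ids)

    # --- proximity around DE HERVs, distance test vs non-DE ----------------
    proximity_records: dict = {}
    tallies: dict = {}
    distance_tests: dict = {}
    herv_by_id = {h.locus_id: h for h in ann.hervs}
    test_cfg = proximity.ProximityConfig(
        initial_window_bp=cfg.proximity.initial_window_bp,
        max_window_bp=cfg.proximity.max_window_bp,
        expansion_step_bp=cfg.proximity.expansion_step_bp,
        gene_universe="protein_coding",
    )
    for d in datasets:
        de_h = sorted(de_ids(d, "hervs"))
        non_de_h = sorted(expressed_ids(d, "hervs") - set(de_h))
        recs_de = proximity.proximity_table(
            [herv_by_id[h] for h in de_h], ann, cfg.proximity
        )
        proximity_records[d] = recs_de
        tallies[d] = proximity.classify_intersections(recs_de)
        if de_h and non_de_h:
            recs_de_pc = proximity.proximity_table(
                [herv_by_id[h] for h in de_h], ann, test_cfg
            )
            recs_nd_pc = proximity.proximity_table(
                [herv_by_id[h] for h in non_de_h], ann, test_cfg
            )
            try:
                distance_tests[d] = proximity.distance_null_test(recs_de_pc, recs_nd_pc)
            except ValueError:
                distance_tests[d] = None
        manifest["stages"][f"proximity:{d}"] = {
            "n_de_hervs": len(de_h),
            "tally": {k: v for k, v in tallies[d].items() if k != "by_biotype"},
        }

    # --- cross-dataset overlap / Fisher / correlation ----------------------
    d1, d2 = datasets[0], datasets[1]
    herv_overlap = overlap.overlap_permutation_test(
        sorted(expressed_ids(d1, "hervs")),
        sorted(expressed_ids(d2, "hervs")),
        de_ids(d1, "hervs"),
        de_ids(d2, "hervs"),
        cfg.overlap,
    )
    gene_overlap = overlap.overlap_permutation_test(
        sorted(expressed_ids(d1, "genes")),
        sorted(expressed_ids(d2, "genes")),
        de_ids(d1, "genes"),
        de_ids(d2, "genes"),
        cfg.overlap,
    )
    fisher_hervs = overlap.fisher_de_association(
        len(de_ids(d1, "hervs")),
        len(expressed_ids(d1, "hervs")),
        len(de_ids(d2, "hervs")),
        len(expressed_ids(d2, "hervs")),
    )
    lfc1 = de_results[(d1, "hervs")]["log2fc"]
    lfc2 = de_results[(d2, "hervs")]["log2fc"]
    correlations = {}
    try:
        correlations["all"] = overlap.cross_dataset_correlation(lfc1, lfc2, "all")
        correlations["de_union"] = overlap.cross_dataset_correlation(
            lfc1, lfc2, "de_union", de_ids(d1, "hervs"), de_ids(d2, "hervs")
        )
    except ValueError:
        pass
    manifest["stages"]["overlap"] = {
        "herv_observed": herv_overlap.observed_overlap,
        "herv_null_max": herv_overlap.null_max,
        "herv_p": herv_overlap.p_empirical,
        "gene_observed": gene_overlap.observed_overlap,
        "fisher_p": fisher_hervs.p_value,
    }

    # --- pair associations for shared DE HERVs and their nearby genes ------
    shared_de = sorted(de_ids(d1, "hervs") & de_ids(d2, "hervs"))
    shared_recs = proximity.proximity_table(
        [herv_by_id[h] for h in shared_de], ann, cfg.proximity
    )
    pairs = [
        (r.herv_id, r.nearest_gene_id)
        for r in shared_recs
        if r.nearest_gene_id is not None
    ]
    gene_universe = counts[d1]["genes"].feature_ids
    pairs = [(h, g) for h, g in pairs if g in set(gene_universe)]
    if pairs:
        pair_assoc = associate.fit_pair_association(
            counts[d1]["genes"], counts[d1]["hervs"], pairs, cfg.association
        )
    else:
        pair_assoc = pd.DataFrame(
            columns=["herv_id", "gene_id", "beta", "se", "p_value", "spearman_rho", "q_value", "significant"]
        )
    manifest["stages"]["association"] = {
        "n_shared_de_hervs": len(shared_de),
        "n_pairs": len(pairs),
        "n_significant": int(pair_assoc["significant"].sum()) if len(pair_assoc) else 0,
    }

    # --- enrichment on condition-model importance scores -------------------
    enrichment_results = {}
    for d in datasets:
        kept_genes = counts[d]["genes"].subset_features(
            sorted(expressed_ids(d, "genes"))
        )
        betas = associate.fit_condition_model(kept_genes, cfg.association)
        enrichment_results[d] = enrich.score_enrichment(
            betas["beta"], gene_sets, cfg.enrichment, de_ids=de_ids(d, "genes")
        )
        manifest["stages"][f"enrichment:{d}"] = {
            "n_sets_tested": int(enrichment_results[d]["tested"].sum()),
            "n_significant": int(enrichment_results[d]["significant"].sum()),
        }

    result = PipelineResult(
        de_results=de_results,
        de_summaries=de_summaries,
        filter_results=filter_results,
        proximity_records=proximity_records,
        intersection_tallies=tallies,
        distance_tests=distance_tests,
        herv_overlap=herv_overlap,
        gene_overlap=gene_overlap,
        fisher_hervs=fisher_hervs,
        correlations=correlations,
        pair_associations=pair_assoc,
        enrichment_results=enrichment_results,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (d, cls), df in result.de_results.items():
        df.to_csv(out / f"de_{d}_{cls}.tsv", sep="\t", index_label="feature_id")
    for (d, cls), fres in result.filter_results.items():
        fres.similarity_curve.to_csv(
            out / f"filter_curve_{d}_{cls}.tsv", sep="\t", index=False
        )
    for d, recs in result.proximity_records.items():
        proximity.records_to_frame(recs).to_csv(
            out / f"proximity_{d}.tsv", sep="\t", index=False
        )
    result.pair_associations.to_csv(out / "pair_associations.tsv", sep="\t", index=False)
    for d, df in result.enrichment_results.items():
        df.to_csv(out / f"enrichment_{d}.tsv", sep="\t", index_label="set_name")
    summary = {
        "herv_overlap": {
            "observed": result.herv_overlap.observed_overlap,
            "null_max": result.herv_overlap.null_max,
            "null_mean": result.herv_overlap.null_mean,
            "p_empirical": result.herv_overlap.p_empirical,
        },
        "gene_overlap": {
            "observed": result.gene_overlap.observed_overlap,
            "null_max": result.gene_overlap.null_max,
            "p_empirical": result.gene_overlap.p_empirical,
        },
        "fisher_hervs_p": result.fisher_hervs.p_value,
        "correlations": {
            k: {"r": v.r, "n": v.n} for k, v in result.correlations.items()
        },
        "distance_tests": {
            d: (None if t is None else {"p_value": t.p_value, "median_de": t.median_distance_de, "median_non_de": t.median_distance_non_de})
            for d, t in result.distance_tests.items()
        },
        "de_summaries": {f"{d}:{c}": s for (d, c), s in result.de_summaries.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# demo study on disk


def make_demo(seed: int, out_dir: str | Path, cfg: SimulationConfig | None = None):
    """Write a complete synthetic two-dataset study to ``out_dir``:
    annotation (GTF + BED), counts and metadata TSVs per dataset and
    feature class, gene sets (GMT), and truth tables."""
    if cfg is None:
        cfg = SimulationConfig(seed=seed)
    else:
        from dataclasses import replace

        cfg = replace(cfg, seed=seed)
    study = simulate_study(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(study.annotation, out / "genes.gtf", out / "hervs.bed")
    for d, mats in study.counts.items():
        for cls, cm in mats.items():
            write_counts(cm, out / f"counts_{d}_{cls}.tsv", out / f"meta_{d}.tsv")
    write_gmt(study.gene_sets, out / "gene_sets.gmt")
    truth_rows = []
    for d in cfg.dataset_names():
        for fid in sorted(study.truth.de_gene_ids[d] | study.truth.de_herv_ids[d]):
            truth_rows.append(
                {"dataset": d, "feature_id": fid, "lfc": study.truth.lfc[d][fid]}
            )
    pd.DataFrame(truth_rows).to_csv(out / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        study.truth.linked_pairs, columns=["herv_id", "gene_id", "distance_bp"]
    ).to_csv(out / "truth_linked_pairs.tsv", sep="\t", index=False)
    return study


def load_study(in_dir: str | Path):
    """Read a demo-study directory back into pipeline inputs."""
    src = Path(in_dir)
    ann = read_annotation(src / "genes.gtf", src / "hervs.bed")
    counts: dict[str, dict[str, CountMatrix]] = {}
    for counts_path in sorted(src.glob("counts_*_*.tsv")):
        _, d, cls = counts_path.stem.split("_", 2)
        counts.setdefault(d, {})[cls] = read_counts(counts_path, src / f"meta_{d}.tsv")
    gene_sets = read_gmt(src / "gene_sets.gmt")
    return ann, counts, gene_sets
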