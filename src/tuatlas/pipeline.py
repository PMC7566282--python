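"""End-to-end orchestration: tss -> tts -> integration -> annotation ->
promoter model -> terminators, from a single structured config.

``run_pipeline`` consumes either a simulation block (scenario generated in
memory, then analysed) or a sample sheet of coverage-file paths.  Every
stage writes its catalog under the output directory and contributes counts
to a manifest that, together with the config hash and seed, suffices to
reproduce the run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import core_io, end_integration, promoter_model, synthetic_data
from . import terminator_analysis, tss_calling, tts_calling, tu_annotation

logger = logging.getLogger("tuatlas")

DEFAULT_THRESHOLDS = {
    "fdr": 0.05,
    "percentile": 95.0,
    "windows": list(tts_calling.DEFAULT_WINDOWS),
    "min_replicates": 2,
    "max_leader": 650,
    "leaderless_max": 5,
    "coalesce_window": 10,
    "refine_window": 15,
    "spacer_range": [12, 22],
    "disc_range": [3, 12],
    "fold": 10.0,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    if any(
        v <= 0
        for k, v in thresholds.items()
        if isinstance(v, (int, float)) and k != "fdr"
    ) or not (0 < thresholds["fdr"] < 1):
        raise ValueError("thresholds must be positive (fdr in (0,1))")
    cfg["thresholds"] = thresholds
    cfg.setdefault("seed", 0)
    if "simulate" not in cfg and "samples" not in cfg:
        raise ValueError("config needs a 'simulate' block or a 'samples' sheet")
    if "samples" in cfg:
        by_cond: dict = {}
        for s in cfg["samples"]:
            by_cond.setdefault((s["condition"], s["kind"]), []).append(s)
        for (cond, kind), libs in by_cond.items():
            if len(libs) < thresholds["min_replicates"]:
                raise ValueError(
                    f"condition {cond!r} has <{thresholds['min_replicates']} "
                    f"{kind} replicates"
                )
        kinds = {s["kind"] for s in cfg["samples"]}
        if "tss_treated" in kinds and "tss_untreated" not in kinds:
            raise ValueError("treated TSS libraries supplied without untreated")
    return cfg


def _load_samples(cfg: dict) -> dict:
    lengths = cfg.get("replicon_lengths")
    if lengths is None:
        genome = core_io.read_genome_fasta(cfg["genome"])
        lengths = {r: g.length for r, g in genome.items()}
    grouped: dict = {}
    for s in cfg["samples"]:
        track = core_io.read_end_coverage(
            (s["plus"], s["minus"]),
            dialect=s.get("dialect", "per_base_depth"),
            library_meta=dict(
                library_id=s.get("library_id", Path(s["plus"]).stem),
                condition_id=s["condition"],
                replicate_id=s.get("replicate", ""),
                library_kind=s["kind"],
            ),
            lengths=lengths,
        )
        grouped.setdefault(s["condition"], {}).setdefault(s["kind"], []).append(track)
    return grouped


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run all stages; returns (and optionally writes) the run manifest."""
    cfg = validate_config(config)
    th = cfg["thresholds"]
    seed = int(cfg["seed"])
    manifest: dict = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}

    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.pop("scenario", None)
        scenario = synthetic_data.default_scenario(seed=seed, **sim)
    else:
        grouped = _load_samples(cfg)
        genome = core_io.read_genome_fasta(cfg["genome"]) if "genome" in cfg else None
        genes = (
            core_io.read_gene_annotations(cfg["genes"], cfg.get("genes_format", "gff3"))
            if "genes" in cfg
            else []
        )
        preds = (
            core_io.read_transterm_output(cfg["terminators"], genome)
            if "terminators" in cfg
            else []
        )
        scenario = {"grouped": grouped, "genome": genome, "genes": genes,
                    "terminator_predictions": preds}

    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: TSS calling per condition -------------------------------
    spec = tts_calling.DynamicLambdaSpec(window_sizes=tuple(th["windows"]))
    if "simulate" in cfg:
        conditions = {
            scenario["condition_id"]: {
                "tss_treated": scenario["treated"],
                "tss_untreated": scenario["untreated"],
                "termseq": scenario["termseq"],
            }
        }
    else:
        conditions = scenario["grouped"]

    per_condition_tss = []
    for cond, kinds in sorted(conditions.items()):
        treated = kinds.get("tss_treated", [])
        untreated = kinds.get("tss_untreated", [])
        if not treated:
            continue
        per_condition_tss.append(
            tss_calling.call_condition(
                treated, untreated, cond, th["fdr"], th["percentile"]
            )
        )
    merged_tss = tss_calling.merge_conditions(per_condition_tss)
    all_tss_sites = [s for cat in per_condition_tss for s in cat]
    manifest["stages"]["tss"] = {
        "n_conditions": len(per_condition_tss),
        "n_called": sum(len(c) for c in per_condition_tss),
        "n_merged_primary": len(merged_tss),
    }
    if out:
        core_io.write_site_catalog(merged_tss, out / "tss_merged.tsv")

    # ---- stage 2: term-seq 3' termini -------------------------------------
    classifications = []
    prelim_by_cond = {}
    for cond, kinds in sorted(conditions.items()):
        term = kinds.get("termseq", [])
        if len(term) < th["min_replicates"]:
            continue
        prelim = tts_calling.call_termini_for_condition(
            term, spec, th["percentile"], th["fdr"], th["min_replicates"],
            condition_id=cond,
        )
        prelim_by_cond[cond] = prelim
    manifest["stages"]["tts_prelim"] = {
        c: len(v) for c, v in sorted(prelim_by_cond.items())
    }

    # ---- stage 3: end integration -----------------------------------------
    genes = scenario["genes"]
    for cond, kinds in sorted(conditions.items()):
        if cond not in prelim_by_cond:
            continue
        mono = end_integration.call_monophosphate_sites(
            kinds.get("tss_untreated", []), all_tss_sites, spec,
            th["percentile"], th["fdr"], th["min_replicates"], condition_id=cond,
        )
        classifications.append(
            end_integration.classify_termini(
                prelim_by_cond[cond], mono, genes, condition_id=cond
            )
        )
    classifications = end_integration.pool_processing_sites(classifications)
    final_tts = end_integration.final_tts_union(classifications)
    manifest["stages"]["end_integration"] = {
        "n_processing": len({s.key for c in classifications for s in c.processing}),
        "n_final_tts": len(final_tts),
    }
    if out:
        core_io.write_site_catalog(final_tts, out / "tts_final.tsv")

    # ---- stage 4: TU annotation -------------------------------------------
    pairs, unassigned = tu_annotation.assign_tss_to_genes(
        merged_tss, genes, th["max_leader"], th["leaderless_max"]
    )
    stats = tu_annotation.compute_utr_stats(pairs) if pairs else {}
    manifest["stages"]["tu_annotation"] = {
        "n_pairs": len(pairs),
        "n_unassigned": len(unassigned),
        **{k: stats[k] for k in ("median_utr", "n_leaderless") if k in stats},
    }
    if out and pairs:
        tu_annotation.pairs_to_frame(pairs).to_csv(
            out / "tss_gene_pairs.tsv", sep="\t", index=False
        )

    # ---- stage 5: promoter model ------------------------------------------
    refined = tss_calling.refine_for_promoter_model(merged_tss, th["refine_window"])
    windows = promoter_model.extract_promoter_windows(refined, scenario["genome"])
    model = None
    if len(windows) >= 10:
        model = promoter_model.build_promoter_model(
            windows,
            seed=seed,
            disc_range=tuple(th["disc_range"]),
            spacer_range=tuple(th["spacer_range"]),
        )
        manifest["stages"]["promoter_model"] = {
            "n_windows": len(windows),
            "n_contributing": len(model.contributing),
            "modal_spacer": model.modal_spacer,
            "modal_discriminator": model.modal_discriminator,
            "minus10_consensus": model.minus10.consensus(),
        }
        if out:
            with open(out / "promoter_model.json", "w") as fh:
                json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
    else:
        manifest["stages"]["promoter_model"] = {"n_windows": len(windows),
                                                "skipped": True}

    # ---- stage 6: terminator mapping --------------------------------------
    preds = scenario["terminator_predictions"]
    matches = terminator_analysis.map_tts_to_terminators(final_tts, preds)
    matches = terminator_analysis.annotate_orientations(matches, genes)
    manifest["stages"]["terminators"] = {
        "n_predictions": len(preds),
        "n_matches": len(matches),
        "n_matched_tts": len(terminator_analysis.dedupe_matched_tts(matches)),
        "n_matched_terminators": len(
            terminator_analysis.matched_terminator_ids(matches)
        ),
    }

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
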