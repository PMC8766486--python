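"""End-to-end orchestration of the calling and association pipeline.

Stage order: simulate? -> call -> qc -> regions -> assoc -> burden ->
bfdp -> direction.  Every stage writes its outputs as TSV under the run
output directory and updates a JSON manifest; the expensive calling
stage can be resumed from its cached outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .assoc import (
    AssociationResult,
    genomic_inflation,
    meta_fixed_effects,
    run_region_scan,
)
from .calling import call_cnvs
from .config import RunConfig
from .core import DELETION, DUPLICATION, validate_sample_sheet
from .posterior import BFDPConfig, bfdp, direction_permutation_test
from .qc import apply_region_masks, apply_sample_qc, structure_masks
from .regions import (
    assign_calls_to_regions,
    build_regions,
    gene_burden_matrix,
    harmonise_arrays,
    merge_gene_regions,
)
from .synthetic import (
    ScenarioConfig,
    StudySpec,
    VariantSpec,
    assign_case_status,
    default_chromosome_structure,
    generate_truth_cohort,
    simulate_intensity_panel,
    synthetic_exons,
)

__all__ = ["run_pipeline", "scenario_from_dict"]

CNV_TYPES = (DELETION, DUPLICATION)


def scenario_from_dict(data: dict) -> ScenarioConfig:
    data = dict(data)
    studies = [StudySpec(**s) for s in data.pop("studies")]
    variants = [VariantSpec(**v) for v in data.pop("variants", [])]
    return ScenarioConfig(studies=studies, variants=variants, **data)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _result_from_row(row) -> AssociationResult:
    return AssociationResult(
        unit_id=row["unit_id"],
        beta=row["beta"],
        se=row["se"],
        or_=row["or"],
        ci_low=row["ci_low"],
        ci_high=row["ci_high"],
        lrt_chi2=row["lrt_chi2"],
        p=row["p"],
        carriers_case=row["carriers_case"],
        carriers_control=row["carriers_control"],
        converged=bool(row["converged"]),
    )


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the pipeline described by ``config``.

    Returns a dictionary of in-memory stage outputs; all tables are also
    written to ``config.output_dir``.  With ``resume=True`` the calling
    stage is loaded from cached TSVs when present.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict = {}

    # ---------------------------------------------------------------- simulate
    if config.scenario is not None:
        scenario = scenario_from_dict(config.scenario)
        probe_maps, sheet, truth = generate_truth_cohort(scenario, config.seed)
        sheet = assign_case_status(
            truth,
            sheet,
            baseline_logit=scenario.baseline_logit,
            study_effects={s.name: s.effect for s in scenario.studies},
            seed=config.seed + 1,
        )
        panels = {}
        for i, (array, pm) in enumerate(probe_maps.items()):
            panels[array] = simulate_intensity_panel(
                pm,
                sheet,
                truth,
                noise_sd=scenario.noise_sd,
                batch_components=scenario.batch_components,
                shift_del=scenario.shift_del,
                shift_dup=scenario.shift_dup,
                seed=config.seed + 10 + i,
                het_rate=scenario.het_rate,
                baf_noise=scenario.baf_noise,
                batch_scale=scenario.batch_scale,
                noisy_multiplier=scenario.noisy_multiplier,
            )
        rio.write_probe_map(pd.concat(probe_maps.values(), ignore_index=True), out / "probe_map.tsv")
        rio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        rio.write_truth(truth, out / "truth.tsv")
        structure = default_chromosome_structure(scenario.chromosome_lengths)
        exons = synthetic_exons(truth)
        state.update(
            probe_maps=probe_maps, sheet=sheet, truth=truth, panels=panels,
            structure=structure, exons=exons,
        )
        manifest["stages"]["simulate"] = {
            "n_samples": len(sheet),
            "n_variants": len(truth),
            "arrays": {a: len(pm) for a, pm in probe_maps.items()},
        }
    else:
        probe_map = rio.read_probe_map(config.paths.probe_map)
        probe_maps = {a: g.reset_index(drop=True) for a, g in probe_map.groupby("array")}
        sheet = rio.read_sample_sheet(config.paths.sample_sheet)
        panels = {}
        for array, path in config.paths.intensities.items():
            ids = sheet.loc[sheet["array"] == array, "sample_id"].to_numpy()
            panels[array], n_missing = rio.load_intensities(path, probe_maps[array], ids)
            with np.errstate(invalid="ignore"):
                observed = 1.0 - n_missing / (2 * len(probe_maps[array]))
            sheet.loc[sheet["array"] == array, "call_rate"] = np.minimum(
                sheet.loc[sheet["array"] == array, "call_rate"].to_numpy(),
                observed.to_numpy(),
            )
        structure = (
            pd.read_csv(config.paths.chromosome_structure, sep="\t")
            if config.paths.chromosome_structure
            else None
        )
        exons = rio.read_bed(config.paths.exons).rename(columns={"name": "gene"}) if config.paths.exons else None
        state.update(probe_maps=probe_maps, sheet=sheet, panels=panels, structure=structure, exons=exons)

    sheet = validate_sample_sheet(state["sheet"])
    arrays = sorted(state["panels"], key=lambda a: -len(state["probe_maps"][a]))
    dense_array = arrays[0]

    # -------------------------------------------------------------------- call
    calls_by_array, metrics_by_array = {}, {}
    for array in arrays:
        calls_path = out / f"calls_{array}.tsv"
        metrics_path = out / f"sample_metrics_{array}.tsv"
        if resume and calls_path.exists() and metrics_path.exists():
            calls_by_array[array] = rio.read_calls(calls_path)
            metrics_by_array[array] = pd.read_csv(metrics_path, sep="\t")
            continue
        res = call_cnvs(
            state["panels"][array],
            state["probe_maps"][array],
            sheet,
            params=config.calling,
        )
        calls_by_array[array] = res.calls
        metrics_by_array[array] = res.sample_metrics
        rio.write_calls(res.calls, calls_path)
        res.sample_metrics.to_csv(metrics_path, sep="\t", index=False)
    manifest["stages"]["call"] = {
        a: {"n_calls": int(len(c))} for a, c in calls_by_array.items()
    }
    state["calls"] = calls_by_array

    # ---------------------------------------------------------------------- qc
    masks = []
    if state.get("structure") is not None:
        masks.append(structure_masks(state["structure"], config.qc.mask_buffer_bp))
    if config.paths.masks_bed:
        masks.append(rio.read_bed(config.paths.masks_bed))
    mask_df = pd.concat(masks, ignore_index=True) if masks else None

    qc_sheets, reports, ledgers = {}, [], []
    for array in arrays:
        sub_sheet = sheet[sheet["array"] == array].reset_index(drop=True)
        filtered, report, ledger = apply_sample_qc(
            sub_sheet,
            metrics_by_array[array],
            min_call_rate=config.qc.min_call_rate,
            k_sd=config.qc.dlrs_k_sd,
        )
        qc_sheets[array] = filtered
        reports.append(report)
        ledgers.append(ledger.assign(array=array))
        kept_calls = calls_by_array[array][
            calls_by_array[array]["sample_id"].isin(filtered["sample_id"])
        ].reset_index(drop=True)
        calls_by_array[array] = apply_region_masks(kept_calls, mask_df)
    qc_report = pd.concat(reports, ignore_index=True)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    qc_ledger = pd.concat(ledgers, ignore_index=True)
    qc_ledger.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {
        "n_excluded": int(qc_report["excluded"].sum()),
        "per_study": qc_ledger.to_dict("records"),
    }
    state["qc_sheets"] = qc_sheets

    mean_calls = {
        array: {
            t: float(
                len(calls_by_array[array].query("cnv_type == @t and filter_flags == ''"))
                / max(len(qc_sheets[array]), 1)
            )
            for t in CNV_TYPES
        }
        for array in arrays
    }
    manifest["stages"]["call_rates_per_sample"] = mean_calls

    # ------------------------------------------------------------------ regions
    anchors = (
        rio.read_bed(config.paths.anchor_genes).rename(columns={"name": "gene"})
        if config.paths.anchor_genes
        else None
    )
    region_tables, carrier_matrices = {}, {}
    for cnv_type in CNV_TYPES:
        dense_regions = build_regions(
            calls_by_array[dense_array],
            state["probe_maps"][dense_array],
            cnv_type,
            min_carriers=config.regions.min_carriers,
            merge_gap_probes=config.regions.merge_gap_probes,
        )
        if anchors is not None and not dense_regions.empty:
            dense_regions = merge_gene_regions(dense_regions, anchors)
        if len(arrays) > 1:
            combined, _ = harmonise_arrays(
                calls_by_array[arrays[1]],
                dense_regions,
                state["probe_maps"][arrays[1]],
                cnv_type,
                min_carriers=config.regions.min_carriers,
                merge_gap_probes=config.regions.merge_gap_probes,
                min_fraction=config.regions.min_fraction,
            )
        else:
            combined = dense_regions.assign(provenance="dense")
        region_tables[cnv_type] = combined
        for array in arrays:
            cm, _ = assign_calls_to_regions(
                calls_by_array[array][calls_by_array[array]["cnv_type"] == cnv_type],
                combined,
                qc_sheets[array]["sample_id"].to_numpy(),
                min_fraction=config.regions.min_fraction,
            )
            carrier_matrices[(cnv_type, array)] = cm
        rio.write_regions(combined, out / f"regions_{cnv_type}.tsv")
    manifest["stages"]["regions"] = {
        t: {
            "n_regions": int(len(region_tables[t])),
            "provenance": region_tables[t]["provenance"].value_counts().to_dict()
            if len(region_tables[t])
            else {},
        }
        for t in CNV_TYPES
    }
    state["regions"] = region_tables
    state["carrier_matrices"] = carrier_matrices

    # -------------------------------------------------------------------- assoc
    assoc_tables = {}
    for cnv_type in CNV_TYPES:
        per_array_frames = {}
        for array in arrays:
            frame, _ = run_region_scan(
                carrier_matrices[(cnv_type, array)],
                qc_sheets[array],
                min_carriers=config.assoc.min_carriers,
                include_pcs=config.assoc.include_pcs,
            )
            per_array_frames[array] = frame.set_index("unit_id")
        meta_rows = []
        all_units = sorted(set().union(*[set(f.index) for f in per_array_frames.values()]))
        for unit in all_units:
            per = {
                a: (_result_from_row(per_array_frames[a].loc[unit].to_dict() | {"unit_id": unit})
                    if unit in per_array_frames[a].index else None)
                for a in arrays
            }
            m = meta_fixed_effects(per, arrays)
            if m is None:
                continue
            meta_rows.append(
                {
                    "unit_id": unit,
                    "beta": m.beta,
                    "se": m.se,
                    "or": float(np.exp(m.beta)),
                    "ci_low": float(np.exp(m.beta - 1.96 * m.se)),
                    "ci_high": float(np.exp(m.beta + 1.96 * m.se)),
                    "p": m.p,
                    "directions": m.directions,
                    "lrt_chi2": (m.beta / m.se) ** 2,
                }
            )
        meta = pd.DataFrame(meta_rows)
        assoc_tables[cnv_type] = {"per_array": per_array_frames, "meta": meta}
        meta.to_csv(out / f"assoc_meta_{cnv_type}.tsv", sep="\t", index=False)
        for array in arrays:
            per_array_frames[array].to_csv(out / f"assoc_{cnv_type}_{array}.tsv", sep="\t")
    state["assoc"] = assoc_tables

    inflation = {}
    for cnv_type in CNV_TYPES:
        meta = assoc_tables[cnv_type]["meta"]
        if len(meta):
            pooled = pd.concat(qc_sheets.values())
            infl = genomic_inflation(
                meta["lrt_chi2"].to_numpy(),
                int((pooled["status"] == "case").sum()),
                int((pooled["status"] == "control").sum()),
            )
            inflation[cnv_type] = {"lambda": infl.lambda_, "lambda_1000": infl.lambda_1000}
    manifest["stages"]["assoc"] = {
        t: {"n_tested": int(len(assoc_tables[t]["meta"])), **inflation.get(t, {})}
        for t in CNV_TYPES
    }

    # ------------------------------------------------------------------- burden
    burden_tables = {}
    if state.get("exons") is not None:
        pooled_sheet = pd.concat(qc_sheets.values(), ignore_index=True)
        # samples genotyped on different arrays count as separate study strata
        pooled_sheet = pooled_sheet.assign(
            study=pooled_sheet["study"].astype(str) + "|" + pooled_sheet["array"].astype(str)
        )
        all_calls = pd.concat(calls_by_array.values(), ignore_index=True)
        for cnv_type in CNV_TYPES:
            gm, gene_summary = gene_burden_matrix(
                all_calls,
                state["exons"],
                cnv_type,
                pooled_sheet["sample_id"].to_numpy(),
                min_carriers=config.assoc.min_carriers,
            )
            frame, _ = run_region_scan(
                gm,
                pooled_sheet,
                min_carriers=config.assoc.min_carriers,
                include_pcs=config.assoc.include_pcs,
            )
            burden_tables[cnv_type] = {"results": frame, "matrix": gm, "summary": gene_summary}
            frame.to_csv(out / f"burden_{cnv_type}.tsv", sep="\t", index=False)
        manifest["stages"]["burden"] = {
            t: {"n_genes_tested": int(len(burden_tables[t]["results"]))} for t in CNV_TYPES
        }
    state["burden"] = burden_tables
    state["pooled_sheet"] = pooled_sheet if burden_tables else None

    # --------------------------------------------------------------------- bfdp
    priors = config.bfdp
    for cnv_type in CNV_TYPES:
        meta = assoc_tables[cnv_type]["meta"]
        if len(meta):
            cfg = BFDPConfig(prior_pi=priors.prior_pi_regions, k_bound=priors.k_bound)
            meta["bfdp"] = [
                bfdp(b, s, cfg).bfdp for b, s in zip(meta["beta"], meta["se"])
            ]
            meta.to_csv(out / f"assoc_meta_{cnv_type}.tsv", sep="\t", index=False)
        if cnv_type in burden_tables:
            frame = burden_tables[cnv_type]["results"]
            vals = []
            for _, row in frame.iterrows():
                known = row["unit_id"] in priors.known_genes
                cfg = BFDPConfig(
                    prior_pi=priors.prior_pi_known if known else priors.prior_pi_genes,
                    k_bound=priors.k_bound_known
                    if row["unit_id"] in ("BRCA1", "BRCA2")
                    else priors.k_bound,
                )
                # only positive associations are scored for genes
                vals.append(bfdp(row["beta"], row["se"], cfg).bfdp if row["beta"] > 0 else np.nan)
            frame["bfdp"] = vals
            frame.to_csv(out / f"burden_{cnv_type}.tsv", sep="\t", index=False)

    # ---------------------------------------------------------------- direction
    direction_rows = []
    categories = [
        (f"{t}_regions", carrier_matrices[(t, dense_array)], qc_sheets[dense_array],
         config.direction.region_exclusions)
        for t in CNV_TYPES
    ] + [
        (f"gene_{t}s", burden_tables[t]["matrix"], state["pooled_sheet"],
         config.direction.gene_exclusions)
        for t in CNV_TYPES
        if t in burden_tables
    ]
    for name, cm, cat_sheet, exclusions in categories:
        try:
            res = direction_permutation_test(
                cm,
                cat_sheet,
                exclusions=exclusions,
                n_perm=config.direction.n_perm,
                seed=config.seed + 100,
                min_carriers=config.assoc.min_carriers,
                include_pcs=config.assoc.include_pcs,
            )
        except ValueError as exc:
            warnings.warn(f"direction test skipped for {name}: {exc}")
            continue
        direction_rows.append(
            {
                "category": name,
                "u_statistic": res.u_observed,
                "direction": res.direction,
                "max_permuted": float(res.permuted_u.max()),
                "min_permuted": float(res.permuted_u.min()),
                "n_extreme": res.k_extreme,
                "p": res.p,
            }
        )
    direction_table = pd.DataFrame(direction_rows)
    direction_table.to_csv(out / "direction_tests.tsv", sep="\t", index=False)
    state["direction"] = direction_table
    manifest["stages"]["direction"] = direction_rows

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    rio.atomic_write_json(manifest, out / "manifest.json")
    state["manifest"] = manifest
    return state
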