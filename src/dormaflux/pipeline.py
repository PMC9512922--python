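"""End-to-end demo workflow tying the stages together.

``run_pipeline`` simulates an imaging cohort, corrects and compares it,
simulates and analyzes tumor-volume arms, runs the metabolomics volcano and
the gene-set enrichment, and writes every result as CSV/JSON under the
configured output directory with full provenance (config hash + seed).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import correction, enrichment, io, metabolomics, stats, survival, synthetic
from .config import RunConfig, child_seed, config_hash

__all__ = ["run_pipeline"]


def _imaging_and_compare(config: RunConfig, outdir: Path) -> dict:
    seed = child_seed(config.seed, "imaging")
    pools = {}
    qc = []
    for p, phase in enumerate(config.phases):
        profile = synthetic.PHASE_PROFILES[(config.line, config.probe, phase)]
        images = []
        for m in range(config.n_mice_per_phase):
            session, truth = synthetic.generate_imaging_session(
                profile,
                synthetic.SessionParams(shape=(config.image_size, config.image_size)),
                seed=seed + 1000 * p + m,
                mouse_id=f"{phase}_m{m}",
            )
            sess_dir = outdir / "sessions" / f"{phase}_m{m}"
            io.write_session(session, sess_dir, truth)
            image = correction.process_session(session)
            io.write_calibrated(image, outdir / "calibrated", f"{phase}_m{m}")
            images.append(image)
            qc.append({"mouse": image.mouse_id, "phase": phase, **image.qc_flags})
        pools[phase] = stats.pool_pixels(images, group=phase)
    a, b = config.phases[:2]
    test = stats.blocked_permutation_test(
        pools[a], pools[b], n_perm=config.n_permutations,
        seed=child_seed(config.seed, "compare"),
    )
    fc = stats.log2_fold_change(pools[b].mouse_means(), pools[a].mouse_means())
    pd.DataFrame(qc).to_csv(outdir / "imaging_qc.csv", index=False)
    result = {
        "comparison": f"{a}_vs_{b}",
        "probe": config.probe,
        "D": test.D_obs,
        "p_empirical": test.p_empirical,
        "n_permutations": test.n_permutations,
        "exhaustive": test.exhaustive,
        "log2fc": fc.log2fc,
        "t_p_value": fc.p_value,
    }
    pd.DataFrame([result]).to_csv(outdir / "compare_results.csv", index=False)
    return result


def _survival_stage(config: RunConfig, outdir: Path) -> dict:
    seed = child_seed(config.seed, "survival")
    presets = {
        "control": replace(synthetic.FAST_LINE, n_mice=config.n_mice_survival),
        "slow": replace(synthetic.SLOW_LINE, n_mice=config.n_mice_survival),
        "etomoxir": replace(synthetic.ETOMOXIR_ARM, n_mice=config.n_mice_survival),
    }
    calls = []
    medians = {}
    for i, arm in enumerate(config.arms):
        cohort = synthetic.generate_volume_cohort(presets[arm], seed=seed + i)
        io.cohort_to_csv(cohort, outdir / f"calipers_{arm}.csv")
        arm_calls = survival.call_cohort(cohort, delta=config.recurrence_delta)
        calls.append(arm_calls)
        km = survival.km_estimate(arm_calls["time"], arm_calls["event"])
        medians[arm] = km.median_rfs
        pd.DataFrame(
            {
                "time": km.event_times,
                "survival": km.survival_probabilities,
                "n_at_risk": km.n_at_risk,
            }
        ).to_csv(outdir / f"km_{arm}.csv", index=False)
    all_calls = pd.concat(calls, ignore_index=True)
    all_calls.to_csv(outdir / "recurrence_calls.csv", index=False)
    result: dict = {"median_rfs": medians}
    if len(config.arms) >= 2:
        a, b = config.arms[:2]
        ca = all_calls[all_calls["arm"] == a]
        cb = all_calls[all_calls["arm"] == b]
        chi2, p = survival.logrank_test(
            ca["time"], ca["event"], cb["time"], cb["event"]
        )
        result["logrank_chi2"] = chi2
        result["logrank_p"] = p
        if np.isfinite(medians[a]) and np.isfinite(medians[b]):
            result["percent_increase_rfs"] = survival.percent_increase_rfs(
                medians[a], medians[b]
            )
    return result


def _metabolomics_stage(config: RunConfig, outdir: Path) -> dict:
    seed = child_seed(config.seed, "metabolomics")
    table = synthetic.generate_metabolomics(seed=seed)
    io.metabolite_table_to_csv(table, outdir / "metabolites_raw.csv")
    imputed = metabolomics.knn_impute(table, k=config.knn_k)
    scaled = metabolomics.log_pareto_scale(imputed)
    outliers = metabolomics.detect_outliers(scaled)
    treated, control = table.group.unique()[:2]
    volc = metabolomics.volcano(
        imputed, scaled, treated, control, exclude_samples=outliers
    )
    volc.to_csv(outdir / "volcano.csv")
    (outdir / "metabolomics_log.json").write_text(
        json.dumps({"removed_outliers": outliers, "k": config.knn_k}, indent=2)
    )
    return {
        "removed_outliers": outliers,
        "significant_decreased_acylcarnitines": metabolomics.count_significant_by_class(
            volc, "acylcarnitine", "decreased"
        ),
        "significant_decreased_amino_acids": metabolomics.count_significant_by_class(
            volc, "amino acid", "decreased"
        ),
    }


def _gsea_stage(config: RunConfig, outdir: Path) -> dict:
    seed = child_seed(config.seed, "gsea")
    matrix, groups, members = synthetic.generate_expression(
        n_genes=config.n_genes,
        geneset_size=config.geneset_size,
        effect=config.expression_effect,
        seed=seed,
    )
    matrix.to_csv(outdir / "expression.csv")
    groups.rename("group").to_csv(outdir / "expression_groups.csv")
    ranked = enrichment.rank_by_fold_change(
        matrix, groups, groups.unique()[0], groups.unique()[1]
    )
    result = enrichment.permutation_pvalue(
        ranked, members, n_perm=config.n_permutations, seed=seed, name="planted_set"
    )
    frame = pd.DataFrame(
        [
            {
                "set": result.name,
                "ES": result.ES,
                "NES": result.NES,
                "p_nominal": result.p_nominal,
                "overlap": result.overlap,
            }
        ]
    )
    frame.to_csv(outdir / "gsea_results.csv", index=False)
    return frame.iloc[0].to_dict()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> correct -> compare -> survival -> metabolomics ->
    gsea and write a run manifest.  Deterministic under a fixed seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "stages": {},
    }
    manifest["stages"]["compare"] = _imaging_and_compare(config, outdir)
    manifest["stages"]["survival"] = _survival_stage(config, outdir)
    manifest["stages"]["metabolomics"] = _metabolomics_stage(config, outdir)
    manifest["stages"]["gsea"] = _gsea_stage(config, outdir)
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float)
    )
    return manifest
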