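"""End-to-end orchestration of the phenogenetic analysis on one cohort."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dp_cluster, embedding, phenogenetics, risk, synthetic
from .cohort import PatientRecord, write_cohort, write_mutations
from .config import PipelineConfig, dump_config
from .schema import MYELOID_DIAGNOSES, FeatureSchema, default_schema
from .variant_filter import apply_somatic_filter, write_decisions

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    simulate: bool = True,
    records: Sequence[PatientRecord] | None = None,
    stability: bool = False,
) -> dict:
    """Run every stage in dependency order, writing reloadable artifacts.

    With ``simulate=True`` a synthetic cohort (scaled by
    ``config.cohort_scale``) is generated first; otherwise ``records``
    must be supplied.  Returns a summary dict of headline quantities.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "config.resolved.yaml")
    schema = default_schema()
    summary: dict = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate")
        if simulate:
            sim_config = synthetic.scaled_config(config.cohort_scale)
            records, truth = synthetic.generate_cohort(
                sim_config, seed=config.seed, schema=schema
            )
            write_cohort(records, outdir / "cohort.tsv", schema)
            write_mutations(records, outdir / "mutations.tsv")
            calls, labels, pon = synthetic.generate_variant_table(seed=config.seed)
            summary["n_patients"] = len(records)
        elif records is None:
            raise ValueError("need records when simulate=False")
        else:
            truth, calls, labels, pon = None, None, None, frozenset()
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        stage("filter")
        if calls is not None:
            decisions = apply_somatic_filter(
                calls, pon, thresholds=config.filter_thresholds
            )
            write_decisions(decisions, outdir / "filter_decisions.tsv")
            summary["filter_kept"] = sum(d.kept for d in decisions)
            summary["filter_label_agreement"] = float(
                np.mean(
                    [
                        (d.kept, d.reason, d.rescued) == expected
                        for d, expected in zip(decisions, labels)
                    ]
                )
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    try:
        stage("dpcluster")
        carried = sorted(
            {v for r in records for v in r.gene_variables}
        )
        matrix = dp_cluster.build_prevalence_matrix(records, carried)
        posterior = dp_cluster.run_gibbs(
            matrix,
            alpha=config.dp.alpha,
            burn_in=config.dp.burn_in,
            n_samples=config.dp.n_samples,
            seed=config.seed,
            beta_prior=(config.dp.beta_a, config.dp.beta_b),
        )
        posterior.labels_frame().to_csv(
            outdir / "gene_clusters.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            posterior.coassignment,
            index=matrix.aberration_ids,
            columns=matrix.aberration_ids,
        ).to_csv(outdir / "coassignment.tsv", sep="\t")
        summary["n_gene_clusters"] = int(posterior.consensus_labels.max()) + 1
    except Exception as e:  # noqa: BLE001
        raise StageError("dpcluster", e) from e

    try:
        stage("embed")
        emb = embedding.axis_pipeline(
            records, schema, seed=config.seed, config=config.net, folds=5
        )
        emb.coords_frame().to_csv(outdir / "embedding.tsv", sep="\t")
        emb.gene_positions.rename("axis_position").to_csv(
            outdir / "gene_centroids.tsv", sep="\t", index_label="gene"
        )
        summary["weighted_auroc"] = emb.weighted_auroc
    except Exception as e:  # noqa: BLE001
        raise StageError("embed", e) from e

    try:
        stage("stratify")
        clusters = {
            f"C{k}": {
                matrix.aberration_ids[i]
                for i in np.flatnonzero(posterior.consensus_labels == k)
            }
            for k in range(int(posterior.consensus_labels.max()) + 1)
        }
        cluster_pos = {
            name: float(
                np.mean([emb.gene_positions.get(g, 0.0) for g in genes])
            )
            for name, genes in clusters.items()
        }
        axis_order = sorted(cluster_pos, key=lambda c: (cluster_pos[c], c))
        spectra = phenogenetics.mutation_spectra(
            [r for r in records if r.diagnosis in MYELOID_DIAGNOSES],
            matrix.aberration_ids,
            diseases=MYELOID_DIAGNOSES,
        )
        myeloid_rate = (
            spectra.carriers.sum(axis=1) / spectra.totals.sum()
        ).to_dict()
        if len(axis_order) >= 4:
            groups = risk.assign_axis_groups(
                clusters, axis_order, myeloid_rate,
                rate_threshold=config.myeloid_rate_threshold,
            )
        else:  # too few clusters to split into four blocks
            groups = risk.AxisGeneGroups(
                mapping={g: "other" for c in clusters.values() for g in c}
            )
        assignments = [
            risk.assign_risk(r, groups, threshold=config.load_threshold)
            for r in records
        ]
        pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "eln": a.eln_class,
                    "load_rmr": a.load_rmr,
                    "load_lml": a.load_lml,
                    "enhanced_group": a.enhanced_group,
                    "mdseb_stratum": a.mdseb_stratum,
                }
                for a in assignments
            ]
        ).to_csv(outdir / "risk_assignments.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("stratify", e) from e

    try:
        stage("evaluate")
        by_id = {a.patient_id: a for a in assignments}
        aml = risk.aml_analysis_subset(records)
        rows = [
            (by_id[r.patient_id].enhanced_group, risk.cr_flag(r), r)
            for r in aml
            if risk.cr_flag(r) is not None
        ]
        if rows and len({cr for _, cr, _ in rows}) == 2:
            groups_v = [g for g, _, _ in rows]
            crs = [cr for _, cr, _ in rows]
            eval_cr = risk.evaluate_binary(groups_v, crs)
            summary["cr_auroc_enhanced"] = eval_cr.auroc
            eln_ord = {"Favorable": 1, "Intermediate": 2, "Adverse": 3}
            summary["cr_auroc_eln"] = risk.evaluate_binary(
                [eln_ord[by_id[r.patient_id].eln_class] for _, _, r in rows], crs
            ).auroc
        surv = [
            (by_id[r.patient_id].enhanced_group, r.os_time, r.os_event)
            for r in aml
            if r.os_time is not None and r.os_event is not None
        ]
        if surv:
            g, t, e = map(list, zip(*surv))
            if len(set(g)) >= 2 and sum(e) > 0:
                eval_os = risk.evaluate_survival(g, t, e)
                eval_os.km_curves.to_csv(
                    outdir / "km_curves.tsv", sep="\t", index=False
                )
                summary["os_concordance_enhanced"] = eval_os.concordance
        (outdir / "evaluation.json").write_text(json.dumps(summary, indent=2))
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    if stability:
        try:
            stage("stability")
            report = embedding.bootstrap_stability(
                records, schema, B=config.bootstrap_B, seed=config.seed,
                config=config.net,
            )
            report.summary().to_csv(outdir / "stability.tsv", sep="\t", index=False)
            summary["stability_mean_tau_genes"] = float(
                np.nanmean(report.taus["genes"])
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("stability", e) from e

    return summary
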