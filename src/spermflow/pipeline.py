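"""End-to-end orchestration: events -> per-sample statistics -> reports.

``run_study_analysis`` drives the whole analysis: gating, per-assay
chromatin and physiology statistics, CASA motility subpopulations, mixed
models per chromatin variable, FDR-masked correlations and Hoeffding-D
variable clustering per analysis day, and a pooled standardized PCA with
hierarchical clustering of the observations on its leading components.
Per-sample failures are recorded and skipped; the run aborts only if every
sample fails.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, Thresholds
from .cytometry import (
    EmptyGateError,
    cma3_statistics,
    default_gate,
    gate_events,
    mbbr_statistics,
    oxodg_statistics,
    physiology_statistics,
    scsa_statistics,
)
from .models import fit_factorial_mixed_models
from .motility import classify_motility, cluster_subpopulations, summarize_subpopulations
from .multivariate import (
    cluster_observations_on_pcs,
    cluster_variables,
    correlation_matrix,
    principal_components,
)
from .synthdata import SampleData, StudyDesign, default_truths, iter_study
from .tables import EventTable, KinematicTable

__all__ = [
    "CHROMATIN_VARIABLES",
    "ReportBundle",
    "sample_statistics",
    "run_study_analysis",
]

#: The chromatin variable set carried into the multivariate layer.
CHROMATIN_VARIABLES = [
    "sd_dfi", "pct_dfi", "pct_hds",
    "mbbr_low", "mbbr_moderate", "mbbr_high", "mbbr_mfi", "disulfide_levels",
    "cma3_low", "cma3_moderate", "cma3_high", "cma3_mfi",
    "oxodg_mfi",
]


@dataclass
class ReportBundle:
    """Everything one study run produces."""

    per_sample: pd.DataFrame
    model_table: pd.DataFrame | None
    correlations: dict[str, Any]
    variable_trees: dict[str, Any]
    pca: Any
    observation_clusters: pd.DataFrame | None
    subpopulation_summary: pd.DataFrame | None
    subpopulation_percentages: pd.DataFrame | None
    gating_log: list[dict[str, Any]]
    qc_excluded: list[dict[str, str]]
    provenance: dict[str, Any]


def sample_statistics(
    sample_id: str,
    events: dict[str, EventTable],
    thresholds: Thresholds,
    gating_log: list[dict[str, Any]] | None = None,
) -> dict[str, float]:
    """Gate every assay of one sample and compute its statistic row."""
    row: dict[str, Any] = {"sample_id": sample_id}
    gated: dict[str, EventTable] = {}
    for assay, table in events.items():
        g, report = gate_events(
            table, default_gate(assay, thresholds), min_events=thresholds.min_events
        )
        gated[assay] = g
        row[f"debris_pct_{assay.lower()}"] = 100.0 * report.n_debris / report.n_total
        if gating_log is not None:
            gating_log.append(
                {
                    "sample_id": sample_id,
                    "assay": assay,
                    "n_total": report.n_total,
                    "n_debris": report.n_debris,
                    "n_sperm": report.n_sperm,
                    "warnings": report.warnings,
                }
            )

    if "SCSA" in gated:
        scsa = scsa_statistics(
            gated["SCSA"], hds_threshold=thresholds.hds_cut,
            dfi_cut=thresholds.dfi_cut,
        )
        row.update(
            sd_dfi=scsa.sd_dfi, pct_dfi=scsa.pct_dfi, pct_hds=scsa.pct_hds
        )
    if "MBBR" in gated and "MBBR_DTT" in gated:
        mbbr = mbbr_statistics(
            gated["MBBR"], gated["MBBR_DTT"],
            reference_mfi=thresholds.mbbr_reference,
            bounds=thresholds.mbbr_bounds,
        )
        row.update(
            mbbr_low=mbbr.pct_low,
            mbbr_moderate=mbbr.pct_moderate,
            mbbr_high=mbbr.pct_high,
            mbbr_mfi=mbbr.mfi_norm,
            disulfide_levels=mbbr.disulfide_index,
        )
    if "CMA3" in gated:
        cma3 = cma3_statistics(
            gated["CMA3"], reference_mfi=thresholds.cma3_reference,
            bounds=thresholds.cma3_bounds,
        )
        row.update(
            cma3_low=cma3.pct_low,
            cma3_moderate=cma3.pct_moderate,
            cma3_high=cma3.pct_high,
            cma3_mfi=cma3.mfi_norm,
        )
    if "OXODG" in gated:
        oxo = oxodg_statistics(
            gated["OXODG"], reference_mfi=thresholds.oxodg_reference,
            high_cut=thresholds.oxodg_high_cut,
        )
        row.update(oxodg_mfi=oxo.mfi_norm, oxodg_high=oxo.pct_high)
    if "PHYS1" in gated and "PHYS2" in gated:
        phys = physiology_statistics(
            gated["PHYS1"], gated["PHYS2"], thresholds=thresholds
        )
        row.update(
            pct_viable=phys.pct_viable,
            pct_apoptotic_of_viable=phys.pct_apoptotic_of_viable,
            pct_acrosome_damaged_total=phys.pct_acrosome_damaged_total,
            pct_acrosome_damaged_of_nonapoptotic=(
                phys.pct_acrosome_damaged_of_nonapoptotic
            ),
            pct_capacitated_of_nonapoptotic=phys.pct_capacitated_of_nonapoptotic,
            pct_active_mitochondria=phys.pct_active_mitochondria,
            pct_high_superoxide_of_viable=phys.pct_high_superoxide_of_viable,
            cytoplasmic_ros_mfi=phys.cytoplasmic_ros_mfi,
        )
    return row


def _motility_block(
    kinematics: dict[str, KinematicTable],
    config: RunConfig,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None, pd.DataFrame | None]:
    """Pool motile cells, cluster, and summarise per sample."""
    frames, sids = [], []
    mot_rows = []
    for sid, kin in kinematics.items():
        if kin is None:
            continue
        cls = classify_motility(
            kin.data["vcl"].to_numpy(),
            kin.data["str"].to_numpy(),
            motile_vcl_cut=config.thresholds.motile_vcl_cut,
        )
        motile = cls != "immotile"
        mot_rows.append(
            {
                "sample_id": sid,
                "pct_motile": 100.0 * float(np.mean(motile)),
                "pct_progressive": 100.0 * float(np.mean(cls == "progressive")),
            }
        )
        sub = kin.data.loc[motile]
        frames.append(sub)
        sids.extend([sid] * len(sub))
    if not frames:
        return None, None, None
    pooled = pd.concat(frames, ignore_index=True)
    motility_table = pd.DataFrame(mot_rows)
    if len(pooled) < config.clustering.stage1_k:
        return motility_table, None, None
    model = cluster_subpopulations(pooled, config.clustering, seed=config.seed)
    summary, percentages = summarize_subpopulations(
        model, pooled, sample_ids=np.array(sids)
    )
    return motility_table, summary, percentages


def run_study_analysis(
    config: RunConfig,
    samples: Iterable[SampleData] | None = None,
    write: bool = True,
) -> ReportBundle:
    """Run the full pipeline described in the module docstring.

    ``samples`` may inject an explicit sample stream (e.g. read from disk);
    by default the synthetic study defined by ``config`` is generated.
    Identical config and seed give identical outputs.
    """
    th = config.thresholds
    if samples is None:
        if config.mode == "synthetic":
            design = StudyDesign(
                boars=config.boars,
                ejaculates_per_boar=config.ejaculates_per_boar,
                days=tuple(config.days),
                events_per_sample=config.events_per_sample,
                casa_cells_per_sample=config.casa_cells_per_sample,
                seed=config.seed,
            )
            samples = iter_study(design, default_truths(), th)
        elif config.mode == "files":
            from .io import read_study_csv

            if not config.input_dir:
                raise ValueError("mode='files' requires input_dir")
            design_table, events, kinematics = read_study_csv(config.input_dir)
            samples = [
                SampleData(
                    sample_id=row["sample_id"],
                    boar=row["boar"],
                    ejaculate=row["ejaculate"],
                    day=row["day"],
                    events={
                        a: t for (s, a), t in events.items() if s == row["sample_id"]
                    },
                    kinematics=kinematics.get(row["sample_id"]),
                    truth={},
                )
                for _, row in design_table.iterrows()
            ]
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

    rows: list[dict[str, Any]] = []
    gating_log: list[dict[str, Any]] = []
    qc_excluded: list[dict[str, str]] = []
    kinematics: dict[str, KinematicTable] = {}
    meta: dict[str, dict[str, str]] = {}
    for sample in samples:
        meta[sample.sample_id] = {
            "boar": sample.boar, "ejaculate": sample.ejaculate, "day": sample.day
        }
        try:
            row = sample_statistics(
                sample.sample_id, sample.events, th, gating_log
            )
        except (EmptyGateError, ValueError) as exc:
            qc_excluded.append(
                {"sample_id": sample.sample_id, "reason": str(exc)}
            )
            continue
        row.update(meta[sample.sample_id])
        rows.append(row)
        kinematics[sample.sample_id] = sample.kinematics
    if not rows:
        raise RuntimeError("all samples failed gating/statistics")

    per_sample = pd.DataFrame(rows)

    motility_table, subpop_summary, subpop_pct = _motility_block(
        kinematics, config
    )
    if motility_table is not None:
        per_sample = per_sample.merge(motility_table, on="sample_id", how="left")
    if subpop_pct is not None:
        per_sample = per_sample.merge(
            subpop_pct.reset_index(), on="sample_id", how="left"
        )
    per_sample = per_sample.sort_values("sample_id").reset_index(drop=True)

    chroma = [v for v in CHROMATIN_VARIABLES if v in per_sample.columns]

    model_table = None
    if (
        per_sample["boar"].nunique() >= 2
        and per_sample["day"].nunique() >= 2
        and chroma
    ):
        model_table = fit_factorial_mixed_models(per_sample, chroma)

    correlations: dict[str, Any] = {}
    variable_trees: dict[str, Any] = {}
    for day, sub in per_sample.groupby("day"):
        if len(sub) >= 4 and chroma:
            correlations[day] = correlation_matrix(
                sub[chroma], alpha=config.multivariate.fdr_alpha
            )
            variable_trees[day] = cluster_variables(
                sub[chroma], method=config.multivariate.variable_linkage
            )

    pca = None
    obs_clusters = None
    if chroma and len(per_sample.dropna(subset=chroma)) > len(chroma):
        pca = principal_components(per_sample, chroma)
        complete = per_sample.dropna(subset=chroma).reset_index(drop=True)
        labels = cluster_observations_on_pcs(
            pca,
            n_pcs=config.multivariate.n_pcs_for_observation_clustering,
            k=config.multivariate.observation_clusters,
        )
        obs_clusters = pd.DataFrame(
            {
                "sample_id": complete["sample_id"],
                "day": complete["day"],
                "cluster": labels,
            }
        )

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "config": config.to_dict(),
        "n_samples_in": len(meta),
        "n_samples_analysed": len(per_sample),
        "n_samples_excluded": len(qc_excluded),
    }

    bundle = ReportBundle(
        per_sample=per_sample,
        model_table=model_table,
        correlations=correlations,
        variable_trees=variable_trees,
        pca=pca,
        observation_clusters=obs_clusters,
        subpopulation_summary=subpop_summary,
        subpopulation_percentages=subpop_pct,
        gating_log=gating_log,
        qc_excluded=qc_excluded,
        provenance=provenance,
    )
    if write:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    from .io import write_json

    out.mkdir(parents=True, exist_ok=True)
    bundle.per_sample.to_csv(out / "per_sample.csv", index=False)
    if bundle.model_table is not None:
        bundle.model_table.to_csv(out / "model_table.csv")
    for day, corr in bundle.correlations.items():
        corr.r.to_csv(out / f"correlations_r_{day}.csv")
        corr.p_adjusted.to_csv(out / f"correlations_p_adjusted_{day}.csv")
        corr.masked_r().to_csv(out / f"correlations_masked_{day}.csv")
    for day, tree in bundle.variable_trees.items():
        tree.similarity.to_csv(out / f"variable_similarity_{day}.csv")
        pd.DataFrame(
            tree.linkage_matrix,
            columns=["left", "right", "distance", "count"],
        ).to_csv(out / f"variable_linkage_{day}.csv", index=False)
    if bundle.pca is not None:
        bundle.pca.loadings.to_csv(out / "pca_loadings.csv")
        bundle.pca.contributions.to_csv(out / "pca_contributions.csv")
        bundle.pca.scores.to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame(
            {
                "eigenvalue": bundle.pca.eigenvalues,
                "explained": bundle.pca.explained,
            }
        ).to_csv(out / "pca_eigenvalues.csv", index=False)
    if bundle.observation_clusters is not None:
        bundle.observation_clusters.to_csv(
            out / "observation_clusters.csv", index=False
        )
    if bundle.subpopulation_summary is not None:
        bundle.subpopulation_summary.to_csv(
            out / "subpopulation_summary.csv", index=False
        )
    write_json(bundle.gating_log, out / "gating_report.json")
    write_json(bundle.qc_excluded, out / "qc_excluded.json")
    write_json(bundle.provenance, out / "provenance.json")
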