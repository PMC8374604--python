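"""End-to-end orchestration: fluxes -> normalization -> screening -> index -> stats.

Stage boundaries match the natural processing steps of a culture study:
flux calculation, RPKM normalization and EC aggregation, the minimum
expression filter, candidate marker fits, the genome-wide correlation
screen, marker selection, the CUE_gene index with its evaluation against
measured CUE, and factorial group statistics.  Every stage writes a
plain-text artifact so externally produced tables can be dropped in at
any boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cue_index import build_index, cue_gene, evaluate_index, simple_ratio
from .expression import aggregate_by_ec, filter_min_expression, rpkm_normalize
from .group_stats import per_group_ttests, tukey_hsd, two_way_anova
from .markers import MarkerModel, correlation_screen, fit_loglog, marker_rank
from .physiology import PhysioConstants, compute_fluxes

logger = logging.getLogger("cuegene")

__all__ = ["PipelineConfig", "run_pipeline", "select_markers"]

GROWTH_CANDIDATES = ("2.4.1.34", "2.4.1.16")
RESP_CANDIDATES = ("1.2.4.2", "1.1.1.41", "1.1.1.42")
NITROGEN_MARKER = "6.3.1.2"


@dataclass
class PipelineConfig:
    """Paths, constants and analysis options for one pipeline run."""

    phenotypes: str
    counts: str
    annotation: str
    metadata: str
    outdir: str
    constants: PhysioConstants = field(default_factory=PhysioConstants)
    rpkm_threshold: float = 10.0
    growth_candidates: tuple = GROWTH_CANDIDATES
    resp_candidates: tuple = RESP_CANDIDATES
    nitrogen_marker: str = NITROGEN_MARKER
    pseudocount: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rpkm_threshold < 0:
            raise ValueError("rpkm_threshold must be >= 0")


def select_markers(
    candidate_models: dict[str, list[MarkerModel]],
) -> tuple[MarkerModel, MarkerModel, dict]:
    """Pick the best growth and respiration candidates by R^2.

    Exact ties break toward the lexicographically smaller EC id (logged).
    Returns the two winners plus a record of runner-up R^2 values.
    """
    chosen: dict[str, MarkerModel] = {}
    record: dict = {}
    for role in ("growth", "respiration"):
        models = candidate_models.get(role, [])
        if not models:
            raise ValueError(f"no candidate models for role {role!r}")
        ordered = sorted(models, key=lambda m: (-m.r2, m.marker_label))
        if len(ordered) > 1 and math.isclose(ordered[0].r2, ordered[1].r2):
            logger.info(
                "%s candidates tied on R^2=%.4f; selecting %s by EC order",
                role, ordered[0].r2, ordered[0].marker_label,
            )
        chosen[role] = ordered[0]
        record[role] = {
            "selected": ordered[0].marker_label,
            "r2": ordered[0].r2,
            "runners_up": {m.marker_label: m.r2 for m in ordered[1:]},
        }
    return chosen["growth"], chosen["respiration"], record


def _candidate_fits(
    ecmat: pd.DataFrame,
    rates: pd.Series,
    candidates: tuple,
    response_label: str,
    pseudocount: float,
) -> list[MarkerModel]:
    models = []
    for ec in candidates:
        if ec not in ecmat.index:
            logger.warning("candidate EC %s absent from expression data; skipped", ec)
            continue
        x = ecmat.loc[ec].reindex(rates.index)
        models.append(
            fit_loglog(
                x.to_numpy(),
                rates.to_numpy(),
                response_label=response_label,
                marker_label=ec,
                pseudocount=pseudocount,
            )
        )
    return models


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the structured run report (also on disk).

    The pipeline is a pure function of its inputs and config: repeated
    runs produce identical artifacts.  Hard errors are raised only for
    inconsistent inputs; per-sample QC problems become exclusions that
    are counted in the report.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    phen = io.read_phenotypes(config.phenotypes)
    counts, annot = io.read_counts(config.counts, config.annotation)
    meta = io.read_metadata(config.metadata)

    phen_ids = {p.sample_id for p in phen}
    count_ids = set(counts.sample_ids)
    meta_ids = set(meta["sample_id"].astype(str))
    orphans = count_ids - phen_ids
    if orphans:
        raise ValueError(f"count samples without phenotypes: {sorted(orphans)}")
    orphans = count_ids - meta_ids
    if orphans:
        raise ValueError(f"count samples without metadata: {sorted(orphans)}")
    unsequenced = sorted(phen_ids - count_ids)
    if unsequenced:
        logger.info("%d sample(s) lack expression data: %s", len(unsequenced), unsequenced)

    # --- stage 1: fluxes -------------------------------------------------
    fluxes = compute_fluxes(phen, config.constants)
    io.write_fluxes(fluxes, out / "fluxes.tsv")
    flagged = {f.sample_id: sorted(f.qc_flags) for f in fluxes if f.qc_flags}
    if flagged:
        logger.info("QC-flagged samples excluded from fits: %s", flagged)
    flux_df = pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in fluxes],
            "mu": [f.mu for f in fluxes],
            "qco2": [f.qco2 for f in fluxes],
            "cue": [f.cue for f in fluxes],
        }
    ).set_index("sample_id")
    usable = [
        f.sample_id for f in fluxes if not f.qc_flags and f.sample_id in count_ids
    ]

    # --- stage 2: normalization and aggregation --------------------------
    rpkm = rpkm_normalize(counts)
    io.write_matrix(rpkm, out / "rpkm.tsv", "gene_id")
    ecmat = aggregate_by_ec(rpkm, annot)
    io.write_matrix(ecmat, out / "ec_rpkm.tsv", "ec_id")
    filtered = filter_min_expression(ecmat, config.rpkm_threshold)
    io.write_matrix(filtered, out / "ec_rpkm_filtered.tsv", "ec_id")
    retained = pd.DataFrame(
        {"ec_id": filtered.index, "min_rpkm": filtered.min(axis=1).to_numpy()}
    )
    retained.to_csv(out / "retained_ecs.tsv", sep="\t", index=False, float_format="%.10g")
    logger.info(
        "retained %d/%d EC classes at >= %g RPKM in all samples",
        len(filtered), len(ecmat), config.rpkm_threshold,
    )

    mu = flux_df.loc[usable, "mu"]
    qco2 = flux_df.loc[usable, "qco2"]
    cue = flux_df.loc[usable, "cue"]
    ec_usable = ecmat.loc[:, usable]

    # --- stage 3: candidate fits (a-priori markers, unfiltered matrix) ---
    growth_models = _candidate_fits(
        ec_usable, mu, tuple(config.growth_candidates), "mu", config.pseudocount
    )
    resp_models = _candidate_fits(
        ec_usable, qco2, tuple(config.resp_candidates), "qco2", config.pseudocount
    )
    io.write_json(
        {
            "growth": [m.to_dict() for m in growth_models],
            "respiration": [m.to_dict() for m in resp_models],
        },
        out / "candidate_models.json",
    )

    # --- stage 4: genome-wide correlation screens -------------------------
    filt_usable = filtered.loc[:, usable]
    growth_screen = correlation_screen(filt_usable, mu, "mu")
    resp_screen = correlation_screen(filt_usable, qco2, "qco2")
    growth_screen.table.to_csv(
        out / "growth_screen.tsv", sep="\t", index=False, float_format="%.10g"
    )
    resp_screen.table.to_csv(
        out / "resp_screen.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # --- stage 5: marker selection and the CUE_gene index -----------------
    report: dict = {
        "n_samples": len(phen),
        "n_sequenced": len(count_ids),
        "n_usable": len(usable),
        "qc_flagged": flagged,
        "unsequenced": unsequenced,
        "n_ec_classes": len(ecmat),
        "n_ec_retained": len(filtered),
    }
    index_done = False
    if growth_models and resp_models:
        growth_best, resp_best, selection = select_markers(
            {"growth": growth_models, "respiration": resp_models}
        )
        index = build_index(growth_best, resp_best)
        gt48 = ec_usable.loc[growth_best.marker_label]
        kgd = ec_usable.loc[resp_best.marker_label]
        idx_df = pd.DataFrame(
            {
                "sample_id": usable,
                "gt48_rpkm": gt48.to_numpy(),
                "kgd_rpkm": kgd.to_numpy(),
                "cue_gene": [
                    cue_gene(index, g, k) for g, k in zip(gt48, kgd)
                ],
                "simple_ratio": [simple_ratio(g, k) for g, k in zip(gt48, kgd)],
                "measured_cue": cue.to_numpy(),
            }
        )
        idx_df.to_csv(out / "cue_index.tsv", sep="\t", index=False, float_format="%.10g")
        eval_model = evaluate_index(idx_df["cue_gene"], idx_df["measured_cue"])
        io.write_json(
            {
                "growth_model": growth_best.to_dict(),
                "resp_model": resp_best.to_dict(),
                "compact_constant": index.compact_constant,
                "evaluation": eval_model.to_dict(),
                "selection": selection,
            },
            out / "index_model.json",
        )
        report.update(
            {
                "selected_growth_marker": growth_best.marker_label,
                "selected_resp_marker": resp_best.marker_label,
                "compact_constant": index.compact_constant,
                "candidate_table": {
                    "growth": {m.marker_label: m.to_dict() for m in growth_models},
                    "respiration": {m.marker_label: m.to_dict() for m in resp_models},
                },
                "index_evaluation": eval_model.to_dict(),
                "growth_marker_rank": (
                    marker_rank(growth_screen, growth_best.marker_label)
                    if growth_best.marker_label in set(filtered.index)
                    else None
                ),
                "resp_marker_rank": (
                    marker_rank(resp_screen, resp_best.marker_label)
                    if resp_best.marker_label in set(filtered.index)
                    else None
                ),
            }
        )
        index_done = True
    else:
        logger.info("index stage skipped: need at least one candidate per role")
        report["index_skipped_reason"] = "need at least one candidate per role"

    # --- stage 6: factorial group statistics ------------------------------
    meta_u = meta.set_index("sample_id").loc[usable]
    responses: dict[str, pd.Series] = {
        "ln_mu": np.log(mu),
        "ln_qco2": np.log(qco2),
        "ln_cue": np.log(cue),
    }
    if index_done:
        responses["ln_growth_marker"] = np.log(gt48)
        responses["ln_resp_marker"] = np.log(kgd)
        responses["cue_gene"] = idx_df.set_index("sample_id")["cue_gene"]
    if config.nitrogen_marker in ec_usable.index:
        responses["ln_gs"] = np.log(ec_usable.loc[config.nitrogen_marker])

    anova_rows = []
    for name, series in responses.items():
        vals = series.reindex(usable)
        try:
            aov = two_way_anova(vals, meta_u["isolate"], meta_u["medium"])
        except ValueError as exc:
            logger.warning("ANOVA for %s skipped: %s", name, exc)
            continue
        tab = aov.table.copy()
        tab.insert(0, "response", name)
        tab.insert(1, "term", tab.index)
        tab["model_r2"] = aov.model_r2
        anova_rows.append(tab)
        tuk = tukey_hsd(vals, meta_u["isolate"])
        tuk.table.assign(response=name).to_csv(
            out / f"tukey_{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        tt = per_group_ttests(vals, meta_u["medium"], meta_u["isolate"])
        tt.to_csv(out / f"ttests_{name}.tsv", sep="\t", index=False, float_format="%.10g")
    if anova_rows:
        pd.concat(anova_rows).to_csv(
            out / "anova.tsv", sep="\t", index=False, float_format="%.10g"
        )

    io.write_json(report, out / "report.json")
    return report


def simulate_to_dir(config, outdir: str | Path) -> None:
    """Write a synthetic study in the exact input formats of the pipeline."""
    from .synthetic import generate_study

    study = generate_study(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    io.write_phenotypes(study.phenotypes, out / "phenotypes.tsv")
    io.write_counts(
        study.counts, study.annotation, out / "counts.tsv", out / "annotation.tsv"
    )
    truth = {
        "seed": study.truth.seed,
        "marker_ecs": study.truth.marker_ecs,
        "marker_genes": study.truth.marker_genes,
        "usable_samples": study.truth.usable_samples,
        "failed_samples": study.truth.failed_samples,
        "samples": study.truth.samples.to_dict(orient="list"),
    }
    io.write_json(truth, out / "truth.json")
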