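"""End-to-end orchestration: simulate or ingest, discover, validate.

``run_discovery`` drives the diagnostic arm (DE subcomparisons, candidate
selection, survival screen, ROC ladder); ``run_validation`` drives the
prospective arm (platform detectability, case-control odds ratios,
time-to-diagnosis trends, window-restricted models, direction
concordance).  Every run writes a manifest with the seed, thresholds and a
config hash so any output table is re-derivable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidates import (
    CandidateSet,
    fit_logfc_loess,
    pooled_curve_input,
    select_candidates,
    write_candidates,
    write_curve,
)
from .datatypes import CountMatrix, ExpressionMatrix
from .de import CASE_CONTROL_CONTRASTS, run_subcomparisons, write_de_table
from .discrimination import ladder_table, model_ladder
from .io import ensure_dir, write_annotation, write_matrix
from .preprocess import filter_expressed_genes, log2_rpm
from .prospective import (
    logistic_case_control,
    validation_table,
)
from .simulate import (
    SimConfig,
    simulate_diagnostic_cohort,
    simulate_prospective_cohorts,
    simulate_survival,
)
from .survival import survival_screen
from .timetrend import detect_window_elevation, stagewise_trends

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and bookkeeping for a pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    fdr_thresh: float = 0.05
    min_fc: float = 1.0
    max_candidates: int = 30
    window_years: float = 2.0
    r_thresh: float = 0.8
    k_se: float = 2.0
    loess_span: float = 0.75
    voom_span: float = 0.5
    min_cpm: float = 1.0
    min_frac: float = 0.2
    detectability_quantile: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fdr_thresh", "min_fc", "window_years", "r_thresh", "k_se"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, stage: str, extra: dict | None = None) -> dict:
    m = {
        "tool": "bloodtrace",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }
    if extra:
        m.update(extra)
    return m


def run_discovery(config: RunConfig, counts: CountMatrix | None = None, annotation: pd.DataFrame | None = None):
    """Diagnostic arm: DE tables, candidate set, survival screen, ROC ladder.

    With no inputs, a diagnostic cohort is simulated from ``config.sim``
    (seeded by ``config.seed``) and survival outcomes are attached.
    Returns a dict bundle; if ``config.out_dir`` is set, all tables and a
    manifest are written there.
    """
    truth = None
    if counts is None:
        sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        counts, annotation, truth = simulate_diagnostic_cohort(sim)
        annotation = simulate_survival(annotation, truth, sim)
    if annotation is None:
        raise ValueError("annotation required when counts are supplied")

    filtered = filter_expressed_genes(counts, config.min_cpm, config.min_frac)
    de_tables = run_subcomparisons(filtered, annotation, span=config.voom_span)

    cc_tables = {k: v for k, v in de_tables.items() if k in CASE_CONTROL_CONTRASTS}
    ave, alfc, used_sig = pooled_curve_input(cc_tables, config.fdr_thresh)
    if ave.size >= 10:
        curve = fit_logfc_loess(ave, alfc, span=config.loess_span)
        candidates = select_candidates(
            cc_tables, curve, config.fdr_thresh, config.min_fc, config.max_candidates
        )
    else:
        warnings.warn("too few genes to fit the logFC curve; empty candidate set", stacklevel=2)
        curve, candidates = None, CandidateSet([], pd.DataFrame())

    expr = log2_rpm(filtered)
    screen = (
        survival_screen(candidates, expr.values, annotation)
        if len(candidates) and annotation["survival_time"].notna().any()
        else pd.DataFrame()
    )

    ladder = []
    if len(candidates):
        gene = candidates.genes[0]
        order = annotation["sample_id"].tolist()
        ladder = model_ladder(
            expr.values.loc[gene, order].to_numpy(dtype=float), annotation, smoking="binary", gene=gene
        )

    bundle = {
        "counts": counts,
        "annotation": annotation,
        "truth": truth,
        "de_tables": de_tables,
        "curve": curve,
        "curve_on_significant": used_sig,
        "candidates": candidates,
        "survival_screen": screen,
        "ladder": ladder,
        "expression": expr,
    }
    if config.out_dir:
        out = ensure_dir(config.out_dir)
        for cid, tab in de_tables.items():
            write_de_table(tab, out / f"de_{cid}.tsv")
        if curve is not None:
            write_curve(curve, out / "logfc_curve.tsv")
        write_candidates(candidates, out / "candidates.tsv")
        if not screen.empty:
            screen.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
        if ladder:
            ladder_table(ladder).to_csv(out / "roc_ladder.tsv", sep="\t", index=False)
        write_annotation(annotation, out / "annotation.csv")
        (out / "manifest.json").write_text(
            json.dumps(_manifest(config, "discovery", {"n_candidates": len(candidates)}), indent=2)
        )
    return bundle


def detectable_in_both(
    intensity: ExpressionMatrix,
    count_based: ExpressionMatrix,
    genes,
    quantile: float = 0.1,
) -> list[str]:
    """Platform-detectability filter for validation candidates.

    A gene is detectable when its median expression clears the given
    quantile of the platform-wide expression distribution in BOTH
    prospective datasets (a minimum-signal rule standing in for
    platform-specific intensity filters).
    """
    kept = []
    for g in genes:
        ok = True
        for em in (intensity, count_based):
            if g not in em.values.index:
                ok = False
                break
            med = em.values.loc[g].median()
            thresh = np.quantile(em.values.to_numpy().ravel(), quantile)
            if med < thresh:
                ok = False
                break
        kept.append((g, ok))
    return [g for g, ok in kept if ok]


def run_validation(
    config: RunConfig,
    candidates,
    intensity: ExpressionMatrix | None = None,
    count_based: ExpressionMatrix | None = None,
    annotation: pd.DataFrame | None = None,
    discovery_signs: dict | None = None,
):
    """Prospective arm for a candidate list.

    Produces odds-ratio tables for the three comparisons, per-gene stagewise
    trend fits with the window-elevation flag, window-restricted odds ratios
    for flagged genes, and (when discovery effect directions are supplied)
    the per-study sign tables feeding the concordance test.
    """
    genes = list(candidates.genes) if hasattr(candidates, "genes") else list(candidates)
    if not genes:
        raise ValueError("candidate list is empty")
    truth = None
    if intensity is None:
        sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        intensity, count_based, annotation, truth = simulate_prospective_cohorts(sim)

    detectable = detectable_in_both(intensity, count_based, genes, config.detectability_quantile)
    dropped = [g for g in genes if g not in detectable]
    for g in dropped:
        logger.info("candidate %s not detectable in both prospective platforms", g)

    combined = pd.concat([intensity.values, count_based.values], axis=1)
    order = annotation["sample_id"].tolist()
    combined = combined[order]

    or_rows, trend_flags, restricted_rows = [], {}, []
    for g in detectable:
        vals = combined.loc[g].to_numpy(dtype=float)
        for comparison in ("all_LC", "NSCLC", "late_stage"):
            try:
                or_rows.append(
                    logistic_case_control(vals, annotation, comparison, gene=g)
                )
            except ValueError as exc:
                warnings.warn(f"{g}/{comparison}: {exc}", stacklevel=2)
        fits = stagewise_trends(vals, annotation)
        flags = {
            label: detect_window_elevation(f, config.window_years, config.k_se)
            for label, f in fits.items()
            if f.grid.max() > config.window_years
        }
        trend_flags[g] = flags
        if any(fl["flag"] for fl in flags.values()):
            for comparison in ("all_LC", "NSCLC", "late_stage"):
                try:
                    restricted_rows.append(
                        logistic_case_control(
                            vals, annotation, comparison, window_years=config.window_years, gene=g
                        )
                    )
                except ValueError as exc:
                    warnings.warn(f"{g}/{comparison} (restricted): {exc}", stacklevel=2)

    concordance = None
    if discovery_signs:
        signs_disc, signs_val = [], []
        per_gene = {r.gene: np.sign(r.coefficient) for r in or_rows if r.comparison == "NSCLC"}
        for g, s in discovery_signs.items():
            if g in per_gene and per_gene[g] != 0 and s != 0:
                signs_disc.append(s)
                signs_val.append(per_gene[g])
        if signs_disc:
            from .prospective import direction_concordance_test

            k, n, p = direction_concordance_test(signs_disc, signs_val)
            concordance = {"concordant": k, "n": n, "p": p}

    bundle = {
        "truth": truth,
        "detectable": detectable,
        "not_detectable": dropped,
        "or_table": validation_table(or_rows),
        "trend_flags": trend_flags,
        "restricted_or_table": validation_table(restricted_rows),
        "concordance": concordance,
    }
    if config.out_dir:
        out = ensure_dir(config.out_dir)
        bundle["or_table"].to_csv(out / "validation_or.tsv", sep="\t", index=False)
        bundle["restricted_or_table"].to_csv(out / "validation_or_restricted.tsv", sep="\t", index=False)
        (out / "trend_flags.json").write_text(json.dumps(trend_flags, indent=2, default=str))
        (out / "manifest.json").write_text(
            json.dumps(
                _manifest(
                    config,
                    "validation",
                    {"n_detectable": len(detectable), "not_detectable": dropped},
                ),
                indent=2,
            )
        )
    return bundle


def simulate_to_dir(config: RunConfig, out_dir) -> None:
    """Write a full simulated dataset (diagnostic + prospective) as text."""
    out = ensure_dir(out_dir)
    sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
    counts, ann, truth = simulate_diagnostic_cohort(sim)
    ann = simulate_survival(ann, truth, sim)
    write_matrix(counts.counts, out / "diagnostic_counts.tsv")
    write_annotation(ann, out / "diagnostic_annotation.csv")
    intensity, count_based, pann, ptruth = simulate_prospective_cohorts(sim)
    write_matrix(intensity.values, out / "prospective_intensity.tsv")
    write_matrix(count_based.values, out / "prospective_log2rpm.tsv")
    write_annotation(pann, out / "prospective_annotation.csv")
    truth_json = {
        "de_gene_ids": sorted(truth.de_gene_ids),
        "trend_gene_ids": sorted(ptruth.trend_gene_ids),
        "trend_amplitude": ptruth.trend_amplitude,
        "log_hazard_coefs": truth.log_hazard_coefs,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
    (out / "manifest.json").write_text(json.dumps(_manifest(config, "simulate"), indent=2))
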