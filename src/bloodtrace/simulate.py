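"""Synthetic cohorts with planted ground truth.

Every downstream stage of the pipeline is testable without external data
through four generators: a diagnostic case/control cohort with
negative-binomial counts and planted differentially expressed genes, two
prospective cohorts (one count-based, one Gaussian-intensity-based) with
pre-diagnostic specimens and genes whose expression ramps up within a
window before diagnosis, cell-type mixtures with a case shift in
composition, and exponential survival outcomes with an expression-dependent
hazard.

Noise model for counts: NB with variance mu + phi(mu) * mu^2 and a
dispersion trend phi(mu) = phi0 + a / mu, the standard bulk RNA-seq
heteroscedasticity that the expression-dependent logFC filter exists to
counter.  All randomness flows through one ``numpy.random.default_rng``
(PCG64) seeded from the config, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MICROARRAY, CountMatrix, ExpressionMatrix, SimTruth
from .preprocess import encode_smoking, log2_rpm

STAGE_PROBS = {"early": 0.18, "middle": 0.33, "late": 0.49}
HISTOLOGY_PROBS = {"AD": 0.33, "SQ": 0.27, "OtherNSCLC": 0.23, "SCLC": 0.17}

#: typical whole-blood composition used as the Dirichlet mean
BLOOD_COMPOSITION = {
    "Neutrophil": 0.50,
    "CD4T": 0.15,
    "CD8T": 0.10,
    "B": 0.08,
    "NK": 0.07,
    "Mono": 0.10,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohorts.

    Defaults mirror the cohort dimensions of the emulated study design: a
    diagnostic cohort of roughly sixty samples per group, two prospective
    studies (125/126 intensity-based and 38/58 count-based case/control
    pairs) with times to diagnosis up to eight years, and a two-year
    pre-diagnostic elevation window.
    """

    n_genes: int = 5000
    n_samples_per_group: int = 60
    frac_de: float = 0.004
    logfc_planted: float = 1.0                     # log2 units
    baseline_logmean_dist: tuple = (3.0, 1.2)      # (mu, sigma) of ln mean count
    dispersion_params: tuple = (0.05, 2.0)         # (phi0, a): phi = phi0 + a/mu
    libsize_dist: tuple = (0.0, 0.25)              # (mu, sigma) of ln library factor
    window_years: float = 2.0
    trend_amplitude: float = 1.0                   # log2 units at diagnosis
    n_trend_genes: int = 2
    trend_noise_sd: float = 0.5                    # log2-intensity noise
    n_prospective_intensity: tuple = (125, 126)    # (cases, controls)
    n_prospective_count: tuple = (38, 58)
    max_ttd_years: float = 8.0
    case_neutrophil_shift: float = 0.05
    dirichlet_concentration: float = 60.0
    mixture_noise_sd: float = 0.5
    survival_log_hr: float = float(np.log(2.0))
    survival_base_rate: float = 0.25               # events per year
    censor_rate: float = 0.3
    batch_effect_log2: float = 0.3
    frac_batch_genes: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "censor_rate", "frac_batch_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_samples_per_group < 2:
            raise ValueError(f"n_samples_per_group must be >= 2, got {self.n_samples_per_group}")
        if self.window_years <= 0:
            raise ValueError(f"window_years must be > 0, got {self.window_years}")
        for name in ("trend_noise_sd", "mixture_noise_sd", "survival_base_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.survival_log_hr):
            raise ValueError("survival_log_hr must be finite")


def _gene_ids(n: int) -> list[str]:
    return [f"gene_{i:05d}" for i in range(n)]


def _nb_counts(rng, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + phi mu^2 (phi -> 0 degrades to Poisson)."""
    phi = np.maximum(phi, 1e-8)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, mean.shape), p)


def _covariates(rng, n: int, case: bool, study: str, smoke_detail: bool):
    sex = rng.choice(["F", "M"], size=n, p=[0.5, 0.5])
    age = np.clip(rng.normal(67.0 if case else 64.0, 8.0, size=n), 45.0, 88.0)
    p_ever = 0.92 if case else 0.8
    ever = rng.random(n) < p_ever
    status = np.where(ever, rng.choice(["former", "current"], size=n), "never")
    pack_years = np.where(ever, np.round(rng.gamma(2.0, 12.0, size=n), 1), np.nan)
    smoking7 = [
        encode_smoking("never" if s == "never" else s, None if np.isnan(py) else py)
        for s, py in zip(status, pack_years)
    ]
    return pd.DataFrame(
        {
            "case_status": "case" if case else "control",
            "sex": sex,
            "age_years": np.round(age, 1),
            "smoking_status": np.where(ever, "ever", "never"),
            "pack_years": pack_years,
            "smoking7": smoking7,
            "study": study,
        }
    )


def simulate_diagnostic_cohort(config: SimConfig):
    """Diagnostic cohort: NB counts, planted DE genes shifted in cases.

    Returns (CountMatrix, SampleAnnotation DataFrame, SimTruth).  Planted
    genes are shifted by ``logfc_planted`` log2 units in cases; a small
    batch effect is planted on a random gene subset and recorded in truth.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n_case = n_ctrl = config.n_samples_per_group
    n = n_case + n_ctrl
    genes = _gene_ids(g)

    mu_g = np.exp(rng.normal(*config.baseline_logmean_dist, size=g))
    phi0, a = config.dispersion_params
    phi_g = phi0 + a / mu_g
    libfac = np.exp(rng.normal(*config.libsize_dist, size=n))

    n_de = int(round(config.frac_de * g))
    de_idx = rng.choice(g, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    # balanced up/down planting keeps library composition comparable between
    # groups, so RPM normalization does not induce spurious shifts elsewhere
    de_signs = np.ones(n_de)
    de_signs[n_de // 2 :] = -1.0
    rng.shuffle(de_signs)
    is_case = np.array([True] * n_case + [False] * n_ctrl)

    ann_case = _covariates(rng, n_case, True, "diagnostic", smoke_detail=False)
    ann_ctrl = _covariates(rng, n_ctrl, False, "diagnostic", smoke_detail=False)
    ann = pd.concat([ann_case, ann_ctrl], ignore_index=True)
    ann.insert(0, "sample_id", [f"D{j:04d}" for j in range(n)])
    ann["stage"] = pd.NA
    ann["histology"] = pd.NA
    ann.loc[is_case, "stage"] = rng.choice(
        list(STAGE_PROBS), size=n_case, p=list(STAGE_PROBS.values())
    )
    ann.loc[is_case, "histology"] = rng.choice(
        list(HISTOLOGY_PROBS), size=n_case, p=list(HISTOLOGY_PROBS.values())
    )
    ann["batch"] = rng.choice(["b1", "b2"], size=n)
    ann["time_to_dx_years"] = np.nan
    ann["survival_time"] = np.nan
    ann["event"] = np.nan

    n_batch_genes = int(round(config.frac_batch_genes * g))
    batch_idx = rng.choice(g, size=n_batch_genes, replace=False) if n_batch_genes else np.array([], dtype=int)

    # symmetric planting: each group deviates +/- half the logFC from the
    # gene baseline, so the compositional library inflation from planted
    # genes is identical in both groups and cancels in the group contrast
    log2shift = np.zeros((g, n))
    if n_de:
        half = de_signs[:, None] * (config.logfc_planted / 2.0)
        log2shift[np.ix_(de_idx, np.where(is_case)[0])] += half
        log2shift[np.ix_(de_idx, np.where(~is_case)[0])] -= half
    in_b2 = (ann["batch"] == "b2").to_numpy()
    if n_batch_genes:
        log2shift[np.ix_(batch_idx, np.where(in_b2)[0])] += config.batch_effect_log2

    mean = mu_g[:, None] * libfac[None, :] * 2.0 ** log2shift
    counts = _nb_counts(rng, mean, phi_g[:, None])
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=ann["sample_id"].tolist()))

    truth = SimTruth(
        de_gene_ids={genes[i] for i in de_idx},
        true_logfc={genes[i]: s * config.logfc_planted for i, s in zip(de_idx, de_signs)},
        covariate_effects={
            "batch_genes": {genes[i]: config.batch_effect_log2 for i in batch_idx}
        },
    )
    # designate the first planted gene (or the most expressed gene) as the
    # survival marker; high/low from its observed log2-RPM median split
    marker = genes[de_idx[0]] if n_de else genes[int(np.argmax(mu_g))]
    expr = log2_rpm(cm).values
    vals = expr.loc[marker]
    truth.hazard_indicator = (vals > vals.median()).astype(int)
    truth.log_hazard_coefs = {"gene": marker, "high_expr": config.survival_log_hr}
    return cm, ann, truth


def _ramp(ttd: np.ndarray, window: float, amplitude: float) -> np.ndarray:
    """Piecewise-linear elevation: amplitude at diagnosis, 0 at the window edge."""
    return amplitude * np.clip(1.0 - ttd / window, 0.0, 1.0)


def simulate_prospective_cohorts(config: SimConfig):
    """Two prospective studies with planted pre-diagnostic trend genes.

    Returns (ExpressionMatrix intensity, ExpressionMatrix count-based,
    SampleAnnotation, SimTruth).  Case times-to-diagnosis are uniform on
    (0, max_ttd]; trend genes gain a linear ramp of ``trend_amplitude``
    log2 units approaching diagnosis, active only inside ``window_years``.
    Controls carry no time-to-diagnosis and no elevation.
    """
    rng = np.random.default_rng(config.seed + 1)
    g = config.n_genes
    genes = _gene_ids(g)
    trend_idx = rng.choice(g, size=config.n_trend_genes, replace=False)
    truth = SimTruth(
        trend_gene_ids={genes[i] for i in trend_idx},
        trend_amplitude=config.trend_amplitude,
    )

    base_intensity = rng.normal(7.0, 1.5, size=g)     # log2 intensity scale
    mu_g = np.exp(rng.normal(*config.baseline_logmean_dist, size=g))
    phi0, a = config.dispersion_params
    phi_g = phi0 + a / mu_g

    frames = []
    annotations = []
    for study, (n_case, n_ctrl), kind in (
        ("prosp_intensity", config.n_prospective_intensity, "intensity"),
        ("prosp_count", config.n_prospective_count, "count"),
    ):
        n = n_case + n_ctrl
        ann_case = _covariates(rng, n_case, True, study, smoke_detail=True)
        ann_ctrl = _covariates(rng, n_ctrl, False, study, smoke_detail=True)
        # matched controls: copy case sex and jitter age within +/- 2 years
        m = min(n_case, n_ctrl)
        ann_ctrl.loc[: m - 1, "sex"] = ann_case.loc[: m - 1, "sex"].to_numpy()
        ann_ctrl.loc[: m - 1, "age_years"] = np.round(
            ann_case.loc[: m - 1, "age_years"].to_numpy() + rng.uniform(-2, 2, size=m), 1
        )
        ann = pd.concat([ann_case, ann_ctrl], ignore_index=True)
        ann.insert(0, "sample_id", [f"{study[:7]}_{j:04d}" for j in range(n)])
        is_case = (ann["case_status"] == "case").to_numpy()
        ttd = np.full(n, np.nan)
        ttd[is_case] = rng.uniform(0.05, config.max_ttd_years, size=n_case)
        ann["time_to_dx_years"] = ttd
        ann["stage"] = pd.NA
        ann["histology"] = pd.NA
        ann.loc[is_case, "stage"] = rng.choice(
            list(STAGE_PROBS), size=n_case, p=list(STAGE_PROBS.values())
        )
        ann.loc[is_case, "histology"] = rng.choice(
            list(HISTOLOGY_PROBS), size=n_case, p=list(HISTOLOGY_PROBS.values())
        )
        ann["batch"] = study
        ann["survival_time"] = np.nan
        ann["event"] = np.nan

        elev = np.zeros((g, n))
        ramp = _ramp(ttd[is_case], config.window_years, config.trend_amplitude)
        elev[np.ix_(trend_idx, np.where(is_case)[0])] = ramp[None, :]

        if kind == "intensity":
            vals = (
                base_intensity[:, None]
                + elev
                + rng.normal(0.0, config.trend_noise_sd, size=(g, n))
            )
            em = ExpressionMatrix(
                pd.DataFrame(vals, index=genes, columns=ann["sample_id"].tolist()),
                modality=MICROARRAY,
            )
        else:
            libfac = np.exp(rng.normal(*config.libsize_dist, size=n))
            mean = mu_g[:, None] * libfac[None, :] * 2.0 ** elev
            counts = _nb_counts(rng, mean, phi_g[:, None])
            cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=ann["sample_id"].tolist()))
            em = log2_rpm(cm)
        frames.append(em)
        annotations.append(ann)

    annotation = pd.concat(annotations, ignore_index=True)
    return frames[0], frames[1], annotation, truth


def make_reference(rng_or_seed=0, n_markers: int = 60, cell_types=None) -> pd.DataFrame:
    """Synthetic marker-by-cell-type expression reference.

    Each cell type receives a block of markers with high signature values;
    off-signature values are low.  Full column rank by construction.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    if cell_types is None:
        cell_types = list(BLOOD_COMPOSITION)
    k = len(cell_types)
    per = n_markers // k
    ref = rng.uniform(0.5, 2.0, size=(per * k, k))
    for j in range(k):
        ref[j * per : (j + 1) * per, j] += rng.uniform(8.0, 15.0, size=per)
    markers = [f"marker_{i:03d}" for i in range(per * k)]
    return pd.DataFrame(ref, index=markers, columns=cell_types)


def simulate_cell_mixtures(reference: pd.DataFrame, config: SimConfig):
    """Bulk profiles from Dirichlet cell-type proportions.

    Cases get ``case_neutrophil_shift`` added to their Neutrophil fraction
    (other fractions rescaled so rows stay on the simplex).  Returns
    (bulk expression DataFrame, methylation-like DataFrame in [0, 1],
    SampleAnnotation, SimTruth).
    """
    if np.linalg.matrix_rank(reference.to_numpy(dtype=float)) < reference.shape[1]:
        raise ValueError("reference matrix is rank-deficient")
    rng = np.random.default_rng(config.seed + 2)
    cell_types = list(reference.columns)
    base = np.array([BLOOD_COMPOSITION.get(ct, 0.05) for ct in cell_types], dtype=float)
    base = base / base.sum()
    alpha = base * config.dirichlet_concentration
    n_case = n_ctrl = config.n_samples_per_group
    n = n_case + n_ctrl
    props = rng.dirichlet(alpha, size=n)
    is_case = np.array([True] * n_case + [False] * n_ctrl)
    delta = config.case_neutrophil_shift
    if delta and "Neutrophil" in cell_types:
        j = cell_types.index("Neutrophil")
        for i in np.where(is_case)[0]:
            old = props[i, j]
            new = min(old + delta, 0.99)
            scale = (1.0 - new) / (1.0 - old)
            props[i] *= scale
            props[i, j] = new

    R = reference.to_numpy(dtype=float)
    bulk = R @ props.T + rng.normal(0.0, config.mixture_noise_sd, size=(R.shape[0], n))
    # paired methylation-like modality from the same proportions
    R_meth = rng.beta(0.5, 0.5, size=R.shape)
    meth = np.clip(R_meth @ props.T + rng.normal(0.0, 0.01, size=(R.shape[0], n)), 0.0, 1.0)

    sample_ids = [f"M{j:04d}" for j in range(n)]
    ann_case = _covariates(rng, n_case, True, "mixture", smoke_detail=False)
    ann_ctrl = _covariates(rng, n_ctrl, False, "mixture", smoke_detail=False)
    ann = pd.concat([ann_case, ann_ctrl], ignore_index=True)
    ann.insert(0, "sample_id", sample_ids)

    truth = SimTruth(
        proportions=pd.DataFrame(props, index=sample_ids, columns=cell_types)
    )
    bulk_df = pd.DataFrame(bulk, index=reference.index, columns=sample_ids)
    meth_df = pd.DataFrame(meth, index=[f"cpg_{i:03d}" for i in range(R.shape[0])], columns=sample_ids)
    return bulk_df, meth_df, ann, truth


def simulate_survival(annotation: pd.DataFrame, truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Exponential event times with a log-hazard linear in the planted
    high/low marker indicator; independent exponential censoring tuned to
    ``censor_rate``.  Cases only; returns the annotation with
    survival_time/event filled in."""
    if truth.hazard_indicator is None:
        raise ValueError("truth carries no hazard indicator; simulate the diagnostic cohort first")
    rng = np.random.default_rng(config.seed + 3)
    ann = annotation.copy()
    is_case = (ann["case_status"] == "case").to_numpy()
    if not is_case.any():
        raise ValueError("no cases present")
    ids = ann.loc[is_case, "sample_id"]
    ind = truth.hazard_indicator.reindex(ids).fillna(0).to_numpy(dtype=float)
    log_hr = float(truth.log_hazard_coefs.get("high_expr", config.survival_log_hr))
    rate = config.survival_base_rate * np.exp(log_hr * ind)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        rate_c = config.survival_base_rate * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=len(t_event))
    else:
        t_cens = np.full(len(t_event), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    ann.loc[is_case, "survival_time"] = np.round(time, 4)
    ann.loc[is_case, "event"] = event
    return ann
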