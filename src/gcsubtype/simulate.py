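"""Synthetic multi-cohort gastric-cancer data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two tumor subtypes (mesenchymal MP, epithelial EP) separated by a
planted gene signature, stromal contamination modeled as a linear-scale
mixture of a tumor-cell profile with a non-tumor (normal mucosa) profile,
an outgroup of GIST-like purely mesenchymal samples, additive per-cohort
batch shifts, exponential proportional-hazards survival with a
subtype x chemotherapy interaction, promoter-methylation beta-values
inversely coupled to expression, and per-sample somatic mutation rates
drawn from subtype-specific log-normals.

Reproducibility contract: one global integer seed; the gene-level study
parameters (baseline means, signature genes and directions, per-gene noise
scales, methylation genes) are drawn from the substream ``(seed, 0)``, and
cohort ``i`` from substream ``(seed, i + 1)``, so any cohort can be
regenerated independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EP,
    MP,
    STAGES,
    ExpressionMatrix,
    SubtypeLabels,
    ValidationError,
)


class SimulationParameterError(ValidationError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort generator.

    All expression-scale parameters are in log2 units; hazards are events
    per year; fractions are probabilities.
    """

    n_cohorts: int = 3
    samples_per_cohort: int = 100
    n_genes: int = 2000
    n_signature_genes: int = 120          # split evenly up/down in MP
    mp_prevalence: float = 0.3            # MP is the smaller cluster
    effect_size: float = 2.5              # MP-vs-EP log2 shift on signature genes
    gene_noise_sd: float = 0.8            # noise sd of signature genes (log2)
    background_sd_log_mean: float = -0.7  # log-scale location of non-signature gene sds
    background_sd_log_sd: float = 0.6     # log-scale spread of non-signature gene sds
    batch_shift_sd: float = 0.3           # per-cohort additive gene shift (log2)
    n_normals: int = 12                   # non-tumor mucosa samples per cohort
    n_outgroup: int = 3                   # GIST-like samples per cohort
    outgroup_amplification: float = 1.5   # GIST shift = amplification * effect_size
    stromal_alpha: float = 6.0            # Beta(alpha, beta) tumor fraction
    stromal_beta: float = 2.0
    baseline_hazard: float = 0.15         # recurrence hazard, EP without chemo
    hr_mp: float = 2.0                    # MP vs EP recurrence hazard ratio
    hr_chemo_ep: float = 0.45             # chemo hazard ratio within EP
    hr_chemo_mp: float = 1.0              # chemo hazard ratio within MP
    chemo_assignment_prob: float = 0.55
    censoring_rate: float = 0.08          # independent exponential censoring
    post_recurrence_hazard: float = 0.5   # death hazard after recurrence (OS = RFS + post)
    n_methylation_genes: int = 20
    meth_expr_slope: float = -0.08        # beta-value change per log2 unit
    meth_noise_sd: float = 0.05
    mut_log_mean_mp: float = 0.7          # ln mutations/Mb, MP
    mut_log_mean_ep: float = 1.6          # ln mutations/Mb, EP
    mut_log_sd_mp: float = 0.8
    mut_log_sd_ep: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts,
            "samples_per_cohort": self.samples_per_cohort,
            "n_genes": self.n_genes,
            "n_signature_genes": self.n_signature_genes,
            "n_normals": self.n_normals,
            "n_outgroup": self.n_outgroup,
            "n_methylation_genes": self.n_methylation_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise SimulationParameterError(f"{name} must be >= 0, got {value}")
        if self.samples_per_cohort == 0:
            raise SimulationParameterError("empty cohort: samples_per_cohort must be > 0")
        if self.n_signature_genes > self.n_genes:
            raise SimulationParameterError("n_signature_genes cannot exceed n_genes")
        if self.n_methylation_genes > max(self.n_signature_genes, 1):
            raise SimulationParameterError(
                "n_methylation_genes cannot exceed n_signature_genes"
            )
        for name in ("mp_prevalence", "chemo_assignment_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.gene_noise_sd <= 0:
            raise SimulationParameterError("gene_noise_sd must be > 0")
        for name in ("hr_mp", "hr_chemo_ep", "hr_chemo_mp"):
            if getattr(self, name) <= 0:
                raise SimulationParameterError(f"{name} must be > 0")
        if self.baseline_hazard <= 0 or self.post_recurrence_hazard <= 0:
            raise SimulationParameterError("hazards must be > 0")
        if self.censoring_rate < 0:
            raise SimulationParameterError("censoring_rate must be >= 0")
        if self.stromal_alpha <= 0 or self.stromal_beta <= 0:
            raise SimulationParameterError("stromal Beta parameters must be > 0")
        if self.mut_log_sd_mp < 0 or self.mut_log_sd_ep < 0:
            raise SimulationParameterError("mutation log-sds must be >= 0")

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, payload) -> "SimulationConfig":
        if not isinstance(payload, dict):
            payload = json.loads(Path(payload).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise SimulationParameterError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: what the generator planted."""

    subtype: pd.Series                 # MP/EP per tumor sample
    signature_genes: pd.DataFrame      # index gene id, column 'direction' (+1 up in MP)
    tumor_fraction: pd.Series          # per sample (normals 0, outgroup 1)
    true_hrs: dict
    methylation_gene_ids: list[str]

    def to_json(self, path=None):
        payload = {
            "subtype": self.subtype.to_dict(),
            "signature_genes": self.signature_genes["direction"].astype(int).to_dict(),
            "tumor_fraction": {k: float(v) for k, v in self.tumor_fraction.items()},
            "true_hrs": self.true_hrs,
            "methylation_gene_ids": list(self.methylation_gene_ids),
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=1))

    @property
    def labels(self) -> SubtypeLabels:
        return SubtypeLabels(self.subtype.copy())


@dataclass(frozen=True)
class _StudyParams:
    gene_ids: np.ndarray
    baseline: np.ndarray          # baseline log2 mean per gene
    noise_sd: np.ndarray          # per-gene noise sd
    signature_idx: np.ndarray
    direction: np.ndarray         # +/-1 per signature gene (up/down in MP)
    methylation_gene_ids: list


def _study_params(config: SimulationConfig) -> _StudyParams:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    G, m = config.n_genes, config.n_signature_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])
    baseline = rng.normal(7.0, 1.0, G)
    # non-signature genes get heterogeneous (mostly smaller) noise scales so
    # that the variable-gene filter concentrates on informative features,
    # as it does on real arrays; signature genes sit at gene_noise_sd.
    noise_sd = config.gene_noise_sd * np.exp(
        rng.normal(config.background_sd_log_mean, config.background_sd_log_sd, G)
    )
    signature_idx = np.sort(rng.choice(G, size=m, replace=False))
    noise_sd[signature_idx] = config.gene_noise_sd
    direction = np.ones(m, dtype=int)
    direction[m // 2:] = -1          # half up in MP, half down
    rng.shuffle(direction)
    meth = rng.choice(signature_idx, size=config.n_methylation_genes, replace=False) \
        if config.n_methylation_genes else np.array([], dtype=int)
    return _StudyParams(
        gene_ids=gene_ids,
        baseline=baseline,
        noise_sd=noise_sd,
        signature_idx=signature_idx,
        direction=direction,
        methylation_gene_ids=[str(g) for g in gene_ids[np.sort(meth)]],
    )


def _draw_survival(rng: np.random.Generator, is_mp: np.ndarray, chemo: np.ndarray,
                   config: SimulationConfig):
    """Exponential PH recurrence times; OS = RFS + post-recurrence time.

    log-hazard = log(hr_mp)*1[MP] + log(hr_chemo_subtype)*1[chemo]; one
    shared censoring time per patient (last contact) censors both endpoints,
    which also enforces RFS <= OS sample-wise.
    """
    n = len(is_mp)
    hr_chemo = np.where(is_mp, config.hr_chemo_mp, config.hr_chemo_ep)
    hazard = config.baseline_hazard * np.where(is_mp, config.hr_mp, 1.0) \
        * np.where(chemo == 1, hr_chemo, 1.0)
    t_rec = rng.exponential(1.0 / hazard)
    t_death = t_rec + rng.exponential(1.0 / config.post_recurrence_hazard, n)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    rfs_time = np.minimum(t_rec, t_cens)
    rfs_event = (t_rec <= t_cens).astype(int)
    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)
    # guard against representable-zero times
    return (np.maximum(os_time, 1e-9), os_event,
            np.maximum(rfs_time, 1e-9), rfs_event)


def generate_cohort(config: SimulationConfig, cohort_index: int):
    """Generate one cohort: (ExpressionMatrix, clinical DataFrame, SyntheticTruth).

    Tumor samples are linear-scale mixtures ``p * tumor + (1 - p) * normal``
    of per-sample tumor-cell and normal-mucosa expression draws, with the
    tumor fraction ``p ~ Beta(stromal_alpha, stromal_beta)``; the result is
    returned on the log2 scale with the cohort batch shift added.  The
    normal profile sits at the EP level on signature genes (normal mucosa
    is epithelial), so MP tumors differ from both EP tumors and normals.
    GIST-like outgroup samples carry the MP-direction shifts at
    ``outgroup_amplification * effect_size`` and are not stromally mixed.
    """
    config.validate()
    if cohort_index < 0 or cohort_index >= config.n_cohorts:
        raise SimulationParameterError(
            f"cohort_index {cohort_index} outside 0..{config.n_cohorts - 1}"
        )
    params = _study_params(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cohort_index + 1]))
    G = config.n_genes
    delta = config.effect_size
    sig, direc = params.signature_idx, params.direction

    n_t, n_n, n_g = config.samples_per_cohort, config.n_normals, config.n_outgroup
    tumor_ids = [f"C{cohort_index}T{j:03d}" for j in range(n_t)]
    normal_ids = [f"C{cohort_index}N{j:03d}" for j in range(n_n)]
    outgroup_ids = [f"C{cohort_index}G{j:03d}" for j in range(n_g)]

    is_mp = rng.random(n_t) < config.mp_prevalence
    batch = rng.normal(0.0, config.batch_shift_sd, G)

    normal_mean = params.baseline.copy()
    normal_mean[sig] -= direc * delta / 2.0        # epithelial state on signature genes

    # per-sample tumor-cell log2 profiles
    tumor_mean = np.tile(params.baseline, (n_t, 1))
    tumor_mean[:, sig] += np.where(is_mp[:, None], 1.0, -1.0) * direc * delta / 2.0
    noise = rng.normal(0.0, 1.0, (n_t, G)) * params.noise_sd
    tumor_log2 = tumor_mean + noise
    normal_component = normal_mean + rng.normal(0.0, 1.0, (n_t, G)) * params.noise_sd

    p = rng.beta(config.stromal_alpha, config.stromal_beta, n_t)
    mixed = p[:, None] * np.exp2(tumor_log2) + (1 - p)[:, None] * np.exp2(normal_component)
    tumor_obs = np.log2(mixed) + batch

    normal_obs = (normal_mean + rng.normal(0.0, 1.0, (n_n, G)) * params.noise_sd) + batch

    outgroup_mean = np.tile(params.baseline, (n_g, 1))
    outgroup_mean[:, sig] += direc * config.outgroup_amplification * delta
    outgroup_obs = outgroup_mean + rng.normal(0.0, 1.0, (n_g, G)) * params.noise_sd + batch

    values = pd.DataFrame(
        np.vstack([tumor_obs, normal_obs, outgroup_obs]).T,
        index=pd.Index(params.gene_ids, name="gene_id"),
        columns=tumor_ids + normal_ids + outgroup_ids,
    )
    annotations = pd.DataFrame(
        {
            "tissue_type": ["tumor"] * n_t + ["normal"] * n_n + ["outgroup"] * n_g,
            "cohort": str(cohort_index),
        },
        index=values.columns,
    )
    matrix = ExpressionMatrix(values, annotations, scale="log2")

    # clinical covariates for tumor samples
    stage = rng.choice(STAGES, size=n_t, p=[0.25, 0.30, 0.30, 0.15])
    metastasis = ((stage == "IV") & (rng.random(n_t) < 0.5)).astype(int)
    age = np.clip(np.round(rng.normal(62.0, 10.0, n_t), 1), 25.0, 90.0)
    sex = np.where(rng.random(n_t) < 0.65, "M", "F")
    chemo = (rng.random(n_t) < config.chemo_assignment_prob).astype(int)
    lauren = np.where(
        is_mp,
        rng.choice(["diffuse", "intestinal", "mixed"], size=n_t, p=[0.60, 0.25, 0.15]),
        rng.choice(["intestinal", "diffuse", "mixed"], size=n_t, p=[0.55, 0.30, 0.15]),
    )
    os_time, os_event, rfs_time, rfs_event = _draw_survival(rng, is_mp, chemo, config)

    clinical = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
            "stage": stage,
            "distant_metastasis": metastasis,
            "age": age,
            "sex": sex,
            "chemo": chemo,
            "lauren": lauren,
            "tissue_type": "tumor",
            "cohort": str(cohort_index),
        }
    )
    # annotation-only rows for non-tumor samples (no survival fields)
    extra = pd.DataFrame(
        {
            "sample_id": normal_ids + outgroup_ids,
            "tissue_type": ["normal"] * n_n + ["outgroup"] * n_g,
            "cohort": str(cohort_index),
        }
    )
    clinical = pd.concat([clinical, extra], ignore_index=True)

    truth = SyntheticTruth(
        subtype=pd.Series(np.where(is_mp, MP, EP), index=tumor_ids, name="subtype"),
        signature_genes=pd.DataFrame(
            {"direction": direc}, index=pd.Index(params.gene_ids[sig], name="gene_id")
        ),
        tumor_fraction=pd.Series(
            np.concatenate([p, np.zeros(n_n), np.ones(n_g)]),
            index=values.columns,
            name="tumor_fraction",
        ),
        true_hrs={
            "hr_mp": config.hr_mp,
            "hr_chemo_ep": config.hr_chemo_ep,
            "hr_chemo_mp": config.hr_chemo_mp,
        },
        methylation_gene_ids=params.methylation_gene_ids,
    )
    return matrix, clinical, truth


def simulate_study(config: SimulationConfig):
    """All cohorts of the configured study: list of (matrix, clinical, truth)."""
    config.validate()
    return [generate_cohort(config, i) for i in range(config.n_cohorts)]


def simulate_clinical(config: SimulationConfig, n_samples: int, stream: int = 0):
    """Clinical-only draw for survival calibration studies.

    Returns a (clinical DataFrame, SubtypeLabels) pair with survival times
    from the same proportional-hazards mechanism as :func:`generate_cohort`
    but without expression data, so large replicate counts stay cheap.
    ``stream`` selects an independent reproducible substream.
    """
    config.validate()
    if n_samples <= 0:
        raise SimulationParameterError("n_samples must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100000 + stream]))
    ids = [f"P{j:04d}" for j in range(n_samples)]
    is_mp = rng.random(n_samples) < config.mp_prevalence
    stage = rng.choice(STAGES, size=n_samples, p=[0.25, 0.30, 0.30, 0.15])
    metastasis = ((stage == "IV") & (rng.random(n_samples) < 0.5)).astype(int)
    age = np.clip(np.round(rng.normal(62.0, 10.0, n_samples), 1), 25.0, 90.0)
    sex = np.where(rng.random(n_samples) < 0.65, "M", "F")
    chemo = (rng.random(n_samples) < config.chemo_assignment_prob).astype(int)
    os_time, os_event, rfs_time, rfs_event = _draw_survival(rng, is_mp, chemo, config)
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
            "stage": stage,
            "distant_metastasis": metastasis,
            "age": age,
            "sex": sex,
            "chemo": chemo,
            "lauren": "NA",
            "tissue_type": "tumor",
            "cohort": "sim",
        }
    )
    labels = SubtypeLabels(pd.Series(np.where(is_mp, MP, EP), index=ids, name="subtype"))
    return clinical, labels


def generate_methylation(truth: SyntheticTruth, expr: ExpressionMatrix,
                         config: SimulationConfig, mode: str = "inverse") -> pd.DataFrame:
    """Promoter beta-values linearly coupled to expression, clipped to [0, 1].

    beta = 0.5 + slope * (x - mean_x) + noise for each methylation gene,
    emulating the inverse methylation-expression relationship; ``mode``
    "inverse" requires a negative slope.
    """
    config.validate()
    genes = [g for g in truth.methylation_gene_ids]
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise ValidationError(f"methylation genes absent from expression: {sorted(missing)[:5]}")
    if mode == "inverse" and config.meth_expr_slope >= 0:
        raise SimulationParameterError("inverse mode requires meth_expr_slope < 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 900001]))
    x = expr.values.loc[genes]
    centered = x.sub(x.mean(axis=1), axis=0)
    beta = 0.5 + config.meth_expr_slope * centered \
        + rng.normal(0.0, config.meth_noise_sd, x.shape)
    return beta.clip(0.0, 1.0)


def generate_mutation_rates(truth: SyntheticTruth, config: SimulationConfig) -> pd.Series:
    """Per-sample somatic mutation rates (mutations/Mb), subtype log-normals."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 900002]))
    is_mp = (truth.subtype == MP).to_numpy()
    mu = np.where(is_mp, config.mut_log_mean_mp, config.mut_log_mean_ep)
    sd = np.where(is_mp, config.mut_log_sd_mp, config.mut_log_sd_ep)
    rates = np.exp(mu + sd * rng.normal(0.0, 1.0, len(is_mp)))
    return pd.Series(rates, index=truth.subtype.index, name="mutations_per_mb")
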