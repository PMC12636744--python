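"""Multi-cohort synthetic data generator.

Produces zero-inflated compositional abundance profiles with planted
cluster-associated taxa, per-cohort batch effects, covariates, cytokine
panels with planted responder structure, and negative-binomial
gene-family counts — everything the downstream stages consume, with
known ground truth.

The abundance model: per-taxon baseline log-means drawn once per spec,
gamma noise (shape ``gamma_shape``) around the per-sample mean,
Bernoulli zero-inflation, then closure to 100.  Planted effects are
applied before closure, so realized (post-closure) fold-changes are
slightly attenuated; effect signs alternate to keep the attenuation
small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    AbundanceTable,
    AnalysisConfig,
    CovariateTable,
    CytokinePanel,
    GeneFamilyTable,
    write_cytokines,
    write_gene_families,
    write_json,
    write_metadata,
    write_metaphlan_merged,
)

_STREAM_GLOBAL = 101
_STREAM_LABELS = 7
_STREAM_ABUND = 11
_STREAM_CYTO = 13
_STREAM_GENES = 17
_STREAM_META = 19


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs of the generator; identical specs give bit-identical output."""

    n_cohorts: int = 3
    n_samples_per_cohort: int = 60
    n_taxa: int = 300
    n_signal_taxa: int = 20
    log_fold_change: float = 1.0
    responder_fraction: float = 0.5
    zero_inflation: float = 0.1
    cohort_batch_sd: float = 0.3
    gamma_shape: float = 5.0
    n_cytokines: int = 27
    responder_fold: float = 8.0
    n_genes: int = 200
    n_signal_genes: int = 20
    gene_fold: float = 2.0
    nb_dispersion: float = 0.3
    cytokine_noise_sd: float = 0.25
    sex_cluster_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_samples_per_cohort", "n_taxa",
                     "n_cytokines", "n_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name, value in (("n_signal_taxa", self.n_signal_taxa),
                            ("n_signal_genes", self.n_signal_genes)):
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_signal_taxa > self.n_taxa:
            raise ValidationError("n_signal_taxa must be <= n_taxa")
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes must be <= n_genes")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValidationError("responder_fraction must be strictly inside (0, 1)")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValidationError("zero_inflation must be in [0, 1)")
        if self.cohort_batch_sd < 0:
            raise ValidationError("cohort_batch_sd must be >= 0")
        if self.gamma_shape <= 0:
            raise ValidationError("gamma_shape must be > 0")
        if self.responder_fold <= 2:
            raise ValidationError(
                "responder_fold must be > 2 (planted responders would be "
                "undetectable under the ratio>2 positivity rule)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")


@dataclass
class Truth:
    """Planted ground truth of a generated cohort set."""

    cluster_labels: dict[str, pd.Series]
    #: taxon id -> signed log-scale effect (positive = up in cluster 1)
    signal_taxa: dict[str, float]
    #: EC id -> signed log-scale effect
    signal_genes: dict[str, float]
    #: analytes carrying the responder signal
    th1_analytes: list[str]


@dataclass
class SyntheticCohortSet:
    abundance: dict[str, AbundanceTable]
    gene_families: dict[str, GeneFamilyTable]
    cytokines: dict[str, CytokinePanel]
    metadata: dict[str, CovariateTable]
    truth: Truth = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# shared per-spec parameters
# ---------------------------------------------------------------------------


def taxon_ids(spec: SimulationSpec) -> list[str]:
    return [f"SGB{i + 1:05d}" for i in range(spec.n_taxa)]


def _lineage(taxon: str, i: int) -> str:
    return (f"k__Bacteria|p__P{i % 7 + 1:02d}|c__C{i % 11 + 1:02d}"
            f"|o__O{i % 13 + 1:02d}|f__F{i % 17 + 1:02d}"
            f"|g__G{i % 29 + 1:03d}|s__Species_{i + 1:04d}|t__{taxon}")


def ec_ids(spec: SimulationSpec) -> list[str]:
    out = []
    for i in range(spec.n_genes):
        out.append(f"{i % 6 + 1}.{i % 9 + 1}.{i % 4 + 1}.{i + 1}")
    return out


def _global_params(spec: SimulationSpec):
    """Baseline means, planted-effect assignments — shared across cohorts."""
    rng = np.random.default_rng([spec.seed, _STREAM_GLOBAL])
    base_log_mean = rng.normal(0.0, 1.2, size=spec.n_taxa)
    sig_idx = rng.choice(spec.n_taxa, size=spec.n_signal_taxa, replace=False)
    # signal taxa live in a lower-abundance stratum so the planted mass
    # shift (and hence the closure attenuation felt by every taxon) is small
    base_log_mean[sig_idx] = rng.normal(-1.0, 0.6, size=spec.n_signal_taxa)
    effects = np.zeros(spec.n_taxa)
    # alternate signs so the planted mass shift (hence closure attenuation)
    # stays small
    signs = np.where(np.arange(spec.n_signal_taxa) % 2 == 0, 1.0, -1.0)
    effects[sig_idx] = signs * spec.log_fold_change

    gene_log_mean = rng.normal(4.0, 0.8, size=spec.n_genes)
    gsig_idx = rng.choice(spec.n_genes, size=spec.n_signal_genes, replace=False)
    gene_effects = np.zeros(spec.n_genes)
    gsigns = np.where(np.arange(spec.n_signal_genes) % 2 == 0, 1.0, -1.0)
    gene_effects[gsig_idx] = gsigns * np.log(spec.gene_fold)
    return base_log_mean, effects, gene_log_mean, gene_effects


def signal_taxa(spec: SimulationSpec) -> dict[str, float]:
    """Planted taxon effects, keyed by taxon id (positive = up in cluster 1)."""
    _, effects, _, _ = _global_params(spec)
    ids = taxon_ids(spec)
    return {ids[i]: float(effects[i]) for i in np.nonzero(effects)[0]}


def signal_genes(spec: SimulationSpec) -> dict[str, float]:
    _, _, _, gene_effects = _global_params(spec)
    ids = ec_ids(spec)
    return {ids[i]: float(gene_effects[i]) for i in np.nonzero(gene_effects)[0]}


def th1_analytes(spec: SimulationSpec) -> list[str]:
    n_th1 = max(3, spec.n_cytokines // 5)
    return [f"CK{i + 1:02d}" for i in range(n_th1)]


def _sample_ids(spec: SimulationSpec, cohort_index: int) -> list[str]:
    return [f"C{cohort_index + 1:02d}_S{i + 1:03d}"
            for i in range(spec.n_samples_per_cohort)]


def _check_labels(spec: SimulationSpec, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (spec.n_samples_per_cohort,):
        raise ValidationError(
            f"cluster_labels must have length n_samples_per_cohort="
            f"{spec.n_samples_per_cohort}, got {labels.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("cluster_labels must be binary")
    return labels.astype(int)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def sample_raw_abundances(spec: SimulationSpec, cluster_labels,
                          cohort_index: int = 0) -> np.ndarray:
    """Pre-closure abundance draws (samples x taxa), zeros applied."""
    labels = _check_labels(spec, cluster_labels)
    base_log_mean, effects, _, _ = _global_params(spec)
    rng = np.random.default_rng([spec.seed, _STREAM_ABUND, cohort_index])
    batch = rng.normal(0.0, spec.cohort_batch_sd, size=spec.n_taxa) \
        if spec.cohort_batch_sd > 0 else np.zeros(spec.n_taxa)
    log_mu = base_log_mean[None, :] + batch[None, :] \
        + np.outer(labels, effects)
    mu = np.exp(log_mu)
    vals = rng.gamma(spec.gamma_shape, mu / spec.gamma_shape)
    if spec.zero_inflation > 0:
        mask = rng.random(vals.shape) < spec.zero_inflation
        vals = np.where(mask, 0.0, vals)
    # guarantee at least one positive taxon per sample
    dead = vals.sum(axis=1) == 0
    if dead.any():
        vals[dead, np.argmax(mu[dead], axis=1)] = mu[dead].max(axis=1)
    return vals


def generate_abundances(spec: SimulationSpec, cluster_labels,
                        cohort_index: int = 0) -> AbundanceTable:
    """Closed (rows sum to 100) relative-abundance table for one cohort."""
    raw = sample_raw_abundances(spec, cluster_labels, cohort_index)
    closed = raw / raw.sum(axis=1, keepdims=True) * 100.0
    ids = taxon_ids(spec)
    values = pd.DataFrame(closed, index=_sample_ids(spec, cohort_index),
                          columns=ids)
    taxonomy = {t: _lineage(t, i) for i, t in enumerate(ids)}
    return AbundanceTable(values=values, taxonomy=taxonomy)


def generate_cytokine_panel(spec: SimulationSpec, cluster_labels,
                            cohort_index: int = 0) -> CytokinePanel:
    """Stimulated/control panel with responder signal on the Th1 analytes.

    Responders (label 1) draw stimulated/control ratios with geometric
    mean ``responder_fold`` on the Th1 subset; everyone else is centred
    at ratio 1.  Paired pre-vaccination values are centred at ratio 1
    for all samples.
    """
    labels = _check_labels(spec, cluster_labels)
    rng = np.random.default_rng([spec.seed, _STREAM_CYTO, cohort_index])
    n, m = spec.n_samples_per_cohort, spec.n_cytokines
    analytes = [f"CK{i + 1:02d}" for i in range(m)]
    th1 = np.zeros(m, dtype=bool)
    th1[:len(th1_analytes(spec))] = True
    sd = spec.cytokine_noise_sd

    def draw(pre: bool) -> tuple[np.ndarray, np.ndarray]:
        ctrl = np.exp(rng.normal(1.0, 0.5, size=(n, m)))
        log_ratio = rng.normal(0.0, sd, size=(n, m))
        if not pre:
            boost = np.outer(labels, th1.astype(float)) * np.log(spec.responder_fold)
            log_ratio = log_ratio + boost
        return ctrl * np.exp(log_ratio), ctrl

    post_stim, post_ctrl = draw(pre=False)
    pre_stim, pre_ctrl = draw(pre=True)
    idx = _sample_ids(spec, cohort_index)

    def frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=idx, columns=analytes)

    return CytokinePanel(stimulated=frame(post_stim), control=frame(post_ctrl),
                         pre_stimulated=frame(pre_stim),
                         pre_control=frame(pre_ctrl))


def generate_gene_families(spec: SimulationSpec, cluster_labels,
                           cohort_index: int = 0) -> GeneFamilyTable:
    """Negative-binomial RPK-like counts with planted multiplicative effects."""
    labels = _check_labels(spec, cluster_labels)
    _, _, gene_log_mean, gene_effects = _global_params(spec)
    rng = np.random.default_rng([spec.seed, _STREAM_GENES, cohort_index])
    batch = rng.normal(0.0, spec.cohort_batch_sd, size=spec.n_genes) \
        if spec.cohort_batch_sd > 0 else np.zeros(spec.n_genes)
    mu = np.exp(gene_log_mean[None, :] + batch[None, :]
                + np.outer(labels, gene_effects))
    # gamma-Poisson mixture == negative binomial with dispersion alpha
    lam = rng.gamma(1.0 / spec.nb_dispersion, mu * spec.nb_dispersion)
    counts = rng.poisson(lam).astype(float)
    values = pd.DataFrame(counts, index=_sample_ids(spec, cohort_index),
                          columns=ec_ids(spec))
    return GeneFamilyTable(values=values)


def generate_cohort_set(spec: SimulationSpec) -> SyntheticCohortSet:
    """The full multi-cohort dataset plus its planted truth."""
    label_rng = np.random.default_rng([spec.seed, _STREAM_LABELS])
    meta_rng = np.random.default_rng([spec.seed, _STREAM_META])
    abundance, genes, cytokines, metadata, labels = {}, {}, {}, {}, {}
    for c in range(spec.n_cohorts):
        cohort = f"cohort{c + 1:02d}"
        n = spec.n_samples_per_cohort
        lab = (label_rng.random(n) < spec.responder_fraction).astype(int)
        if lab.min() == lab.max():  # force both clusters to exist
            lab[0] = 1 - lab[0]
        sample_ids = _sample_ids(spec, c)
        age = meta_rng.uniform(20.0, 70.0, size=n)
        logit = spec.sex_cluster_log_odds * lab
        p_female = 1.0 / (1.0 + np.exp(-logit))
        sex = np.where(meta_rng.random(n) < p_female, "F", "M")
        md = pd.DataFrame({
            "subject_id": [f"{cohort}_subj{i + 1:03d}" for i in range(n)],
            "cohort": cohort,
            "age": age,
            "sex": sex,
            "timepoint": "post",
        }, index=pd.Index(sample_ids, name="sample_id"))
        abundance[cohort] = generate_abundances(spec, lab, c)
        genes[cohort] = generate_gene_families(spec, lab, c)
        cytokines[cohort] = generate_cytokine_panel(spec, lab, c)
        metadata[cohort] = CovariateTable(md)
        labels[cohort] = pd.Series(lab, index=sample_ids, name="cluster")
    truth = Truth(cluster_labels=labels, signal_taxa=signal_taxa(spec),
                  signal_genes=signal_genes(spec),
                  th1_analytes=th1_analytes(spec))
    return SyntheticCohortSet(abundance=abundance, gene_families=genes,
                              cytokines=cytokines, metadata=metadata,
                              truth=truth)


def write_cohort_set(cohort_set: SyntheticCohortSet, outdir: str | Path,
                     config: AnalysisConfig | None = None) -> None:
    """Write one file quartet per cohort plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort, table in cohort_set.abundance.items():
        write_metaphlan_merged(table, outdir / f"{cohort}_abundance.tsv", config)
        write_gene_families(cohort_set.gene_families[cohort],
                            outdir / f"{cohort}_genefamilies.tsv", config)
        write_cytokines(cohort_set.cytokines[cohort],
                        outdir / f"{cohort}_cytokines.tsv", config)
        write_metadata(cohort_set.metadata[cohort],
                       outdir / f"{cohort}_metadata.tsv", config)
    truth = cohort_set.truth
    write_json({
        "cluster_labels": {c: s.to_dict() for c, s in truth.cluster_labels.items()},
        "signal_taxa": truth.signal_taxa,
        "signal_genes": truth.signal_genes,
        "th1_analytes": truth.th1_analytes,
    }, outdir / "truth.json")
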