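"""Synthetic case-control expression cohort generator.

Emulates a two-arm (ASD vs typically-developing, "TD") leukocyte microarray
cohort: probe-level intensities with detection p-values, a phenotype table
(diagnosis, train/test split, age, race/ethnicity, risk-gene mutation-carrier
flag, prenatal-event flags), and a ground-truth sidecar recording which genes
are differentially expressed and which ASD subjects belong to the attenuated
effect-size subgroup.

The generative model, on the log2 scale:

    x_gs = base_g + delta_g * d_s * sigma_g + eps_gs,   eps_gs ~ N(0, sigma_g^2)

where ``sigma_g^2`` is drawn from a scaled inverse-chi-squared distribution
(so empirical-Bayes variance shrinkage downstream is exercised under its own
model assumption), ``delta_g`` is a random +-1 direction for truth-DE genes
and 0 otherwise, and ``d_s`` is the standardized effect for sample ``s``:
``effect_size_full`` for full-effect ASD, ``effect_size_attenuated`` for the
attenuated ASD subgroup, 0 for TD. Each gene is expanded to ``probes_per_gene``
probes; emitted intensities are linear scale (2**x) as array software would
report them. A configurable fraction of extra "junk" probes has background
intensity and detection p > 0.1 in every sample, providing the negative-probe
pool the probe filter needs.

Mutation-carrier flags are drawn independently of expression; the attenuated
subgroup carries the elevated severe-prenatal-event rate, standing in for the
below-the-ensemble-mean stratum whose enrichment the downstream statistics
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PHENOTYPE_COLUMNS


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names it."""


#: Severe prenatal-event rates per generator group (attenuated ASD stands in
#: for the below-the-mean stratum; full-effect ASD for above-the-mean).
DEFAULT_PRENATAL_RATES: dict[str, float] = {
    "ASD_full": 19 / 79,
    "ASD_attenuated": 20 / 45,
    "TD": 24 / 107,
}

#: Control (neutral) prenatal-event rates per group.
DEFAULT_CONTROL_EVENT_RATES: dict[str, float] = {
    "ASD_full": 52 / 79,
    "ASD_attenuated": 24 / 45,
    "TD": 70 / 107,
}

#: Age distributions (months): per-group mean/sd of a lognormal.
DEFAULT_AGE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "ASD": (50.8, 28.8),
    "TD": (34.5, 8.4),
}

_ETHNICITIES = ["Not Hispanic Latino", "Hispanic and Latino", "Unknown"]
_ETHNICITY_P = {"ASD": [64 / 127, 29 / 127, 34 / 127], "TD": [82 / 113, 18 / 113, 13 / 113]}
_RACES = ["Caucasian", "Unknown", "Caucasian/Asian", "African American", "Asian",
          "Pacific Islander", "Other"]
_RACE_P = {
    "ASD": np.array([65, 40, 4, 5, 8, 3, 2]) / 127,
    "TD": np.array([73, 19, 5, 4, 9, 2, 1]) / 113,
}


@dataclass
class CohortConfig:
    n_train: int = 175
    n_test: int = 65
    n_asd: int = 127
    n_td: int = 113
    n_genes: int = 2000
    n_de_genes: int | None = None  # defaults to 10% of n_genes
    effect_size_full: float = 1.2
    effect_size_attenuated: float = 0.4
    frac_subgroup_attenuated: float = 45 / 124
    probes_per_gene: int = 2
    frac_junk_probes: float = 0.05
    carrier_rate_td: float = 12 / 105
    carrier_rate_asd: float = 13 / 112
    prenatal_event_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRENATAL_RATES))
    control_event_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_EVENT_RATES))
    age_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTIONS))
    # variance model: sigma_g^2 ~ s0^2 * d0 / chi2(d0)
    variance_prior_df: float = 4.0
    variance_prior_scale: float = 0.09
    base_mean: float = 8.0
    base_sd: float = 1.5
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.1
    background_mean: float = 4.0
    background_sd: float = 0.5
    block_correlation: float = 0.0  # optional within-block gene correlation
    block_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes is None:
            self.n_de_genes = max(1, round(0.1 * self.n_genes))

    def validate(self) -> "CohortConfig":
        for name in ("n_train", "n_test", "n_asd", "n_td", "n_genes", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_train + self.n_test != self.n_asd + self.n_td:
            raise ConfigError(
                "n_train + n_test must equal n_asd + n_td "
                f"({self.n_train}+{self.n_test} != {self.n_asd}+{self.n_td})")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds n_genes")
        if self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene must be >= 1")
        for name in ("carrier_rate_td", "carrier_rate_asd", "frac_subgroup_attenuated",
                     "frac_junk_probes"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for mapping_name in ("prenatal_event_rates", "control_event_rates"):
            for grp, v in getattr(self, mapping_name).items():
                if not 0 <= v <= 1:
                    raise ConfigError(f"{mapping_name}[{grp!r}] must lie in [0, 1], got {v}")
        for name in ("effect_size_full", "effect_size_attenuated"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if not 0 <= self.block_correlation < 1:
            raise ConfigError("block_correlation must lie in [0, 1)")
        return self


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    phenotype: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        expr_samples = set(self.expression.sample_ids)
        pheno_samples = set(self.phenotype["sample_id"])
        if expr_samples != pheno_samples:
            raise ValueError("expression and phenotype sample ids disagree")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a lognormal to the requested mean/sd
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort. Deterministic given ``config.seed``.

    All randomness flows from a single :class:`numpy.random.SeedSequence`
    split into independent streams per component, so e.g. changing the number
    of genes does not perturb the phenotype draw.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_pheno = np.random.default_rng(streams[0])
    rng_genes = np.random.default_rng(streams[1])
    rng_expr = np.random.default_rng(streams[2])
    rng_junk = np.random.default_rng(streams[3])

    phenotype, is_asd, attenuated = _draw_phenotype(config, rng_pheno)
    sample_ids = phenotype["sample_id"].to_numpy()
    n_samples = len(sample_ids)

    # gene-level parameters
    base = rng_genes.normal(config.base_mean, config.base_sd, config.n_genes)
    sigma2 = (config.variance_prior_scale * config.variance_prior_df
              / rng_genes.chisquare(config.variance_prior_df, config.n_genes))
    sigma = np.sqrt(sigma2)
    de_genes = rng_genes.choice(config.n_genes, size=config.n_de_genes, replace=False)
    direction = np.zeros(config.n_genes)
    direction[de_genes] = rng_genes.choice([-1.0, 1.0], size=config.n_de_genes)

    d_sample = np.zeros(n_samples)
    d_sample[is_asd & ~attenuated] = config.effect_size_full
    d_sample[is_asd & attenuated] = config.effect_size_attenuated

    noise = rng_expr.normal(size=(config.n_genes, n_samples))
    if config.block_correlation > 0 and config.block_size > 1:
        noise = _blockify(noise, config.block_correlation, config.block_size, rng_expr)
    log_gene = (base[:, None]
                + direction[:, None] * d_sample[None, :] * sigma[:, None]
                + sigma[:, None] * noise)

    # expand genes to probes
    ppg = config.probes_per_gene
    gene_names = np.array([f"GENE{g:05d}" for g in range(config.n_genes)])
    probe_gene = np.repeat(np.arange(config.n_genes), ppg)
    probe_ids = [f"PROBE{g:05d}_{j}" for g in range(config.n_genes) for j in range(ppg)]
    offsets = rng_expr.normal(0.0, config.probe_offset_sd, len(probe_ids))
    probe_log = (log_gene[probe_gene]
                 + offsets[:, None]
                 + rng_expr.normal(0.0, config.probe_noise_sd, (len(probe_ids), n_samples)))

    # detection p: mostly confident for expressed probes
    detected = rng_expr.random((len(probe_ids), n_samples)) < 0.95
    det_p = np.where(detected,
                     rng_expr.uniform(0.0, 0.04, (len(probe_ids), n_samples)),
                     rng_expr.uniform(0.04, 0.5, (len(probe_ids), n_samples)))

    # junk probes: background intensity, never detected
    n_junk = max(1, int(round(config.frac_junk_probes * len(probe_ids))))
    junk_ids = [f"JUNK{j:05d}" for j in range(n_junk)]
    junk_log = rng_junk.normal(config.background_mean, config.background_sd,
                               (n_junk, n_samples))
    junk_p = rng_junk.uniform(0.11, 1.0, (n_junk, n_samples))

    all_ids = pd.Index(probe_ids + junk_ids, name="probe_id")
    values = pd.DataFrame(
        np.power(2.0, np.vstack([probe_log, junk_log])),
        index=all_ids, columns=sample_ids)
    detection = pd.DataFrame(np.vstack([det_p, junk_p]), index=all_ids, columns=sample_ids)
    gene_map = pd.Series(
        list(gene_names[probe_gene]) + junk_ids, index=all_ids, name="gene_id")

    truth = {
        "de_genes": list(gene_names[np.sort(de_genes)]),
        "de_direction": {gene_names[g]: direction[g] for g in np.sort(de_genes)},
        "attenuated_samples": list(sample_ids[is_asd & attenuated]),
        "full_effect_samples": list(sample_ids[is_asd & ~attenuated]),
        "gene_sigma": dict(zip(gene_names, sigma)),
    }

    em = ExpressionMatrix(values=values, gene_ids=gene_map, detection_p=detection)
    return SyntheticCohort(expression=em, phenotype=phenotype, truth=truth)


def _draw_phenotype(config: CohortConfig, rng: np.random.Generator):
    n_total = config.n_asd + config.n_td
    sample_ids = np.array([f"S{i:04d}" for i in range(n_total)])
    is_asd = np.zeros(n_total, dtype=bool)
    is_asd[: config.n_asd] = True

    # split keeps the train/test ASD fraction close to the overall fraction
    n_asd_train = int(round(config.n_asd * config.n_train / max(n_total, 1)))
    n_td_train = config.n_train - n_asd_train
    split = np.where(
        is_asd,
        np.where(np.arange(n_total) < n_asd_train, "train", "test"),
        "train")
    td_idx = np.where(~is_asd)[0]
    split[td_idx[n_td_train:]] = "test"

    attenuated = np.zeros(n_total, dtype=bool)
    asd_idx = np.where(is_asd)[0]
    n_att = int(round(config.frac_subgroup_attenuated * config.n_asd))
    attenuated[rng.choice(asd_idx, size=n_att, replace=False)] = True

    group = np.where(~is_asd, "TD", np.where(attenuated, "ASD_attenuated", "ASD_full"))
    carrier_rate = np.where(is_asd, config.carrier_rate_asd, config.carrier_rate_td)
    carrier = rng.random(n_total) < carrier_rate
    severe_rate = np.array([config.prenatal_event_rates[g] for g in group])
    severe = rng.random(n_total) < severe_rate
    control_rate = np.array([config.control_event_rates[g] for g in group])
    control = rng.random(n_total) < control_rate

    ages = np.empty(n_total)
    for dx in ("ASD", "TD"):
        mu, s = _lognormal_params(*config.age_distributions[dx])
        mask = is_asd if dx == "ASD" else ~is_asd
        ages[mask] = rng.lognormal(mu, s, mask.sum())

    ethnicity = np.empty(n_total, dtype=object)
    race = np.empty(n_total, dtype=object)
    for dx in ("ASD", "TD"):
        mask = is_asd if dx == "ASD" else ~is_asd
        ethnicity[mask] = rng.choice(_ETHNICITIES, size=mask.sum(), p=_ETHNICITY_P[dx])
        race[mask] = rng.choice(_RACES, size=mask.sum(), p=_RACE_P[dx])

    phenotype = pd.DataFrame({
        "sample_id": sample_ids,
        "diagnosis": np.where(is_asd, "ASD", "TD"),
        "split": split,
        "age_months": np.round(ages, 1),
        "race": race,
        "ethnicity": ethnicity,
        "mutation_carrier": carrier,
        "severe_prenatal_event": severe,
        "control_prenatal_event": control,
    })[PHENOTYPE_COLUMNS]
    return phenotype, is_asd, attenuated


def _blockify(noise: np.ndarray, rho: float, block: int,
              rng: np.random.Generator) -> np.ndarray:
    """Impose equicorrelation ``rho`` within consecutive gene blocks."""
    out = noise.copy()
    n_genes, n_samples = noise.shape
    for start in range(0, n_genes, block):
        stop = min(start + block, n_genes)
        shared = rng.normal(size=n_samples)
        out[start:stop] = (np.sqrt(rho) * shared[None, :]
                           + np.sqrt(1 - rho) * noise[start:stop])
    return out
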