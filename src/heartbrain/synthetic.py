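"""Synthetic biobank generator with known ground truth.

Restricted cohort data (UK Biobank / All of Us style record-level tables)
cannot ship with the package, so this module simulates the shapes the
analysis consumes:

* a participant covariate table (continuous and categorical covariates with
  configurable missingness),
* long-format ICD-10 condition records implying binary CVD exposures and the
  Alzheimer's-disease outcome,
* paired GWAS summary-statistic tables with planted shared loci within a
  configurable offset of each other.

The outcome is drawn from the same logistic model the analysis fits
(correct specification by design), so parameter recovery and confidence-
interval coverage are valid acceptance surfaces.  Condition records carry no
dates: the downstream analysis is cross-sectional and temporality is not
modeled.  A single seed drives everything through spawned child streams, one
per sub-generator, so e.g. adding a covariate does not perturb the exposure
draws.  Missingness is applied after the outcome is assigned, so the outcome
never depends on masked values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from heartbrain.coloc import GwasSnp


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureSpec:
    """One binary CVD exposure: its ICD-10 code spec, marginal prevalence,
    and true log-odds effect on the outcome."""

    name: str
    icd10: str
    prevalence: float
    log_odds: float

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigError(f"exposure {self.name!r}: prevalence must be in (0,1)")
        if not math.isfinite(self.log_odds):
            raise ConfigError(f"exposure {self.name!r}: non-finite effect")


@dataclass(frozen=True)
class CovariateSpec:
    """One adjustment covariate.

    ``kind='continuous'``: normal(mu, sigma) via params ``{"mean","sd"}``;
    the effect is the log-odds increment per standardized unit.
    ``kind='categorical'``: params ``{"levels": [...], "probs": [...]}``;
    the effect attaches to membership in ``risk_level`` (default: the last
    declared level).
    """

    name: str
    kind: str  # {continuous, categorical}
    params: dict = field(default_factory=dict)
    log_odds: float = 0.0
    missing_rate: float = 0.0
    risk_level: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ConfigError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if not math.isfinite(self.log_odds):
            raise ConfigError(f"covariate {self.name!r}: non-finite effect")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"covariate {self.name!r}: missing rate must be in [0,1)")
        if self.kind == "categorical":
            levels = self.params.get("levels", [])
            probs = self.params.get("probs", [])
            if len(levels) < 2 or len(levels) != len(probs):
                raise ConfigError(f"covariate {self.name!r}: levels/probs mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"covariate {self.name!r}: probs must sum to 1")


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_participants: int
    outcome_prevalence_baseline: float
    exposure_specs: list[ExposureSpec] = field(default_factory=list)
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    outcome_code: str = "G30"
    exposure_correlation: float = 0.0  # Gaussian-copula rho among exposure latents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if not 0 < self.outcome_prevalence_baseline < 1:
            raise ConfigError("outcome_prevalence_baseline must be in (0,1)")
        if not -0.999 <= self.exposure_correlation <= 0.999:
            raise ConfigError("exposure_correlation must be in (-0.999, 0.999)")
        names = [e.name for e in self.exposure_specs] + [c.name for c in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ConfigError("exposure/covariate names must be unique")


@dataclass
class TruthTable:
    """Ground truth behind one simulated cohort: the generating coefficients
    and each participant's latent outcome probability."""

    intercept: float
    exposure_log_odds: dict[str, float]
    covariate_log_odds: dict[str, float]
    latent_probability: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "exposure_log_odds": self.exposure_log_odds,
            "covariate_log_odds": self.covariate_log_odds,
            "latent_probability_mean": float(np.mean(self.latent_probability)),
            "n_participants": int(len(self.latent_probability)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate (participant table, condition records, truth table).

    The participant table has exactly ``n_participants`` rows with a
    ``participant_id`` column, one column per covariate (with missingness
    applied) and one boolean column per exposure (the generator's assignment,
    which downstream ascertainment must reproduce from the condition
    records).  Condition records carry one row per (participant, assigned
    ICD-10 code): each exposure emits its code for assigned participants,
    and outcome-positive participants get the outcome code (default G30).
    Identical seeds give byte-identical output.
    """
    n = config.n_participants
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order: exposures, covariates, outcome, record sub-codes
    ss_expo, ss_cov, ss_out, ss_codes = root.spawn(4)
    expo_streams = ss_expo.spawn(max(len(config.exposure_specs), 1))
    cov_streams = ss_cov.spawn(max(len(config.covariate_specs), 1))

    linpred = np.full(n, _logit(config.outcome_prevalence_baseline))

    # exposures: correlated via a shared Gaussian factor when rho != 0
    expo_cols: dict[str, np.ndarray] = {}
    rho = config.exposure_correlation
    shared = np.random.default_rng(ss_expo).standard_normal(n) if rho else None
    from scipy.stats import norm as _norm

    for spec, stream in zip(config.exposure_specs, expo_streams):
        rng = np.random.default_rng(stream)
        if rho:
            z = math.sqrt(abs(rho)) * np.sign(rho) * shared + math.sqrt(1 - abs(rho)) * rng.standard_normal(n)
            assigned = _norm.cdf(z) < spec.prevalence
        else:
            assigned = rng.random(n) < spec.prevalence
        expo_cols[spec.name] = assigned
        linpred = linpred + spec.log_odds * assigned

    # covariates (values kept pre-missingness for the outcome draw)
    cov_cols: dict[str, np.ndarray] = {}
    cov_missing_masks: dict[str, np.ndarray] = {}
    for spec, stream in zip(config.covariate_specs, cov_streams):
        rng = np.random.default_rng(stream)
        if spec.kind == "continuous":
            mu = spec.params.get("mean", 0.0)
            sd = spec.params.get("sd", 1.0)
            vals = rng.normal(mu, sd, size=n)
            linpred = linpred + spec.log_odds * (vals - mu) / sd
        else:
            levels = list(spec.params["levels"])
            probs = np.asarray(spec.params["probs"], dtype=float)
            idx = rng.choice(len(levels), size=n, p=probs)
            vals = np.asarray(levels, dtype=object)[idx]
            risk = spec.risk_level if spec.risk_level is not None else levels[-1]
            linpred = linpred + spec.log_odds * (vals == risk)
        cov_cols[spec.name] = vals
        cov_missing_masks[spec.name] = rng.random(n) < spec.missing_rate if spec.missing_rate else np.zeros(n, bool)

    prob = _expit(linpred)
    outcome = np.random.default_rng(ss_out).random(n) < prob

    ids = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    table = pd.DataFrame({"participant_id": ids})
    for name, vals in cov_cols.items():
        col = pd.Series(vals, dtype=object if vals.dtype == object else float)
        col[cov_missing_masks[name]] = np.nan  # applied after the outcome draw
        table[name] = col
    for name, assigned in expo_cols.items():
        table[name] = assigned
    table["AD"] = outcome

    # condition records: exposures emit their code spec's concrete code;
    # a random half get a sub-code suffix to exercise prefix matching
    rng_codes = np.random.default_rng(ss_codes)
    rec_ids: list[np.ndarray] = []
    rec_codes: list[np.ndarray] = []
    for spec in config.exposure_specs:
        assigned_ids = ids[expo_cols[spec.name]]
        base = _concrete_code(spec.icd10)
        suffixes = rng_codes.integers(0, 10, size=len(assigned_ids))
        with_sub = rng_codes.random(len(assigned_ids)) < 0.5
        codes = np.where(with_sub, np.char.add(base + ".", suffixes.astype(str)), base)
        rec_ids.append(assigned_ids)
        rec_codes.append(codes)
    rec_ids.append(ids[outcome])
    rec_codes.append(np.full(int(outcome.sum()), config.outcome_code, dtype=object))
    records = pd.DataFrame(
        {
            "participant_id": np.concatenate(rec_ids) if rec_ids else np.array([], dtype=object),
            "icd10_code": np.concatenate(rec_codes) if rec_codes else np.array([], dtype=object),
        }
    )
    records = records.sort_values(["participant_id", "icd10_code"], kind="mergesort").reset_index(drop=True)

    truth = TruthTable(
        intercept=_logit(config.outcome_prevalence_baseline),
        exposure_log_odds={e.name: e.log_odds for e in config.exposure_specs},
        covariate_log_odds={c.name: c.log_odds for c in config.covariate_specs},
        latent_probability=prob,
    )
    return table, records, truth


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _concrete_code(icd10_spec: str) -> str:
    """First atom of a code spec (range -> its low endpoint)."""
    first = icd10_spec.split(",")[0].strip().upper().replace("–", "-")
    return first.split("-")[0].strip()


@dataclass
class GwasSimConfig:
    """Study conditions for one paired GWAS simulation.

    Planted shared loci put one SNP on each side on the same chromosome at a
    distance drawn uniformly in [0, planted_offset_max]; background SNPs are
    placed uniformly (optionally kept at least ``background_clearance_bp``
    from every planted locus).  Significant p-values are drawn log-uniform in
    [1e-30, alpha); a configurable number of non-significant background SNPs
    per side is emitted separately to exercise the significance filter.
    """

    n_snps_per_side: int
    n_chromosomes: int = 22
    chromosome_length: int = 100_000_000
    n_planted_shared_loci: int = 0
    planted_offset_max: int = 50_000
    alpha: float = 5e-8
    n_nonsignificant_per_side: int = 0
    background_clearance_bp: int = 0
    chromosomes_a: list[str] | None = None  # restrict side A placement
    chromosomes_b: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_per_side <= 0:
            raise ConfigError("n_snps_per_side must be positive")
        if not 1 <= self.n_chromosomes <= 22:
            raise ConfigError("n_chromosomes must be in 1..22")
        if self.planted_offset_max < 0:
            raise ConfigError("planted_offset_max must be >= 0")
        if self.n_planted_shared_loci > self.n_snps_per_side:
            raise ConfigError("n_planted_shared_loci cannot exceed n_snps_per_side")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0,1)")
        # need room for planted loci, offsets and clearance without forced
        # collisions: the space blocked by planted loci (clearance on both
        # sides plus the offset span) must leave at least half of the total
        # base-pair space free for background placement
        n_chrom_eff = min(
            len(self.chromosomes_a) if self.chromosomes_a else self.n_chromosomes,
            len(self.chromosomes_b) if self.chromosomes_b else self.n_chromosomes,
        )
        total_space = self.chromosome_length * n_chrom_eff
        blocked = self.n_planted_shared_loci * (2 * self.background_clearance_bp + self.planted_offset_max + 2)
        if self.chromosome_length < 2 * (self.planted_offset_max + 2) or blocked > total_space // 2:
            raise ConfigError(
                f"chromosome_length {self.chromosome_length} too small to host "
                f"{self.n_snps_per_side} SNPs with the requested offsets/clearance"
            )


def simulate_gwas_pair(
    config: GwasSimConfig,
) -> tuple[list[GwasSnp], list[GwasSnp], list[dict], tuple[list[GwasSnp], list[GwasSnp]]]:
    """Simulate paired significant SNP lists with planted shared loci.

    Returns ``(side_a, side_b, truth_pairs, prefilter_extra)``:
    ``side_a``/``side_b`` hold the genome-wide-significant SNPs (every
    emitted p-value < alpha); ``truth_pairs`` enumerates the planted pairs
    (rsids, chromosome, positions, offset); ``prefilter_extra`` holds the
    additional non-significant SNPs per side (p in [alpha, 1)) for
    exercising the significance filter upstream of the join.
    Identical seeds give identical tables.
    """
    root = np.random.SeedSequence(config.seed)
    ss_place, ss_pa, ss_pb, ss_nonsig = root.spawn(4)
    rng = np.random.default_rng(ss_place)

    chroms_a = config.chromosomes_a or [str(i) for i in range(1, config.n_chromosomes + 1)]
    chroms_b = config.chromosomes_b or [str(i) for i in range(1, config.n_chromosomes + 1)]
    shared_chroms = [c for c in chroms_a if c in chroms_b]
    if config.n_planted_shared_loci > 0 and not shared_chroms:
        raise ConfigError("planted loci require at least one chromosome shared between sides")

    margin = config.planted_offset_max + 1
    planted_positions: dict[str, list[int]] = {}
    proto_a: list[tuple[str, str, int, str]] = []  # (rsid, chrom, pos, trait)
    proto_b: list[tuple[str, str, int, str]] = []
    truth: list[dict] = []

    for i in range(config.n_planted_shared_loci):
        chrom = shared_chroms[int(rng.integers(len(shared_chroms)))]
        pos_a = int(rng.integers(margin, config.chromosome_length - margin))
        offset = int(rng.integers(0, config.planted_offset_max + 1))
        pos_b = pos_a + int(rng.choice((-1, 1))) * offset
        planted_positions.setdefault(chrom, []).extend([pos_a, pos_b])
        proto_a.append((f"rsA{i:05d}", chrom, pos_a, f"trait_A_{i}"))
        proto_b.append((f"rsB{i:05d}", chrom, pos_b, f"trait_B_{i}"))
        truth.append(
            {"catalog_rsid": f"rsA{i:05d}", "biobank_rsid": f"rsB{i:05d}",
             "chromosome": chrom, "catalog_pos": pos_a, "biobank_pos": pos_b,
             "offset": abs(pos_b - pos_a)}
        )

    n_background = config.n_snps_per_side - config.n_planted_shared_loci
    for proto, chroms, prefix in ((proto_a, chroms_a, "bgA"), (proto_b, chroms_b, "bgB")):
        placed = 0
        while placed < n_background:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, config.chromosome_length))
            if config.background_clearance_bp and any(
                abs(pos - p) < config.background_clearance_bp
                for p in planted_positions.get(chrom, [])
            ):
                continue
            proto.append((f"{prefix}{placed:05d}", chrom, pos, f"trait_{prefix}_{placed}"))
            placed += 1

    # significant p-values: log-uniform in [1e-30, alpha)
    side_a: list[GwasSnp] = []
    side_b: list[GwasSnp] = []
    for proto, out, ss, label in ((proto_a, side_a, ss_pa, "catalog"), (proto_b, side_b, ss_pb, "biobank")):
        prng = np.random.default_rng(ss)
        logs = prng.uniform(math.log10(1e-30), math.log10(config.alpha), size=len(proto))
        for (rsid, chrom, pos, trait), lg in zip(proto, logs):
            p = min(10.0**lg, config.alpha * (1 - 1e-12))
            out.append(GwasSnp(rsid, chrom, pos, float(p), trait, label))

    # non-significant background for the pre-filter file
    nonsig_a: list[GwasSnp] = []
    nonsig_b: list[GwasSnp] = []
    nrng = np.random.default_rng(ss_nonsig)
    for out, chroms, prefix, label in (
        (nonsig_a, chroms_a, "nsA", "catalog"),
        (nonsig_b, chroms_b, "nsB", "biobank"),
    ):
        for i in range(config.n_nonsignificant_per_side):
            chrom = chroms[int(nrng.integers(len(chroms)))]
            pos = int(nrng.integers(1, config.chromosome_length))
            p = float(nrng.uniform(config.alpha, 1.0))
            out.append(GwasSnp(f"{prefix}{i:05d}", chrom, pos, p, f"trait_{prefix}_{i}", label))
    return side_a, side_b, truth, (nonsig_a, nonsig_b)


def snps_to_frame(snps: list[GwasSnp]) -> pd.DataFrame:
    """Native-dialect tabular view (rsid, chrom, pos, pvalue, trait)."""
    return pd.DataFrame(
        [
            {"rsid": s.rsid, "chrom": s.chromosome, "pos": s.position,
             "pvalue": s.p_value, "trait": s.trait}
            for s in snps
        ],
        columns=["rsid", "chrom", "pos", "pvalue", "trait"],
    )
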