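"""Synthetic populations, cohorts and CF registries with known ground truth.

The generator mirrors the statistical structure the indirect-estimation chain
assumes: a randomly mating diploid population in Hardy-Weinberg equilibrium
with disease-allele frequency ``q_true``, whose disease alleles are
partitioned among named variants with proportions ``fa_true``; a registry
that records every affected child born over a fixed horizon (complete
ascertainment); and a genotyped patient sample whose allele spectrum is a
multinomial draw from ``fa_true``.

Defaults are the national registry-scale conditions: q = 0.0105, the
F508del / CFTRdele2,3(21kb) / other spectrum 0.5155 / 0.0611 / 0.4234,
140,000 births per year over an 18-year horizon, 300 patients genotyped,
and a 100,000-individual population draw.

Randomness is reproducible: each experiment takes one master seed, and
replicates derive independent streams from it by counter
(``numpy.random.SeedSequence(seed, spawn_key=(replicate,))``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import CohortAF, CohortEntry, PatientSpectrum, RegionRegistryRecord
from .estimate import allele_freq_from_prevalence, cf_prevalence, indirect_af, spectrum_proportions
from .exceptions import ValidationError

_DEFAULT_FA = {
    "F508del": 0.5155,
    "CFTRdele2,3(21kb)": 0.0611,
    "other": 0.4234,
}


@dataclass
class SimulationParams:
    """Ground-truth parameters for one synthetic region."""

    q_true: float = 0.0105
    fa_true: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FA))
    n_population: int = 100_000
    births_per_year: int = 140_000
    horizon_years: int = 18
    n_patients_genotyped: int = 300
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.q_true <= 1.0:
            raise ValidationError(f"q_true {self.q_true} outside [0, 1]")
        if not self.fa_true:
            raise ValidationError("fa_true must be non-empty")
        if any(f < 0 for f in self.fa_true.values()):
            raise ValidationError("fa_true proportions must be >= 0")
        if not math.isclose(sum(self.fa_true.values()), 1.0, abs_tol=1e-12):
            raise ValidationError("fa_true proportions must sum to 1")
        for size in (
            self.n_population,
            self.births_per_year,
            self.horizon_years,
            self.n_patients_genotyped,
        ):
            if size < 1:
                raise ValidationError("all sizes must be >= 1")


def _rng(params: SimulationParams, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(stream,))
    )


def simulate_population(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> CohortAF:
    """Draw a healthy-population cohort and return its observed per-variant AFs.

    Each of the ``2 * n_population`` chromosomes independently carries a
    disease allele with probability ``q_true`` and is then assigned a variant
    according to ``fa_true``; equivalently, one multinomial draw over
    (variant_1, ..., variant_k, non-disease).
    """
    params.validate()
    rng = _rng(params) if rng is None else rng
    variants = list(params.fa_true.keys())
    probs = np.array([params.q_true * f for f in params.fa_true.values()])
    probs = np.append(probs, 1.0 - probs.sum())
    an = 2 * params.n_population
    counts = rng.multinomial(an, probs)
    cohort = CohortAF(cohort_id=f"synthetic-seed{params.seed}", n_individuals=params.n_population)
    for variant, count in zip(variants, counts[:-1]):
        cohort.entries[variant] = CohortEntry(af=count / an, allele_count=int(count))
    cohort.validate()
    return cohort


def simulate_registry(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[RegionRegistryRecord, PatientSpectrum]:
    """Draw a regional registry and a genotyped patient allele spectrum.

    Affected births are binomial(births_per_year * horizon_years, q_true**2)
    per Hardy-Weinberg; the patient spectrum is multinomial over
    ``2 * n_patients_genotyped`` alleles with probabilities ``fa_true`` and
    sums exactly to that total.
    """
    params.validate()
    rng = _rng(params, stream=1) if rng is None else rng
    total_births = params.births_per_year * params.horizon_years
    n_cases = int(rng.binomial(total_births, params.q_true**2))
    record = RegionRegistryRecord(
        region_id=f"synthetic-seed{params.seed}",
        n_cases=n_cases,
        mean_annual_births=float(params.births_per_year),
        horizon_years=params.horizon_years,
    )
    record.validate()
    variants = list(params.fa_true.keys())
    counts = rng.multinomial(
        2 * params.n_patients_genotyped, np.array(list(params.fa_true.values()))
    )
    spectrum = PatientSpectrum(
        region_id=record.region_id,
        n_patients=params.n_patients_genotyped,
        counts={v: int(c) for v, c in zip(variants, counts)},
    )
    spectrum.validate(strict=True)
    return record, spectrum


@dataclass
class RecoverySummary:
    """Monte-Carlo recovery of the indirect AF chain against ground truth."""

    params: SimulationParams
    n_replicates: int
    true_af: dict[str, float]
    mean_estimate: dict[str, float]
    mean_bias: dict[str, float]
    rmse: dict[str, float] | None  # None for a single replicate


def recovery_experiment(params: SimulationParams, n_replicates: int) -> RecoverySummary:
    """Repeatedly simulate a registry and run the full indirect chain.

    Each replicate draws registry + patient spectrum, computes prevalence,
    the Hardy-Weinberg ``q``, and the per-variant indirect AF, and the
    summary reports the mean estimate, mean bias and RMSE against the
    ground truth ``q_true * fa_true``.
    """
    params.validate()
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    variants = list(params.fa_true.keys())
    estimates = np.empty((n_replicates, len(variants)))
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(rep,))
        )
        record, spectrum = simulate_registry(params, rng=rng)
        q = allele_freq_from_prevalence(cf_prevalence(record))
        fa_hat = spectrum_proportions(spectrum)
        estimates[rep] = [indirect_af(q, fa_hat[v]) for v in variants]
    true_af = {v: params.q_true * params.fa_true[v] for v in variants}
    truth = np.array([true_af[v] for v in variants])
    mean_est = estimates.mean(axis=0)
    summary = RecoverySummary(
        params=params,
        n_replicates=n_replicates,
        true_af=true_af,
        mean_estimate=dict(zip(variants, mean_est)),
        mean_bias=dict(zip(variants, mean_est - truth)),
        rmse=(
            dict(zip(variants, np.sqrt(((estimates - truth) ** 2).mean(axis=0))))
            if n_replicates > 1
            else None
        ),
    )
    return summary


def thin_registry(
    record: RegionRegistryRecord,
    ascertainment: float,
    rng: np.random.Generator,
) -> RegionRegistryRecord:
    """Emulate registry incompleteness by binomial thinning of the case count."""
    if not 0.0 <= ascertainment <= 1.0:
        raise ValidationError("ascertainment probability must be in [0, 1]")
    return replace(record, n_cases=int(rng.binomial(record.n_cases, ascertainment)))
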