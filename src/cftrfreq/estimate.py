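"""Registry-based estimation of CFTR variant allele frequencies.

The indirect chain for an autosomal recessive disease:

1. Birth prevalence from the patient registry, ``Fd = n / (N * horizon)``,
   where ``n`` is the number of registered affected children under the age
   horizon and ``N`` the mean annual births over that horizon.
2. Disease-allele frequency under Hardy-Weinberg equilibrium, ``q = sqrt(Fd)``
   (a recessive disease's birth prevalence is ``q**2`` under random mating).
3. Per-variant population AF, ``af = q * fa``, where ``fa`` is the variant's
   share of disease alleles observed among genotyped patients.

Direct estimates (``af = allele_count / allele_number``) and exact binomial
confidence intervals complete the comparison side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .catalog import IndirectAFEstimate, PatientSpectrum, RegionRegistryRecord
from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: Supported confidence-interval methods.
CI_METHODS = ("clopper-pearson", "wilson")


@dataclass(frozen=True)
class BinomialCI:
    """Two-sided confidence interval for a binomial proportion."""

    allele_count: int
    allele_number: int
    level: float
    low: float
    high: float

    @property
    def point(self) -> float:
        return self.allele_count / self.allele_number

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.point <= self.high <= 1.0:
            raise ValidationError(
                f"CI ({self.low}, {self.high}) does not bracket {self.point}"
            )


def cf_prevalence(record: RegionRegistryRecord) -> float:
    """Disease birth prevalence ``Fd = n_cases / (mean_annual_births * horizon)``."""
    record.validate()
    births = record.mean_annual_births * record.horizon_years
    fd = record.n_cases / births
    if not 0.0 <= fd <= 1.0:
        raise ValidationError(f"{record.region_id}: prevalence {fd} outside [0, 1]")
    return fd


def allele_freq_from_prevalence(fd: float) -> float:
    """Disease-allele frequency ``q = sqrt(Fd)`` under Hardy-Weinberg equilibrium."""
    if not 0.0 <= fd <= 1.0:
        raise ValidationError(f"prevalence {fd} outside [0, 1]")
    return math.sqrt(fd)


def indirect_af(q: float, fa: float) -> float:
    """Indirect population AF of one variant: ``q * fa``."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"q {q} outside [0, 1]")
    if not 0.0 <= fa <= 1.0:
        raise ValidationError(f"fa {fa} outside [0, 1]")
    return q * fa


def af_from_counts(allele_count: int, allele_number: int) -> float:
    """Direct AF from counts: ``allele_count / allele_number``."""
    if allele_number <= 0:
        raise ValidationError("allele_number must be positive")
    if not 0 <= allele_count <= allele_number:
        raise ValidationError(
            f"allele_count {allele_count} outside [0, {allele_number}]"
        )
    return allele_count / allele_number


def reconstruct_count(af: float, allele_number: int) -> int:
    """Nearest-integer allele count implied by a rounded AF.

    Published AF columns are 3-4 decimal roundings; the reconstruction is
    logged so downstream statistics remain traceable to it.
    """
    count = round(af * allele_number)
    log.info("reconstructed AC=%d from af=%s, AN=%d", count, af, allele_number)
    return count


def binomial_ci(
    allele_count: int,
    allele_number: int,
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> BinomialCI:
    """Two-sided binomial confidence interval for an allele frequency.

    The default is the exact Clopper-Pearson interval (inversion of the
    binomial tail probabilities); ``method="wilson"`` selects the Wilson
    score interval.
    """
    if allele_number <= 0:
        raise ValidationError("allele_number must be positive")
    if not 0 <= allele_count <= allele_number:
        raise ValidationError(
            f"allele_count {allele_count} outside [0, {allele_number}]"
        )
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    if method not in CI_METHODS:
        raise ValidationError(f"unknown CI method {method!r}; choose from {CI_METHODS}")
    sm_method = "beta" if method == "clopper-pearson" else "wilson"
    low, high = proportion_confint(
        allele_count, allele_number, alpha=1.0 - level, method=sm_method
    )
    low = min(max(float(low), 0.0), 1.0)
    high = min(max(float(high), 0.0), 1.0)
    return BinomialCI(
        allele_count=allele_count,
        allele_number=allele_number,
        level=level,
        low=low,
        high=high,
    )


def spectrum_proportions(spectrum: PatientSpectrum) -> dict[str, float]:
    """Share ``fa`` of each variant category among all patient alleles."""
    total = spectrum.total_alleles
    if total <= 0:
        raise ValidationError(f"{spectrum.region_id}: empty spectrum")
    return {cat: count / total for cat, count in spectrum.counts.items()}


def indirect_estimates(
    record: RegionRegistryRecord, spectrum: PatientSpectrum
) -> list[IndirectAFEstimate]:
    """Full indirect chain for one region: prevalence -> q -> per-variant AF."""
    fd = cf_prevalence(record)
    q = allele_freq_from_prevalence(fd)
    out = []
    for variant, fa in spectrum_proportions(spectrum).items():
        est = IndirectAFEstimate(
            region_id=record.region_id,
            variant=variant,
            Fd=fd,
            q=q,
            fa=fa,
            af=indirect_af(q, fa),
        )
        est.validate()
        out.append(est)
    return out
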