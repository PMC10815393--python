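"""Contingency-table comparisons of CFTR allele spectra and cohort AFs.

Spectra are collapsed to the most abundant variant categories plus a pooled
``other`` remainder before testing (small per-variant counts make the full
spectrum untestable region by region), then compared with Pearson's
chi-squared test.  The Yates continuity correction follows the mainstream
convention: applied to 2x2 tables only, overridable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .catalog import OTHER_CATEGORY, CohortAF, PatientSpectrum
from .estimate import reconstruct_count
from .exceptions import DegenerateTableError, MissingDataError, ValidationError

log = logging.getLogger(__name__)

#: Expected-count threshold below which the chi-squared approximation is shaky.
MIN_EXPECTED_WARN = 5.0

YATES_POLICIES = ("auto", "on", "off")


@dataclass
class ContingencyTable:
    """Allele counts: rows are groups (regions/cohorts), columns categories."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        r, c = self.counts.shape
        if r != len(self.row_labels) or c != len(self.col_labels):
            raise ValidationError("label/count shape mismatch")
        if r < 2 or c < 2:
            raise ValidationError("contingency table needs >= 2 rows and >= 2 columns")
        if (self.counts < 0).any():
            raise ValidationError("negative count in contingency table")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValidationError("contingency table has an empty row")


@dataclass
class ContingencyResult:
    """Chi-squared test outcome with its expected counts."""

    statistic: float
    df: int
    p_value: float
    yates_applied: bool
    expected: np.ndarray = field(repr=False)
    min_expected: float = 0.0


def collapse_spectrum(spectrum: PatientSpectrum, keep: Sequence[str]) -> PatientSpectrum:
    """Pool every category not in ``keep`` into the reserved ``other`` group.

    Total allele count is conserved; categories named in ``keep`` but absent
    from the spectrum appear with count 0.
    """
    if not keep:
        raise ValidationError("keep must be non-empty")
    if OTHER_CATEGORY in keep:
        raise ValidationError(f"'{OTHER_CATEGORY}' is reserved and cannot be kept")
    kept = {cat: spectrum.counts.get(cat, 0) for cat in keep}
    kept[OTHER_CATEGORY] = spectrum.total_alleles - sum(kept.values())
    if kept[OTHER_CATEGORY] < 0:
        raise ValidationError(f"{spectrum.region_id}: keep categories overlap counts")
    return PatientSpectrum(
        region_id=spectrum.region_id,
        n_patients=spectrum.n_patients,
        counts=kept,
    )


def build_table(
    spectra: Sequence[PatientSpectrum], keep: Sequence[str]
) -> ContingencyTable:
    """Region-by-category allele-count table after collapsing to ``keep`` + other."""
    if len(spectra) < 2:
        raise ValidationError("need at least 2 spectra to build a table")
    seen: set[str] = set()
    rows = []
    for s in spectra:
        if s.region_id in seen:
            raise ValidationError(f"duplicate region_id {s.region_id!r}")
        seen.add(s.region_id)
        collapsed = collapse_spectrum(s, keep)
        rows.append([collapsed.counts[c] for c in [*keep, OTHER_CATEGORY]])
    return ContingencyTable(
        row_labels=[s.region_id for s in spectra],
        col_labels=[*keep, OTHER_CATEGORY],
        counts=np.array(rows, dtype=np.int64),
    )


def chi_square_test(table: ContingencyTable, yates: str = "auto") -> ContingencyResult:
    """Pearson chi-squared test of homogeneity on an allele-count table.

    ``yates="auto"`` applies the continuity correction iff the table is 2x2;
    ``"on"`` forces it (2x2 only — the correction is undefined otherwise);
    ``"off"`` disables it.  A warning is logged when the smallest expected
    count falls below 5.
    """
    if yates not in YATES_POLICIES:
        raise ValidationError(f"yates must be one of {YATES_POLICIES}")
    if (table.counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero column margin: statistic undefined")
    is_2x2 = table.counts.shape == (2, 2)
    if yates == "on" and not is_2x2:
        raise ValidationError("Yates correction is defined for 2x2 tables only")
    correction = is_2x2 if yates == "auto" else (yates == "on")
    statistic, p_value, df, expected = stats.chi2_contingency(
        table.counts, correction=correction
    )
    min_expected = float(expected.min())
    if min_expected < MIN_EXPECTED_WARN:
        log.warning(
            "chi-squared approximation questionable: min expected count %.2f < %g",
            min_expected, MIN_EXPECTED_WARN,
        )
    return ContingencyResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        yates_applied=bool(correction),
        expected=expected,
        min_expected=min_expected,
    )


def total_burden(cohort: CohortAF, variants: Sequence[str]) -> tuple[float, int]:
    """Summed AF of the listed variants in one cohort.

    Returns ``(total, n_missing)``: MISSING entries are excluded from the sum
    and counted, never treated as zero.
    """
    total = 0.0
    n_missing = 0
    for name in variants:
        entry = cohort.entries.get(name)
        if entry is None or entry.af is None:
            n_missing += 1
        else:
            total += entry.af
    return total, n_missing


def _carrier_count(cohort: CohortAF, variant: str) -> int:
    entry = cohort.entries.get(variant)
    if entry is None or entry.af is None:
        raise MissingDataError(
            f"variant {variant!r} is MISSING in cohort {cohort.cohort_id!r}"
        )
    if entry.allele_count is not None:
        return entry.allele_count
    return reconstruct_count(entry.af, cohort.allele_number)


def compare_cohort_afs(
    a: CohortAF, b: CohortAF, variant: str, yates: str = "auto"
) -> ContingencyResult:
    """2x2 chi-squared test of one variant's AF between two cohorts.

    Allele counts are taken from the cohorts when present, otherwise
    reconstructed as ``round(af * allele_number)`` (logged).
    """
    ka, kb = _carrier_count(a, variant), _carrier_count(b, variant)
    table = ContingencyTable(
        row_labels=[a.cohort_id, b.cohort_id],
        col_labels=[variant, "rest"],
        counts=np.array(
            [[ka, a.allele_number - ka], [kb, b.allele_number - kb]], dtype=np.int64
        ),
    )
    return chi_square_test(table, yates=yates)


def compare_total_burden(
    cohorts: Sequence[CohortAF], variants: Sequence[str], yates: str = "auto"
) -> ContingencyResult:
    """k x 2 chi-squared test of the summed variant burden across cohorts.

    Carrier-allele counts are reconstructed from the summed AFs; MISSING
    entries are excluded from each cohort's sum (and logged via total_burden
    semantics), so cohorts with different missingness are compared on their
    observed burden only.
    """
    if len(cohorts) < 2:
        raise ValidationError("need at least 2 cohorts")
    rows = []
    for c in cohorts:
        burden, n_missing = total_burden(c, variants)
        if n_missing:
            log.info(
                "cohort %s: %d of %d variants MISSING, excluded from burden",
                c.cohort_id, n_missing, len(variants),
            )
        k = reconstruct_count(burden, c.allele_number)
        rows.append([k, c.allele_number - k])
    table = ContingencyTable(
        row_labels=[c.cohort_id for c in cohorts],
        col_labels=["burden", "rest"],
        counts=np.array(rows, dtype=np.int64),
    )
    return chi_square_test(table, yates=yates)
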