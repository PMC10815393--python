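"""Domain types and TSV readers/writers for variant catalogs, cohort
allele-frequency tables, CF-patient allele spectra, and registry records.

Conventions
-----------
* All tables are tab-separated text; lines starting with ``#`` are comments.
* Cohorts are diploid: the allele number is always ``2 * n_individuals``.
* A missing allele frequency is represented as :data:`None` in memory and as
  ``n.a.`` on disk (``NA`` and an empty cell are also accepted on input).
  Missing values are never silently treated as zero.
* ``other`` is a reserved allele-category label for the pooled remainder of a
  patient spectrum; a named variant may not use it.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import ParseError, ValidationError

log = logging.getLogger(__name__)

#: Reserved category label for the pooled remainder of a spectrum.
OTHER_CATEGORY = "other"

#: Input tokens (lower-cased) that denote a missing allele frequency.
MISSING_TOKENS = frozenset({"n.a.", "na", ""})

#: Token written for a missing AF and for an absent rsID.
MISSING_OUT = "n.a."
ABSENT_RSID = "-"

_RSID_RE = re.compile(r"^rs[0-9]+$")
_COHORT_HEADER_RE = re.compile(r"^(?P<id>.+?)\s*\(\s*n\s*=\s*(?P<n>[0-9]+)\s*\)$")

# AF/count agreement tolerances: cohort entries are 4-decimal roundings,
# spectrum AF columns are 3-4 decimal roundings of count/total.
COHORT_AF_TOL = 5e-5
SPECTRUM_AF_TOL = 5e-4


@dataclass(frozen=True)
class VariantDef:
    """A CFTR variant: legacy label plus HGVS and dbSNP identifiers."""

    legacy_name: str
    hgvs_c: str
    hgvs_p: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if not self.legacy_name:
            raise ValidationError("legacy_name must be non-empty")
        if self.legacy_name == OTHER_CATEGORY:
            raise ValidationError(f"'{OTHER_CATEGORY}' is a reserved category label")
        if not self.hgvs_c:
            raise ValidationError(f"{self.legacy_name}: hgvs_c must be non-empty")
        if self.rsid is not None and not _RSID_RE.match(self.rsid):
            raise ValidationError(f"{self.legacy_name}: malformed rsID {self.rsid!r}")


@dataclass
class CohortEntry:
    """One variant's measurement in one cohort.

    ``af`` is :data:`None` when the cohort did not report the variant
    (MISSING); ``allele_count`` is kept when known, otherwise it can be
    reconstructed downstream as ``round(af * allele_number)``.
    """

    af: float | None
    allele_count: int | None = None


@dataclass
class CohortAF:
    """Per-variant allele frequencies for one diploid cohort."""

    cohort_id: str
    n_individuals: int
    entries: dict[str, CohortEntry] = field(default_factory=dict)

    @property
    def allele_number(self) -> int:
        """Chromosomes assayed: 2 per diploid individual."""
        return 2 * self.n_individuals

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError(f"{self.cohort_id}: n_individuals must be positive")
        for name, e in self.entries.items():
            if e.af is not None and not 0.0 <= e.af <= 1.0:
                raise ValidationError(f"{self.cohort_id}/{name}: af {e.af} outside [0, 1]")
            if e.allele_count is not None:
                if e.allele_count < 0 or e.allele_count > self.allele_number:
                    raise ValidationError(
                        f"{self.cohort_id}/{name}: allele_count {e.allele_count} "
                        f"outside [0, {self.allele_number}]"
                    )
                if e.af is not None:
                    implied = e.allele_count / self.allele_number
                    if abs(e.af - implied) >= COHORT_AF_TOL:
                        raise ValidationError(
                            f"{self.cohort_id}/{name}: af {e.af} disagrees with "
                            f"allele_count/allele_number = {implied:.6f}"
                        )


@dataclass
class RegionRegistryRecord:
    """Epidemiological inputs for one region's CF prevalence.

    ``n_cases`` is the number of registered children with CF under the age
    horizon; ``mean_annual_births`` the average yearly birth count over that
    horizon (default 18 years, the registry's under-18 convention).
    """

    region_id: str
    n_cases: int
    mean_annual_births: float
    horizon_years: int = 18

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValidationError(f"{self.region_id}: n_cases must be >= 0")
        if self.mean_annual_births <= 0:
            raise ValidationError(f"{self.region_id}: mean_annual_births must be > 0")
        if self.horizon_years < 1:
            raise ValidationError(f"{self.region_id}: horizon_years must be >= 1")
        if self.n_cases > self.mean_annual_births * self.horizon_years:
            raise ValidationError(
                f"{self.region_id}: n_cases exceeds total births over the horizon"
            )


@dataclass
class PatientSpectrum:
    """Allele counts of variant categories among CF chromosomes in one region."""

    region_id: str
    n_patients: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_alleles(self) -> int:
        return sum(self.counts.values())

    def validate(self, strict: bool = False) -> None:
        """Check invariants.

        Published tables are internally rounded and may be off by a few
        alleles; deviations of ``|total - 2n| > 1`` are logged as warnings.
        With ``strict=True`` (synthetic data) exact equality is enforced.
        """
        if self.n_patients <= 0:
            raise ValidationError(f"{self.region_id}: n_patients must be positive")
        for cat, c in self.counts.items():
            if c < 0:
                raise ValidationError(f"{self.region_id}/{cat}: negative count {c}")
        expected = 2 * self.n_patients
        dev = self.total_alleles - expected
        if strict and dev != 0:
            raise ValidationError(
                f"{self.region_id}: counts sum to {self.total_alleles}, expected {expected}"
            )
        if abs(dev) > 1:
            log.warning(
                "spectrum %s: counts sum to %d but 2*n_patients = %d (off by %+d)",
                self.region_id, self.total_alleles, expected, dev,
            )


@dataclass
class IndirectAFEstimate:
    """Population AF of one variant inferred from registry epidemiology.

    ``Fd`` is the CF birth prevalence, ``q = sqrt(Fd)`` the disease-allele
    frequency under Hardy-Weinberg equilibrium, ``fa`` the variant's share of
    patient alleles, and ``af = q * fa`` the indirect population AF.
    """

    region_id: str
    variant: str
    Fd: float
    q: float
    fa: float
    af: float

    def validate(self) -> None:
        if not 0.0 <= self.Fd <= 1.0:
            raise ValidationError(f"Fd {self.Fd} outside [0, 1]")
        if not math.isclose(self.q, math.sqrt(self.Fd), rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError("q must equal sqrt(Fd)")
        if not 0.0 <= self.fa <= 1.0:
            raise ValidationError(f"fa {self.fa} outside [0, 1]")
        if self.af > self.q + 1e-12:
            raise ValidationError("af = q*fa cannot exceed q")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: Path | str) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        rows.append(raw.split("\t"))
    return rows


def read_variant_catalog(path: Path | str) -> list[VariantDef]:
    """Read a variant catalog TSV (legacy_name, hgvs_c, hgvs_p, rsid)."""
    rows = _data_lines(path)
    if not rows:
        return []
    header, body = rows[0], rows[1:]
    if [h.strip() for h in header[:2]] != ["legacy_name", "hgvs_c"]:
        raise ParseError(f"{path}: unexpected catalog header {header[:2]}")
    out: list[VariantDef] = []
    seen: set[str] = set()
    for cells in body:
        name, hgvs_c = cells[0].strip(), cells[1].strip()
        hgvs_p = cells[2].strip() if len(cells) > 2 else ""
        rsid = cells[3].strip() if len(cells) > 3 else ""
        if name in seen:
            raise ValidationError(f"{path}: duplicate legacy_name {name!r}")
        seen.add(name)
        out.append(
            VariantDef(
                legacy_name=name,
                hgvs_c=hgvs_c,
                hgvs_p=None if hgvs_p in (ABSENT_RSID, "") else hgvs_p,
                rsid=None if rsid in (ABSENT_RSID, "") else rsid,
            )
        )
    return out


def _parse_af_token(token: str, *, row: str, column: str) -> float | None:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return None
    try:
        value = float(tok)
    except ValueError:
        raise ParseError(
            f"row {row!r}, column {column!r}: malformed AF token {tok!r}"
        ) from None
    if not 0.0 <= value <= 1.0:
        raise ParseError(
            f"row {row!r}, column {column!r}: AF {value} outside [0, 1]"
        )
    return value


def read_cohort_table(path: Path | str) -> list[CohortAF]:
    """Read a cohort AF matrix.

    The first two columns are ``legacy_name`` and ``rsid``; every further
    header cell names a cohort as ``label (n=<individuals>)``.  ``n.a.``,
    ``NA`` and empty cells denote MISSING and are preserved as such.
    """
    rows = _data_lines(path)
    if not rows:
        return []
    header, body = rows[0], rows[1:]
    if len(header) < 2 or header[0].strip() != "legacy_name" or header[1].strip() != "rsid":
        raise ParseError(f"{path}: first two columns must be legacy_name and rsid")
    cohorts: list[CohortAF] = []
    for cell in header[2:]:
        m = _COHORT_HEADER_RE.match(cell.strip())
        if not m:
            raise ParseError(f"{path}: cohort header {cell!r} is not 'label (n=...)'")
        cohorts.append(CohortAF(cohort_id=m["id"], n_individuals=int(m["n"])))
    seen: set[str] = set()
    for cells in body:
        name = cells[0].strip()
        if name in seen:
            raise ValidationError(f"{path}: duplicate legacy_name {name!r}")
        seen.add(name)
        for cohort, tok in zip(cohorts, cells[2:]):
            af = _parse_af_token(tok, row=name, column=cohort.cohort_id)
            cohort.entries[name] = CohortEntry(af=af)
    for cohort in cohorts:
        cohort.validate()
    return cohorts


def read_spectrum_table(
    path: Path | str, *, strict: bool = False, counts_from: str = "ac"
) -> list[PatientSpectrum]:
    """Read per-region patient allele spectra.

    Expected columns: ``region``, ``n``, then ``<category>_AF`` /
    ``<category>_AC`` pairs.  By default the AC columns are authoritative and
    each AF column is cross-checked against ``AC/total`` with a warning logged
    on mismatch beyond the rounding tolerance.  ``counts_from="af"`` instead
    re-derives every count as ``round(AF * 2n)`` (logged), which traces
    published statistics computed from the rounded AF columns.
    """
    if counts_from not in ("ac", "af"):
        raise ValidationError(f"counts_from must be 'ac' or 'af', got {counts_from!r}")
    rows = _data_lines(path)
    if not rows:
        return []
    header, body = rows[0], rows[1:]
    if header[:2] != ["region", "n"]:
        raise ParseError(f"{path}: first two columns must be region and n")
    categories: list[str] = []
    for i in range(2, len(header), 2):
        af_col, ac_col = header[i].strip(), header[i + 1].strip()
        if not (af_col.endswith("_AF") and ac_col.endswith("_AC")):
            raise ParseError(f"{path}: expected <category>_AF/<category>_AC pairs")
        cat = af_col[:-3]
        if ac_col[:-3] != cat:
            raise ParseError(f"{path}: AF/AC pair mismatch {af_col!r} vs {ac_col!r}")
        if cat in categories:
            raise ValidationError(f"{path}: duplicate category {cat!r}")
        categories.append(cat)
    spectra: list[PatientSpectrum] = []
    for cells in body:
        region = cells[0].strip()
        n_patients = int(cells[1])
        counts: dict[str, int] = {}
        afs: dict[str, float] = {}
        for j, cat in enumerate(categories):
            af_tok, ac_tok = cells[2 + 2 * j], cells[3 + 2 * j]
            count = int(ac_tok)
            if count < 0:
                raise ValidationError(f"{region}/{cat}: negative count {count}")
            counts[cat] = count
            afs[cat] = float(af_tok)
        if counts_from == "af":
            from .estimate import reconstruct_count  # local import: no cycle at load

            counts = {
                cat: reconstruct_count(afs[cat], 2 * n_patients) for cat in categories
            }
        spectrum = PatientSpectrum(region_id=region, n_patients=n_patients, counts=counts)
        spectrum.validate(strict=strict)
        total = spectrum.total_alleles
        if total > 0:
            for cat in categories:
                implied = counts[cat] / total
                if abs(afs[cat] - implied) > SPECTRUM_AF_TOL:
                    log.warning(
                        "spectrum %s/%s: printed AF %.4f disagrees with AC/total = %.4f",
                        region, cat, afs[cat], implied,
                    )
        spectra.append(spectrum)
    return spectra


def read_registry_table(path: Path | str) -> list[RegionRegistryRecord]:
    """Read registry records: region, n_cases, mean_annual_births[, horizon_years]."""
    rows = _data_lines(path)
    if not rows:
        return []
    header, body = rows[0], rows[1:]
    expected = ["region", "n_cases", "mean_annual_births"]
    if [h.strip() for h in header[:3]] != expected:
        raise ParseError(f"{path}: registry header must start with {expected}")
    records = []
    for cells in body:
        rec = RegionRegistryRecord(
            region_id=cells[0].strip(),
            n_cases=int(cells[1]),
            mean_annual_births=float(cells[2]),
            horizon_years=int(cells[3]) if len(cells) > 3 else 18,
        )
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt_value(value, fmt: str) -> str:
    if value is None:
        return MISSING_OUT
    if isinstance(value, float):
        return fmt % value
    return str(value)


def write_report_table(
    rows: Sequence[Mapping[str, object]],
    path: Path | str,
    *,
    float_fmt: str = "%.4f",
    column_fmts: Mapping[str, str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write homogeneous rows as TSV.

    Floats are rendered with ``float_fmt`` (4 decimal places by default, the
    convention of the source AF tables); per-column overrides go through
    ``column_fmts``.  ``None`` values are written as ``n.a.``.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("write_report_table: no rows to write")
    columns = list(rows[0].keys())
    for r in rows[1:]:
        if list(r.keys()) != columns:
            raise ValidationError("write_report_table: rows are not homogeneous")
    fmts = dict(column_fmts or {})
    lines = []
    if header_comment:
        lines.extend("# " + ln for ln in header_comment.splitlines())
    lines.append("\t".join(columns))
    for r in rows:
        lines.append("\t".join(_fmt_value(r[c], fmts.get(c, float_fmt)) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort_table(
    cohorts: Sequence[CohortAF],
    path: Path | str,
    *,
    variants: Sequence[str] | None = None,
    rsids: Mapping[str, str | None] | None = None,
    extra_rows: Sequence[Mapping[str, object]] = (),
    header_comment: str | None = None,
) -> None:
    """Write a cohort AF matrix in the same dialect :func:`read_cohort_table` reads."""
    if not cohorts:
        raise ValidationError("write_cohort_table: no cohorts")
    if variants is None:
        variants = list(cohorts[0].entries.keys())
    rows: list[Mapping[str, object]] = []
    for name in variants:
        row: dict[str, object] = {
            "legacy_name": name,
            "rsid": (rsids or {}).get(name) or ABSENT_RSID,
        }
        for c in cohorts:
            entry = c.entries.get(name)
            row[f"{c.cohort_id} (n={c.n_individuals})"] = None if entry is None else entry.af
        rows.append(row)
    for extra in extra_rows:
        rows.append(dict(extra))
    write_report_table(rows, path, header_comment=header_comment)


def write_spectrum_table(
    spectra: Sequence[PatientSpectrum],
    path: Path | str,
    *,
    precision: int = 4,
    header_comment: str | None = None,
) -> None:
    """Write spectra in the AF/AC-pair dialect :func:`read_spectrum_table` reads."""
    if not spectra:
        raise ValidationError("write_spectrum_table: no spectra")
    categories = list(spectra[0].counts.keys())
    fmt = f"%.{precision}f"
    rows = []
    for s in spectra:
        row: dict[str, object] = {"region": s.region_id, "n": s.n_patients}
        total = s.total_alleles
        for cat in categories:
            count = s.counts.get(cat, 0)
            row[f"{cat}_AF"] = (count / total) if total else 0.0
            row[f"{cat}_AC"] = count
        rows.append(row)
    write_report_table(rows, path, float_fmt=fmt, header_comment=header_comment)


def load_packaged_fixture(name: str) -> Path:
    """Path to one of the TSV tables shipped with the package."""
    from importlib.resources import files

    resource = files("cftrfreq").joinpath("data", name)
    return Path(str(resource))
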