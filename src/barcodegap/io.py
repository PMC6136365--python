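"""Readers and writers for the three tabular inputs.

Formats
-------
checklist.csv : binomial,genus,family,order,growth_form,naturalized,threat_class,distribution_class
accessions.csv: accession_id,taxon,marker,submission_date,source
surveys.csv   : survey_id,taxon,count[,area_ha]
synonyms.csv  : old_name,accepted_name   (optional)

Dates are ISO-8601; the GenBank flat-file dialect ``01-DEC-1993`` is also
accepted.  Name matching is exact on the canonical binomial after
case/whitespace normalization (optionally via a user synonym table);
no fuzzy matching is attempted.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ValidationError
from .markers import normalize_marker
from .names import MatchLevel, parse_taxon_name
from .records import (
    AccessionRecord,
    CommunitySurvey,
    DistributionClass,
    GrowthForm,
    LoadReport,
    Source,
    SpeciesRecord,
    ThreatClass,
    UNRESOLVED,
)

PathLike = Union[str, Path]

CHECKLIST_COLUMNS = [
    "binomial", "genus", "family", "order", "growth_form",
    "naturalized", "threat_class", "distribution_class",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _canon_binomial(name: str) -> str:
    return " ".join(str(name).split()).lower()


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"row {row}: invalid boolean 'naturalized' value {value!r}")


def _parse_enum(enum_cls, value, row: int, column: str):
    try:
        return enum_cls(str(value).strip())
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"row {row}, column {column!r}: unknown code {value!r} (valid: {valid})"
        ) from None


def load_checklist(path: PathLike) -> list[SpeciesRecord]:
    """Load and validate a species checklist.

    Raises :class:`ValidationError` on duplicate binomials, genus/binomial
    mismatches, or unknown enum codes, naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CHECKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"checklist missing columns: {missing}")
    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        binomial = " ".join(str(row.binomial).split())
        key = binomial.lower()
        if key in seen:
            raise ValidationError(f"row {i}: duplicate binomial {binomial!r}")
        seen.add(key)
        genus = str(row.genus).strip()
        if binomial.split()[0] != genus:
            raise ValidationError(
                f"row {i}: genus {genus!r} does not match binomial {binomial!r}"
            )
        records.append(
            SpeciesRecord(
                binomial=binomial,
                genus=genus,
                family=str(row.family).strip(),
                order=str(row.order).strip(),
                growth_form=_parse_enum(GrowthForm, row.growth_form, i, "growth_form"),
                naturalized=_parse_bool(row.naturalized, i),
                threat_class=_parse_enum(ThreatClass, row.threat_class, i, "threat_class"),
                distribution_class=_parse_enum(
                    DistributionClass, row.distribution_class, i, "distribution_class"
                ),
            )
        )
    return records


def write_checklist(records: Iterable[SpeciesRecord], path: PathLike) -> None:
    """Write a checklist; ``load_checklist(write_checklist(x))`` round-trips."""
    df = checklist_frame(records)
    df.to_csv(path, index=False)


def checklist_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    rows = [
        {
            "binomial": r.binomial,
            "genus": r.genus,
            "family": r.family,
            "order": r.order,
            "growth_form": r.growth_form.value,
            "naturalized": str(r.naturalized).lower(),
            "threat_class": r.threat_class.value,
            "distribution_class": r.distribution_class.value,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CHECKLIST_COLUMNS)


def load_synonyms(path: PathLike) -> dict[str, str]:
    """Load an old_name -> accepted_name mapping (lower-cased keys)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("old_name", "accepted_name"):
        if col not in df.columns:
            raise ValidationError(f"synonyms file missing column {col!r}")
    return {
        _canon_binomial(o): " ".join(str(a).split())
        for o, a in zip(df["old_name"], df["accepted_name"])
    }


def parse_date(value: str) -> dt.date:
    """Parse ISO-8601 ``1993-12-01`` or GenBank ``01-DEC-1993`` dates."""
    s = str(value).strip()
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        pass
    try:
        return dt.datetime.strptime(s.upper(), "%d-%b-%Y").date()
    except ValueError:
        raise ValidationError(f"unparseable date: {value!r}") from None


def load_accessions(
    path: PathLike,
    checklist: list[SpeciesRecord],
    synonyms: Optional[dict[str, str]] = None,
) -> tuple[list[AccessionRecord], LoadReport]:
    """Load accession metadata, resolving taxa against the checklist.

    Unresolvable taxa are flagged :data:`UNRESOLVED` and counted (never
    silently dropped); rows with unparseable dates are skipped and listed
    in the report.  ``resolved + unresolved + skipped == input rows``.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["accession_id", "taxon", "marker", "submission_date", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"accessions missing columns: {missing}")
    known = {_canon_binomial(r.binomial): r.binomial for r in checklist}
    synonyms = synonyms or {}
    report = LoadReport()
    out: list[AccessionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        report.n_rows += 1
        try:
            date = parse_date(row.submission_date)
        except ValidationError:
            report.n_skipped += 1
            report.skipped_rows.append(
                f"row {i} ({row.accession_id}): bad date {row.submission_date!r}"
            )
            continue
        raw = str(row.taxon)
        lookup = synonyms.get(_canon_binomial(raw), raw)
        try:
            parsed = parse_taxon_name(lookup)
        except Exception:
            parsed = None
        species = UNRESOLVED
        if parsed is not None:
            if parsed.infraspecific:
                report.n_trinomial += 1
            if parsed.match_level is MatchLevel.SPECIES and parsed.binomial:
                species = known.get(_canon_binomial(parsed.binomial), UNRESOLVED)
        if species == UNRESOLVED:
            report.n_unresolved += 1
            report.unresolved_names[raw] = report.unresolved_names.get(raw, 0) + 1
        else:
            report.n_resolved += 1
        out.append(
            AccessionRecord(
                accession_id=str(row.accession_id),
                raw_taxon=raw,
                species=species,
                marker=normalize_marker(row.marker),
                submission_date=date,
                source=Source(str(row.source).strip().lower()),
            )
        )
    report.check()
    return out, report


def load_surveys(path: PathLike, checklist=None) -> list[CommunitySurvey]:
    """Load long-format community surveys; counts must be positive integers."""
    df = pd.read_csv(path, dtype=str)
    required = ["survey_id", "taxon", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"surveys missing columns: {missing}")
    has_area = "area_ha" in df.columns
    surveys: dict[str, CommunitySurvey] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count = int(str(row.count))
        except ValueError:
            raise ValidationError(f"row {i}: non-integer count {row.count!r}") from None
        if count <= 0:
            raise ValidationError(f"row {i}: count must be positive, got {count}")
        parsed = parse_taxon_name(row.taxon)
        sid = str(row.survey_id)
        if sid not in surveys:
            area = None
            if has_area and str(getattr(row, "area_ha", "")) not in ("", "nan"):
                area = float(row.area_ha)
            surveys[sid] = CommunitySurvey(survey_id=sid, records=[], sampled_area_ha=area)
        surveys[sid].records.append((parsed, count))
    return list(surveys.values())
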