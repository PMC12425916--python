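"""Study records: reading, validation, descriptives and results tables.

A *study record* is one reanalyzed cross-lagged effect: the sample size N,
the six pairwise correlations among the predictor and the outcome measured
at two occasions (P1, P2, E1, E2), and descriptive metadata.  Standardized
regression effects are functions of these correlations alone, which is what
makes correlation-matched simulation a faithful reanalysis device.

Column/field naming convention (used by every reader and writer in the
package): the four variables are ordered (P1, P2, E1, E2) and the six
correlations are ``r_p1p2, r_p1e1, r_p1e2, r_p2e1, r_p2e2, r_e1e2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "StudyRecord",
    "StudySummary",
    "CORRELATION_FIELDS",
    "load_studies",
    "write_studies",
    "builtin_table1",
    "summarize_studies",
    "write_results_table",
    "render_results_markdown",
    "p_stars",
    "format_effect_cell",
]

CORRELATION_FIELDS = ("r_p1p2", "r_p1e1", "r_p1e2", "r_p2e1", "r_p2e2", "r_e1e2")

_REQUIRED_FIELDS = ("effect_id", "n")
_MIN_N = 4


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class StudyRecord:
    """One reanalyzed cross-lagged effect.

    The six correlations may be missing (``None``) — the built-in descriptive
    fixture carries only what the source table prints, and correlations must
    then be supplied by the user before scrutiny can run.
    """

    effect_id: str
    n: int
    r_p1p2: float | None = None
    r_p1e1: float | None = None
    r_p1e2: float | None = None
    r_p2e1: float | None = None
    r_p2e2: float | None = None
    r_e1e2: float | None = None
    predictor_name: str = ""
    waves: tuple[int, int] = (1, 2)
    original_b: float | None = None
    pct_male: float | None = None
    mean_age: float | None = None

    def __post_init__(self):
        if not self.effect_id:
            raise SchemaError("effect_id must be a non-empty string")
        if int(self.n) < _MIN_N:
            raise ValidationError(
                f"effect {self.effect_id!r}: n={self.n} is below the minimum "
                f"of {_MIN_N} required by the fitted models"
            )
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "waves", tuple(int(w) for w in self.waves))
        for name in CORRELATION_FIELDS:
            r = getattr(self, name)
            if _is_missing(r):
                object.__setattr__(self, name, None)
                continue
            r = float(r)
            if not -1.0 <= r <= 1.0:
                raise ValidationError(
                    f"effect {self.effect_id!r}: correlation {name}={r} "
                    "lies outside [-1, 1]"
                )
            object.__setattr__(self, name, r)
        pm = self.pct_male
        if not _is_missing(pm) and not 0.0 <= float(pm) <= 100.0:
            raise ValidationError(
                f"effect {self.effect_id!r}: pct_male={pm} outside [0, 100]"
            )

    @property
    def study_id(self) -> str:
        """Study identifier: the part of the effect id before the dot."""
        return self.effect_id.split(".")[0]

    @property
    def has_correlations(self) -> bool:
        return all(getattr(self, f) is not None for f in CORRELATION_FIELDS)

    def correlations(self) -> dict[str, float]:
        if not self.has_correlations:
            missing = [f for f in CORRELATION_FIELDS if getattr(self, f) is None]
            raise ValidationError(
                f"effect {self.effect_id!r}: missing correlations {missing}"
            )
        return {f: getattr(self, f) for f in CORRELATION_FIELDS}

    def with_correlations(self, **corr: float) -> "StudyRecord":
        """Return a copy with (some of) the six correlations replaced."""
        unknown = set(corr) - set(CORRELATION_FIELDS)
        if unknown:
            raise SchemaError(f"unknown correlation fields: {sorted(unknown)}")
        return replace(self, **corr)


@dataclass(frozen=True)
class StudySummary:
    """Study-level descriptive statistics (one row per study, not per effect)."""

    n_studies: int
    n_effects: int
    n_min: float
    n_max: float
    n_mean: float
    pct_male_mean: float | None
    age_mean: float | None

    def __post_init__(self):
        if not self.n_min <= self.n_mean <= self.n_max:
            raise ValidationError("n_min <= n_mean <= n_max violated")


# --------------------------------------------------------------------------
# Reading and writing study tables
# --------------------------------------------------------------------------

_CSV_COLUMNS = [
    "effect_id", "n", *CORRELATION_FIELDS, "predictor_name",
    "wave_from", "wave_to", "original_b", "pct_male", "mean_age",
]


def _normalize_minus(x):
    if isinstance(x, str):
        return x.replace("−", "-").strip()
    return x


def _record_from_mapping(row: dict) -> StudyRecord:
    for f in _REQUIRED_FIELDS:
        if f not in row or _is_missing(row[f]) or row[f] == "":
            raise SchemaError(f"missing required field {f!r} in study row {row!r}")
    if "waves" in row and not _is_missing(row["waves"]):
        waves = tuple(int(w) for w in row["waves"])
    else:
        waves = (int(row.get("wave_from", 1) or 1), int(row.get("wave_to", 2) or 2))

    def num(key):
        v = _normalize_minus(row.get(key))
        if _is_missing(v) or v == "" or v == "-":
            return None
        return float(v)

    return StudyRecord(
        effect_id=str(row["effect_id"]),
        n=int(float(_normalize_minus(row["n"]))),
        **{f: num(f) for f in CORRELATION_FIELDS},
        predictor_name=str(row.get("predictor_name", "") or ""),
        waves=waves,
        original_b=num("original_b"),
        pct_male=num("pct_male"),
        mean_age=num("mean_age"),
    )


def load_studies(path: str | Path, format: str | None = None) -> list[StudyRecord]:
    """Read study records from a CSV or JSON file.

    CSV must have a header row with the field names (``waves`` is split into
    ``wave_from``/``wave_to``); JSON is a list of objects with the field
    names, ``waves`` as a two-element list.  Unicode minus signs are accepted
    and normalized.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_FIELDS if c not in df.columns]
        if missing:
            raise SchemaError(f"CSV {path} lacks required columns {missing}")
        rows = df.to_dict(orient="records")
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise SchemaError(f"JSON {path} must contain a list of study objects")
    else:
        raise SchemaError(f"unknown format {fmt!r} (expected 'csv' or 'json')")
    return [_record_from_mapping(dict(row)) for row in rows]


def write_studies(records: Sequence[StudyRecord], path: str | Path,
                  format: str | None = None) -> Path:
    """Write study records to CSV or JSON (inverse of :func:`load_studies`)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "waves"}
        if fmt == "csv":
            row["wave_from"], row["wave_to"] = r.waves
        else:
            row["waves"] = list(r.waves)
        rows.append(row)
    if fmt == "csv":
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise SchemaError(f"unknown format {fmt!r}")
    return path


# --------------------------------------------------------------------------
# Built-in descriptive fixture
# --------------------------------------------------------------------------

# (effect_id, n, pct_male, mean_age, wave_from, wave_to, predictor, original_b)
# Correlations are deliberately absent: the source table prints only the
# descriptives, and the six correlations live in the public data deposit of
# the reanalysis; users supply them via StudyRecord.with_correlations.
_TABLE1 = [
    ("1.1", 651, 90.0, 35.0, 1, 2, "Organizational demands", 0.11),
    ("2.1", 1314, 32.0, 43.0, 1, 2, "Job insecurity", 0.05),
    ("3.1", 261, 52.0, 46.0, 1, 2, "Work family interference", 0.14),
    ("3.2", 261, 52.0, 46.0, 1, 2, "Avoidance", 0.10),
    ("3.3", 261, 52.0, 46.0, 1, 2, "Perfectionism", 0.12),
    ("4.1", 2235, 54.0, 45.0, 1, 2, "Work to family conflict", 0.34),
    ("4.2", 2235, 54.0, 45.0, 1, 2, "Work to family facilitation", -0.24),
    ("4.3", 2235, 54.0, 45.0, 1, 2, "Family to work conflict", 0.06),
    ("5.1", 1703, 78.0, None, 1, 2, "Work role conflict", 0.06),
    ("5.2", 1703, 78.0, None, 1, 2, "Work family conflict", 0.06),
    ("6.1", 1702, 78.0, None, 1, 2, "Psychological health complaints", 0.16),
    ("7.1", 664, 42.0, 48.0, 1, 2, "Affective rumination", 0.14),
    ("7.2", 664, 42.0, 48.0, 2, 3, "Affective rumination", 0.11),
    ("8.1", 1226, 50.0, 13.0, 1, 2, "Sleep problems", 0.24),
    ("8.2", 1226, 50.0, 13.0, 2, 3, "Sleep problems", 0.23),
    ("8.3", 1226, 50.0, 13.0, 3, 4, "Sleep problems", 0.33),
    ("9.1", 142, 24.0, 21.0, 1, 2, "Grades", -0.14),
    ("10.1", 191, 44.0, 43.0, 1, 2, "Perfectionistic concerns", 0.22),
    ("11.1", 542, 46.0, 23.0, 1, 2, "Depression", 0.11),
    ("11.2", 542, 46.0, 23.0, 2, 3, "Depression", 0.12),
    ("11.3", 542, 46.0, 23.0, 3, 4, "Depression", 0.13),
    ("12.1", 155, None, None, 1, 2, "Incivility", 0.18),
    ("13.1", 349, 0.0, 49.0, 1, 2, "Work ability", -0.16),
]


def builtin_table1() -> list[StudyRecord]:
    """The 23 reanalyzed effects' descriptives (N, predictor, waves, original b).

    The six correlation fields are missing by construction; supply them from
    the deposited per-study correlation matrices (or synthetically) before
    running the scrutiny pipeline.
    """
    return [
        StudyRecord(
            effect_id=eid, n=n, pct_male=male, mean_age=age,
            waves=(w1, w2), predictor_name=pred, original_b=b,
        )
        for eid, n, male, age, w1, w2, pred, b in _TABLE1
    ]


def summarize_studies(records: Sequence[StudyRecord]) -> StudySummary:
    """Study-level descriptives: one row per study before averaging.

    Effects from the same study (same id prefix before the dot) share sample
    and demographics, so N, %male and age are deduplicated to the study level
    first.  Missing demographics are excluded from their means.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize_studies requires at least one record")
    per_study: dict[str, StudyRecord] = {}
    for r in records:
        per_study.setdefault(r.study_id, r)
    ns = [float(r.n) for r in per_study.values()]
    males = [r.pct_male for r in per_study.values() if r.pct_male is not None]
    ages = [r.mean_age for r in per_study.values() if r.mean_age is not None]
    return StudySummary(
        n_studies=len(per_study),
        n_effects=len(records),
        n_min=min(ns),
        n_max=max(ns),
        n_mean=sum(ns) / len(ns),
        pct_male_mean=sum(males) / len(males) if males else None,
        age_mean=sum(ages) / len(ages) if ages else None,
    )


# --------------------------------------------------------------------------
# Results output
# --------------------------------------------------------------------------

def p_stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_effect_cell(b: float, ci_low: float, ci_high: float,
                       stars: str = "") -> str:
    """Render an effect with its 95% CI at two decimals: ``0.35 [0.28; 0.42]``."""
    return f"{b:.2f} [{ci_low:.2f}; {ci_high:.2f}]{stars}"


def _result_row(res) -> dict:
    row: dict = {"effect_id": res.effect_id}
    for key, eff in (("A", res.effect_A), ("B", res.effect_B), ("C", res.effect_C)):
        row[f"b_{key}"] = round(eff.b, 2)
        row[f"ci_low_{key}"] = round(eff.ci95[0], 2)
        row[f"ci_high_{key}"] = round(eff.ci95[1], 2)
        row[f"stars_{key}"] = p_stars(eff.p_value)
    d = res.fit_D
    row["chi2_D"] = round(d.chi2, 1)
    row["cfi_D"] = round(d.cfi, 2)
    row["rmsea_D"] = round(d.rmsea, 2)
    row["rmsea_low_D"] = round(d.rmsea_ci90[0], 2)
    row["rmsea_high_D"] = round(d.rmsea_ci90[1], 2)
    row["verdict"] = res.verdict
    return row


def write_results_table(results: Iterable, path: str | Path) -> Path:
    """Write per-effect scrutiny results as CSV.

    Columns: focal effect b with 95% CI and significance stars for the CLPM
    (A), reversed CLPM (B) and latent change score model (C); χ², CFI and
    RMSEA with 90% CI for the artifactualness model (D); and the verdict.
    Numbers are rounded to two decimals (χ² to one), matching the reporting
    convention of the reanalysis tables.
    """
    results = list(results)
    if not results:
        raise ValueError("write_results_table requires at least one result")
    df = pd.DataFrame([_result_row(r) for r in results])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def render_results_markdown(results: Iterable) -> str:
    """Human-readable Markdown rendering of the scrutiny results table."""
    results = list(results)
    if not results:
        raise ValueError("no results to render")
    lines = [
        "| Effect | A | B | C | χ² | CFI | RMSEA [90% CI] | Verdict |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for res in results:
        cells = [
            format_effect_cell(e.b, *e.ci95, stars=p_stars(e.p_value))
            for e in (res.effect_A, res.effect_B, res.effect_C)
        ]
        d = res.fit_D
        lines.append(
            f"| {res.effect_id} | {cells[0]} | {cells[1]} | {cells[2]} | "
            f"{d.chi2:.1f} | {d.cfi:.2f} | "
            f"{d.rmsea:.2f} [{d.rmsea_ci90[0]:.2f}; {d.rmsea_ci90[1]:.2f}] | "
            f"{res.verdict} |"
        )
    return "\n".join(lines)
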