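"""Cohort file I/O and the end-to-end validation pipeline.

The cohort lives in a single flat delimited file (comma, UTF-8, header
row) with one subject per row.  Units: cm (height, tumor size), kg,
ug/day (urinary metanephrines), months (event and follow-up times).
Booleans are written as 0/1 and read as {0, 1, true, false, yes, no},
case-insensitively.  Vascular and capsular invasion appear once each —
they are shared between the GAPP invasion item and the corresponding
PASS items, so there are no ``pass_vascular_invasion`` /
``pass_capsular_invasion`` columns.

:func:`run_validation` takes a cohort and produces every table of the
validation report: baseline group comparisons, univariate/multivariate
Cox tables per scoring system, score distributions and classification
contingencies, the ROC/AUC comparison with DeLong tests, Kaplan-Meier
metastasis-free-survival curves with log-rank tests, and score-vs-time
correlations.  Stages whose preconditions fail (e.g. a single-class
cohort) are skipped with a logged reason rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import grading_core as gc
from . import validation_stats as vs
from .errors import (
    ConvergenceError,
    DomainError,
    PPGLError,
    SchemaError,
)
from .grading_core import (
    BiochemistryProfile,
    Cellularity,
    GappClass,
    HistologyProfile,
    PatientRecord,
    ScorePanel,
    ScoringConfig,
    Sex,
    TumorSite,
    compute_score_panel,
)

logger = logging.getLogger("ppgl_grading")

__all__ = [
    "COHORT_COLUMNS",
    "ValidationReport",
    "convert_spreadsheet",
    "read_cohort",
    "run_validation",
    "scores_frame",
    "write_cohort",
]

_PASS_OWN = tuple(k for k in gc.PASS_ITEMS if k not in ("vascular_invasion", "capsular_invasion"))

_BOOL_COLUMNS = (
    "familial",
    "umn_elevated",
    "unm_elevated",
    "large_irregular_nest",
    "pseudorosette",
    "comedo_necrosis",
    "vascular_invasion",
    "capsular_invasion",
    "sdhb_ihc_positive",
    "metastasis",
) + tuple(f"pass_{k}" for k in _PASS_OWN)

_FLOAT_COLUMNS = (
    "age_years",
    "height_cm",
    "weight_kg",
    "bmi",
    "tumor_size_cm",
    "umn_ug_day",
    "unm_ug_day",
    "ki67_percent",
    "time_to_metastasis_months",
    "followup_months",
)

#: The documented cohort schema, in file order.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "bmi",
    "tumor_site",
    "tumor_size_cm",
    "familial",
    "umn_ug_day",
    "unm_ug_day",
    "umn_elevated",
    "unm_elevated",
    "large_irregular_nest",
    "pseudorosette",
    "comedo_necrosis",
    "cellularity_class",
    "ki67_percent",
    "vascular_invasion",
    "capsular_invasion",
    "sdhb_ihc_positive",
    *(f"pass_{k}" for k in _PASS_OWN),
    "metastasis",
    "time_to_metastasis_months",
    "followup_months",
)

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


def _parse_bool(value, column: str, row: int) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token == "" or token == "nan":
        return None
    if token.endswith(".0"):
        token = token[:-2]
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise SchemaError(f"row {row}: column {column!r}: unparseable boolean {value!r}")


def _parse_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: column {column!r}: unparseable number {value!r}")
    return None if np.isnan(out) else out


def _parse_enum(value, enum_cls, column: str, row: int):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    token = str(value).strip()
    if token == "" or token.lower() == "nan":
        return None
    try:
        return enum_cls(token if enum_cls is not Cellularity else token.lower())
    except ValueError:
        raise SchemaError(
            f"row {row}: column {column!r}: {value!r} not in "
            f"{[m.value for m in enum_cls]}"
        )


def _record_from_row(row: Mapping, idx: int) -> PatientRecord:
    b = {c: _parse_bool(row[c], c, idx) for c in _BOOL_COLUMNS}
    f = {c: _parse_float(row[c], c, idx) for c in _FLOAT_COLUMNS}
    histology = HistologyProfile(
        large_irregular_nest=b["large_irregular_nest"],
        pseudorosette=b["pseudorosette"],
        comedo_necrosis=b["comedo_necrosis"],
        cellularity_class=_parse_enum(row["cellularity_class"], Cellularity, "cellularity_class", idx),
        ki67_percent=f["ki67_percent"],
        vascular_invasion=b["vascular_invasion"],
        capsular_invasion=b["capsular_invasion"],
        sdhb_ihc_positive=b["sdhb_ihc_positive"],
        pass_features_own={k: b[f"pass_{k}"] for k in _PASS_OWN},
    )
    bio = BiochemistryProfile(
        umn_ug_day=f["umn_ug_day"],
        unm_ug_day=f["unm_ug_day"],
        umn_elevated=b["umn_elevated"],
        unm_elevated=b["unm_elevated"],
    )
    if b["metastasis"] is None:
        raise SchemaError(f"row {idx}: column 'metastasis': value required")
    if f["followup_months"] is None:
        raise SchemaError(f"row {idx}: column 'followup_months': value required")
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=f["age_years"],
        sex=_parse_enum(row["sex"], Sex, "sex", idx),
        height_cm=f["height_cm"],
        weight_kg=f["weight_kg"],
        bmi=f["bmi"],
        tumor_site=_parse_enum(row["tumor_site"], TumorSite, "tumor_site", idx),
        tumor_size_cm=f["tumor_size_cm"],
        familial=b["familial"],
        biochemistry=bio,
        histology=histology,
        metastasis=b["metastasis"],
        time_to_metastasis_months=f["time_to_metastasis_months"],
        followup_months=f["followup_months"],
    )


def read_cohort(path, strict: bool = True) -> list[PatientRecord]:
    """Read a cohort file into validated :class:`PatientRecord` objects.

    A missing mandatory column raises :class:`SchemaError` immediately.
    Row-level problems are collected with their (1-based, header-excluded)
    row numbers; with ``strict`` (default) any row error raises a single
    :class:`SchemaError` listing all of them, otherwise offending rows are
    dropped with a warning.
    """
    df = pd.read_csv(path, dtype=object, keep_default_na=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file is missing mandatory column(s): {missing}")
    records: list[PatientRecord] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_record_from_row(row, i))
        except (SchemaError, DomainError, PPGLError) as exc:
            problems.append(f"row {i}: {exc}" if "row" not in str(exc) else str(exc))
    if problems:
        if strict:
            raise SchemaError(
                f"{len(problems)} invalid row(s):\n" + "\n".join(problems)
            )
        for msg in problems:
            logger.warning("dropped %s", msg)
    return records


def _serialize(value):
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if hasattr(value, "value"):  # Enum
        return value.value
    return value


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records in the documented schema (booleans as 0/1, lossless)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "bmi": r.bmi,
            "tumor_site": r.tumor_site,
            "tumor_size_cm": r.tumor_size_cm,
            "familial": r.familial,
            "umn_ug_day": r.biochemistry.umn_ug_day,
            "unm_ug_day": r.biochemistry.unm_ug_day,
            "umn_elevated": r.biochemistry.umn_elevated,
            "unm_elevated": r.biochemistry.unm_elevated,
            "large_irregular_nest": r.histology.large_irregular_nest,
            "pseudorosette": r.histology.pseudorosette,
            "comedo_necrosis": r.histology.comedo_necrosis,
            "cellularity_class": r.histology.cellularity_class,
            "ki67_percent": r.histology.ki67_percent,
            "vascular_invasion": r.histology.vascular_invasion,
            "capsular_invasion": r.histology.capsular_invasion,
            "sdhb_ihc_positive": r.histology.sdhb_ihc_positive,
            **{f"pass_{k}": r.histology.pass_features_own.get(k) for k in _PASS_OWN},
            "metastasis": r.metastasis,
            "time_to_metastasis_months": r.time_to_metastasis_months,
            "followup_months": r.followup_months,
        }
        rows.append({k: _serialize(v) for k, v in row.items()})
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def convert_spreadsheet(xlsx_path, column_map: Mapping[str, str], out_path) -> None:
    """Convert a participant-level spreadsheet to the flat cohort schema.

    ``column_map`` maps source spreadsheet column names to schema column
    names — the source naming is site-specific, so the map must be
    supplied by the user rather than guessed.  Unmapped schema columns are
    written empty; unmapped source columns are dropped.
    """
    df = pd.read_excel(xlsx_path, dtype=object)
    missing_src = [c for c in column_map if c not in df.columns]
    if missing_src:
        raise SchemaError(f"spreadsheet is missing mapped column(s): {missing_src}")
    bad_targets = [c for c in column_map.values() if c not in COHORT_COLUMNS]
    if bad_targets:
        raise SchemaError(f"column map targets unknown schema column(s): {bad_targets}")
    out = df.rename(columns=dict(column_map))
    for col in COHORT_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[list(COHORT_COLUMNS)].to_csv(out_path, index=False)


# ---------------------------------------------------------------------------
# validation pipeline


def scores_frame(
    records: Sequence[PatientRecord], config: ScoringConfig = gc.DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-subject :class:`ScorePanel` as a data frame (one row per subject)."""
    rows = []
    for r in records:
        panel: ScorePanel = compute_score_panel(r, config)
        rows.append(
            {
                "patient_id": r.patient_id,
                "gapp_score": panel.gapp_score,
                "gapp_class": panel.gapp_class.value,
                "pass_score": panel.pass_score,
                "pass_high": panel.pass_high,
                "mgapp_score": panel.mgapp_score,
                "mgapp_high": panel.mgapp_high,
                "catecholamine_type": panel.catecholamine_type.value,
                "metastasis": r.metastasis,
                "mfs_time_months": r.mfs_time_months,
                "time_to_metastasis_months": r.time_to_metastasis_months,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Every output table of the validation run, plus run metadata."""

    baseline: pd.DataFrame
    cox_tables: dict[str, pd.DataFrame]
    score_table: pd.DataFrame
    contingency_table: pd.DataFrame
    roc_table: pd.DataFrame
    mfs_curves: pd.DataFrame
    logrank_table: pd.DataFrame
    correlation_table: pd.DataFrame
    metadata: dict
    skipped: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        """Emit every table as a delimited text file under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        for name, table in self.cox_tables.items():
            table.to_csv(out / f"cox_{name}.csv", index=False)
        self.score_table.to_csv(out / "score_comparison.csv", index=False)
        self.contingency_table.to_csv(out / "classification_contingency.csv", index=False)
        self.roc_table.to_csv(out / "roc_comparison.csv", index=False)
        self.mfs_curves.to_csv(out / "mfs_curves.csv", index=False)
        self.logrank_table.to_csv(out / "mfs_logrank.csv", index=False)
        self.correlation_table.to_csv(out / "score_mfs_correlation.csv", index=False)
        meta = dict(self.metadata)
        meta["skipped_stages"] = list(self.skipped)
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def _median_iqr(x: np.ndarray) -> str:
    return f"{np.median(x):.1f} [{np.percentile(x, 25):.1f}, {np.percentile(x, 75):.1f}]"


def _baseline_table(records, scores: pd.DataFrame) -> pd.DataFrame:
    met = scores["metastasis"].to_numpy(dtype=bool)
    rows = []

    def add_continuous(name, values):
        values = np.asarray([np.nan if v is None else v for v in values], dtype=float)
        ok = ~np.isnan(values)
        a, b = values[ok & ~met[: len(values)]], values[ok & met[: len(values)]]
        if a.size < 2 or b.size < 2:
            return
        stat, p = vs.compare_groups(a, b, method="t_test")
        rows.append(
            {
                "variable": name,
                "non_metastatic": f"{a.mean():.1f}±{a.std(ddof=1):.1f}",
                "metastatic": f"{b.mean():.1f}±{b.std(ddof=1):.1f}",
                "test": "t",
                "p": p,
            }
        )

    def add_binary(name, flags):
        flags = np.asarray(flags, dtype=bool)
        # rows: outcome group; cols: flag present / absent
        table = np.array(
            [
                [int((~met & flags).sum()), int((~met & ~flags).sum())],
                [int((met & flags).sum()), int((met & ~flags).sum())],
            ]
        )
        try:
            _, p = vs.contingency_test(table, method="auto")
        except PPGLError:
            p = np.nan
        def cell(mask):
            k = int((mask & flags).sum())
            pct = 100.0 * k / mask.sum() if mask.any() else float("nan")
            return f"{k} ({pct:.1f}%)"

        rows.append(
            {
                "variable": name,
                "non_metastatic": cell(~met),
                "metastatic": cell(met),
                "test": "chi2/fisher",
                "p": p,
            }
        )

    add_continuous("age_years", [r.age_years for r in records])
    add_continuous("height_cm", [r.height_cm for r in records])
    add_continuous("weight_kg", [r.weight_kg for r in records])
    add_continuous("bmi", [r.bmi for r in records])
    add_continuous("tumor_size_cm", [r.tumor_size_cm for r in records])
    add_continuous("followup_months", [r.followup_months for r in records])
    add_binary("female", [r.sex is Sex.FEMALE for r in records])
    add_binary("pgl_site", [r.tumor_site is TumorSite.PGL for r in records])
    add_binary("familial", [bool(r.familial) for r in records])
    add_binary(
        "functioning",
        [
            bool(r.biochemistry.umn_elevated or r.biochemistry.unm_elevated)
            for r in records
        ],
    )
    add_binary(
        "noradrenergic",
        (scores["catecholamine_type"] == "noradrenergic").tolist(),
    )
    add_binary(
        "sdhb_loss", [not r.histology.sdhb_ihc_positive for r in records]
    )
    return pd.DataFrame(rows)


def _gapp_design(records, scores) -> dict[str, np.ndarray]:
    """GAPP parameters as binary regressors (reference levels dropped)."""
    h = [r.histology for r in records]
    return {
        "pattern_nest_or_pseudorosette": np.array(
            [bool(x.large_irregular_nest or x.pseudorosette) for x in h], dtype=float
        ),
        "comedo_necrosis": np.array([bool(x.comedo_necrosis) for x in h], dtype=float),
        "cellularity_moderate": np.array(
            [x.cellularity_class is Cellularity.MODERATE for x in h], dtype=float
        ),
        "cellularity_high": np.array(
            [x.cellularity_class is Cellularity.HIGH for x in h], dtype=float
        ),
        "ki67_1_to_3": np.array([1 <= x.ki67_percent <= 3 for x in h], dtype=float),
        "ki67_gt_3": np.array([x.ki67_percent > 3 for x in h], dtype=float),
        "vascular_or_capsular_invasion": np.array(
            [bool(x.vascular_invasion or x.capsular_invasion) for x in h], dtype=float
        ),
        "noradrenergic_type": (scores["catecholamine_type"] == "noradrenergic")
        .to_numpy()
        .astype(float),
    }


def _mgapp_design(records, scores) -> dict[str, np.ndarray]:
    cols = {p: [] for p in gc.MGAPP_PARAMETERS}
    for r, ctype in zip(records, scores["catecholamine_type"]):
        flags = gc.mgapp_parameter_flags(
            r.histology, gc.CatecholamineType(ctype)
        )
        for p in gc.MGAPP_PARAMETERS:
            cols[p].append(float(flags[p]))
    return {p: np.asarray(v) for p, v in cols.items()}


def _pass_design(records) -> dict[str, np.ndarray]:
    return {
        item: np.array(
            [bool(r.histology.pass_features[item]) for r in records], dtype=float
        )
        for item in gc.PASS_ITEMS
    }


# multi-level GAPP parameters whose dummies enter univariate fits jointly
_GAPP_DUMMY_GROUPS = (
    ("cellularity_moderate", "cellularity_high"),
    ("ki67_1_to_3", "ki67_gt_3"),
)


def _cox_table(design: dict[str, np.ndarray], times, events, ties: str) -> pd.DataFrame:
    grouped: list[tuple[str, ...]] = []
    used = set()
    for group in _GAPP_DUMMY_GROUPS:
        if all(g in design for g in group):
            grouped.append(group)
            used.update(group)
    for name in design:
        if name not in used:
            grouped.append((name,))

    rows = []
    for group in grouped:
        x = np.column_stack([design[g] for g in group])
        try:
            res = vs.fit_cox(times, events, x, names=group, ties=ties)
            for name in group:
                rows.append({"mode": "univariate", **res.summary_row(name)})
        except (DomainError, ConvergenceError) as exc:
            for name in group:
                rows.append(
                    {"mode": "univariate", "covariate": name, "note": str(exc)}
                )
    all_names = tuple(design)
    x = np.column_stack([design[n] for n in all_names])
    try:
        res = vs.fit_cox(times, events, x, names=all_names, ties=ties)
        for name in all_names:
            rows.append({"mode": "multivariate", **res.summary_row(name)})
    except (DomainError, ConvergenceError) as exc:
        rows.append({"mode": "multivariate", "covariate": "(all)", "note": str(exc)})
    return pd.DataFrame(rows)


def run_validation(
    records: Sequence[PatientRecord],
    config: ScoringConfig = gc.DEFAULT_CONFIG,
    ties: str = "breslow",
) -> ValidationReport:
    """Score every subject and compute the full validation report.

    Deterministic given (records, config).  Stages whose preconditions are
    not met — e.g. fewer than two subjects per outcome class for the ROC
    and Cox stages — are skipped, with the reason recorded in
    ``report.skipped``.
    """
    if len(records) == 0:
        raise DomainError("cannot validate an empty cohort")
    scores = scores_frame(records, config)
    met = scores["metastasis"].to_numpy(dtype=bool)
    times = scores["mfs_time_months"].to_numpy(dtype=float)
    skipped: list[str] = []
    two_class = 2 <= met.sum() <= len(records) - 2

    logger.info("scoring %d subjects (%d metastatic)", len(records), int(met.sum()))
    baseline = _baseline_table(records, scores)

    empty = pd.DataFrame()
    cox_tables: dict[str, pd.DataFrame] = {}
    score_rows, cont_rows, roc_rows, corr_rows, lr_rows, curve_rows = [], [], [], [], [], []

    if two_class:
        for system, design in (
            ("gapp", _gapp_design(records, scores)),
            ("pass", _pass_design(records)),
            ("mgapp", _mgapp_design(records, scores)),
        ):
            cox_tables[system] = _cox_table(design, times, met, ties)
    else:
        skipped.append("cox: need >= 2 subjects in each outcome class")

    systems = (
        ("gapp", scores["gapp_score"]),
        ("pass", scores["pass_score"]),
        ("mgapp", scores["mgapp_score"]),
    )
    for name, s in systems:
        s = s.to_numpy(dtype=float)
        if two_class:
            stat, p = vs.compare_groups(s[~met], s[met], method="mann_whitney")
            score_rows.append(
                {
                    "score": name,
                    "non_metastatic_median_iqr": _median_iqr(s[~met]),
                    "metastatic_median_iqr": _median_iqr(s[met]),
                    "mann_whitney_U": stat,
                    "p": p,
                }
            )
        else:
            skipped.append(f"score comparison ({name}): single outcome class")

    # classification contingencies (GAPP class, PASS >= 4, M-GAPP >= cutoff)
    class_specs = [
        (
            "gapp_class",
            scores["gapp_class"],
            [c.value for c in (GappClass.WD, GappClass.MD, GappClass.PD)],
        ),
        ("pass_high", scores["pass_high"].map({False: "PASS<4", True: "PASS>=4"}),
         ["PASS<4", "PASS>=4"]),
        (
            "mgapp_high",
            scores["mgapp_high"].map(
                {False: f"M-GAPP<{config.mgapp_cutoff}", True: f"M-GAPP>={config.mgapp_cutoff}"}
            ),
            [f"M-GAPP<{config.mgapp_cutoff}", f"M-GAPP>={config.mgapp_cutoff}"],
        ),
    ]
    for name, labels, level_order in class_specs:
        counts = []
        present_levels = [lv for lv in level_order if (labels == lv).any()]
        for lv in present_levels:
            mask = (labels == lv).to_numpy()
            counts.append([int((mask & ~met).sum()), int((mask & met).sum())])
        table = np.asarray(counts)
        p = np.nan
        if table.shape[0] >= 2 and two_class:
            try:
                _, p = vs.contingency_test(table, method="auto")
            except PPGLError as exc:
                skipped.append(f"contingency ({name}): {exc}")
        for lv, (n_non, n_met) in zip(present_levels, counts):
            total = n_non + n_met
            cont_rows.append(
                {
                    "system": name,
                    "class": lv,
                    "n": total,
                    "non_metastatic": n_non,
                    "metastatic": n_met,
                    "metastatic_pct": 100.0 * n_met / total if total else np.nan,
                    "p": p,
                }
            )

    if two_class:
        rocs = {name: vs.roc_auc(s.to_numpy(dtype=float), met.astype(int)) for name, s in systems}
        for name, _ in systems:
            roc = rocs[name]
            row = {
                "score": name,
                "auc": roc.auc,
                "ci_low": roc.auc_ci[0],
                "ci_high": roc.auc_ci[1],
            }
            for ref in ("gapp", "pass"):
                if name == ref:
                    row[f"improvement_vs_{ref}"] = np.nan
                    row[f"p_vs_{ref}"] = np.nan
                else:
                    _, _, diff, p = vs.delong_compare(
                        scores[f"{name}_score"].to_numpy(dtype=float),
                        scores[f"{ref}_score"].to_numpy(dtype=float),
                        met.astype(int),
                    )
                    row[f"improvement_vs_{ref}"] = diff
                    row[f"p_vs_{ref}"] = p
            roc_rows.append(row)
    else:
        skipped.append("roc: need both outcome classes")

    # MFS: KM curves per classification group + log-rank
    group_specs = [
        ("gapp_class", scores["gapp_class"]),
        ("pass_high", class_specs[1][1]),
        ("mgapp_high", class_specs[2][1]),
    ]
    for name, labels in group_specs:
        groups, level_names = [], []
        for lv in labels.unique():
            mask = (labels == lv).to_numpy()
            groups.append((times[mask], met[mask]))
            level_names.append(lv)
        for lv, (t, e) in zip(level_names, groups):
            try:
                curve = vs.km_estimate(t, e)
            except DomainError as exc:
                skipped.append(f"km ({name}={lv}): {exc}")
                continue
            for ti, si, ni in zip(curve.times, curve.survival, curve.at_risk):
                curve_rows.append(
                    {"system": name, "group": lv, "time_months": ti,
                     "survival": si, "at_risk": int(ni)}
                )
        if len(groups) >= 2 and met.sum() >= 1:
            try:
                stat, p = vs.log_rank(groups)
                lr_rows.append({"system": name, "chi2": stat, "df": len(groups) - 1, "p": p})
            except DomainError as exc:
                skipped.append(f"log-rank ({name}): {exc}")
        else:
            skipped.append(f"log-rank ({name}): fewer than 2 groups or no events")

    # score vs time-to-metastasis correlation among metastatic subjects
    event_times = scores.loc[met, "time_to_metastasis_months"].to_numpy(dtype=float)
    for name, s in systems:
        sm = s.to_numpy(dtype=float)[met]
        try:
            r, p = vs.pearson_mfs_corr(sm, event_times)
            corr_rows.append({"score": name, "pearson_r": r, "p": p})
        except DomainError as exc:
            skipped.append(f"correlation ({name}): {exc}")

    try:
        pkg_version = _pkg_version("ppgl-grading")
    except PackageNotFoundError:
        pkg_version = "unknown"
    metadata = {
        "n_subjects": len(records),
        "n_metastatic": int(met.sum()),
        "ties": ties,
        "software_version": pkg_version,
        "gapp_weights": dict(config.gapp_weights),
        "pass_weights": dict(config.pass_weights),
        "mgapp_weights": dict(config.mgapp_weights),
        "thresholds": {
            "pass_cutoff": config.pass_cutoff,
            "mgapp_cutoff": config.mgapp_cutoff,
            "gapp_bands": [config.gapp_wd_max, config.gapp_md_max, config.gapp_max],
            "timing_cutoff_months": config.timing_cutoff_months,
        },
    }
    for reason in skipped:
        logger.info("skipped stage: %s", reason)
    return ValidationReport(
        baseline=baseline,
        cox_tables=cox_tables,
        score_table=pd.DataFrame(score_rows) if score_rows else empty,
        contingency_table=pd.DataFrame(cont_rows) if cont_rows else empty,
        roc_table=pd.DataFrame(roc_rows) if roc_rows else empty,
        mfs_curves=pd.DataFrame(curve_rows) if curve_rows else empty,
        logrank_table=pd.DataFrame(lr_rows) if lr_rows else empty,
        correlation_table=pd.DataFrame(corr_rows) if corr_rows else empty,
        metadata=metadata,
        skipped=skipped,
    )
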