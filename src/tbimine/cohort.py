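"""Analysis-ready matched cohort: index dates, phases, code matrices, labels, splits.

Conventions (all configurable where noted):

* Case index date = date of the earliest visit bearing an index-event
  (TBI) diagnosis code; ties on the same date break on visit order in the
  input after a stable sort.
* Reference index date = date of the rank-midpoint visit; for an even
  visit count the earlier of the two middle visits is used.
* Event window = ``[index - 30 d, index + 30 d]`` inclusive on both sides,
  i.e. 61 calendar days.
* Pre-injury phase = ``[index - 5 y, index - 31 d]`` inclusive (calendar
  year arithmetic).  Everything else is ``excluded``.
* Binary code matrices use 3-character truncation (one alphabetic + two
  numeric characters) and drop the provisional codes U98 and U99.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .synthetic_data import TBI_CODES

__all__ = [
    "assign_index_dates",
    "assign_phases",
    "build_code_matrix",
    "split_cohort",
    "load_mapping",
    "label_severity_and_cause",
    "EXCLUDED_CODES",
]

#: Provisional ICD-10 codes for research / temporary assignment, never analysed.
EXCLUDED_CODES = ("U98", "U99")

_CODE3_RE = re.compile(r"^[A-Z][0-9]{2}$")


def _split_codes(codes: pd.Series) -> pd.Series:
    """Semicolon-joined code strings -> exploded Series of single codes."""
    return codes.fillna("").str.split(";").explode().str.strip()


def assign_index_dates(
    visits: pd.DataFrame, tbi_code_set: tuple[str, ...] = TBI_CODES
) -> pd.DataFrame:
    """Per-patient index dates.

    Cases anchor on their first index-event-coded visit; references on the
    rank midpoint of their visit stream (earlier middle visit for even
    counts).  Returns one row per patient with the matching covariates
    carried along.

    Raises ``ValueError`` for a case without any index-event code or a
    patient without visits.
    """
    visits = visits.sort_values(["patient_id", "visit_date"], kind="stable").reset_index(
        drop=True
    )
    grp = visits.groupby("patient_id", sort=True)
    out = grp[["pair_id", "role", "sex", "age_band", "rural", "income_q"]].first()

    # references: earlier of the two middle visits when the count is even
    n = grp.size()
    rank = grp.cumcount()
    mid_of_patient = visits["patient_id"].map((n - 1) // 2)
    mid_dates = (
        visits[rank == mid_of_patient].set_index("patient_id")["visit_date"]
    )

    # cases: earliest visit carrying an index-event code (prefix match)
    pattern = "(?:^|;)(?:" + "|".join(re.escape(c) for c in tbi_code_set) + ")"
    is_tbi = visits["codes"].str.contains(pattern, regex=True, na=False)
    tbi_dates = (
        visits[is_tbi].groupby("patient_id", sort=True)["visit_date"].first()
    )

    is_case = out["role"] == "case"
    missing = set(out.index[is_case]) - set(tbi_dates.index)
    if missing:
        raise ValueError(
            f"case(s) with no visit bearing an index-event code: {sorted(missing)[:5]}"
        )
    out["index_date"] = mid_dates.reindex(out.index)
    out.loc[is_case, "index_date"] = tbi_dates.reindex(out.index[is_case])
    return out.reset_index()


def assign_phases(
    visits: pd.DataFrame,
    index_dates: pd.DataFrame,
    event_halfwidth_days: int = 30,
    preinjury_years: int = 5,
) -> pd.DataFrame:
    """Tag each visit with its phase relative to the patient's index date.

    The event window spans ``2 * event_halfwidth_days + 1`` calendar days
    (61 by default); the pre-injury phase runs from ``preinjury_years``
    calendar years before the index date up to the day before the window
    opens.  Visits outside both are ``excluded``.
    """
    idx = index_dates.set_index("patient_id")["index_date"]
    out = visits.copy()
    vidx = out["patient_id"].map(idx)
    if vidx.isna().any():
        missing = out.loc[vidx.isna(), "patient_id"].unique()[:5]
        raise ValueError(f"visits for patients without an index date, e.g. {list(missing)}")
    halfw = pd.Timedelta(days=event_halfwidth_days)
    delta = out["visit_date"] - vidx
    in_event = delta.abs() <= halfw
    pre_start = vidx - pd.DateOffset(years=preinjury_years)
    in_pre = (out["visit_date"] >= pre_start) & (delta <= -pd.Timedelta(days=event_halfwidth_days + 1))
    out["phase"] = np.select([in_event, in_pre], ["event_window", "pre_injury"], "excluded")
    return out


def build_code_matrix(
    visits: pd.DataFrame, phase: str, patients: list[str] | None = None
) -> pd.DataFrame:
    """Patients x 3-character-codes presence/absence matrix for one phase.

    Codes are truncated to their first three characters; anything not
    matching one alphabetic + two numeric characters is skipped with a
    warning, and U98/U99 are dropped.  Columns are sorted lexicographically.
    ``patients`` fixes the row axis (patients with no qualifying visit get
    all-zero rows); by default rows are all patients present in ``visits``.
    """
    if patients is None:
        patients = sorted(visits["patient_id"].unique())
    sub = visits.loc[visits["phase"] == phase, ["patient_id", "codes"]]
    exploded = (
        _split_codes(sub.set_index("patient_id")["codes"])
        .rename("code")
        .reset_index()
    )
    exploded = exploded.dropna()
    exploded = exploded[exploded["code"] != ""]
    exploded["code"] = exploded["code"].str.upper().str[:3]
    bad = ~exploded["code"].str.match(_CODE3_RE)
    if bad.any():
        warnings.warn(
            f"skipping {int(bad.sum())} malformed code entries "
            f"(e.g. {sorted(exploded.loc[bad, 'code'].unique())[:5]})",
            stacklevel=2,
        )
        exploded = exploded[~bad]
    exploded = exploded[~exploded["code"].isin(EXCLUDED_CODES)]
    present = exploded.drop_duplicates()
    mat = (
        pd.crosstab(present["patient_id"], present["code"])
        .clip(upper=1)
        .astype(np.int8)
    )
    mat = mat.reindex(index=patients, columns=sorted(mat.columns), fill_value=0)
    mat.index.name = "patient_id"
    mat.columns.name = "code"
    return mat


def split_cohort(
    pair_ids, fractions: tuple[float, float, float] = (0.5, 0.25, 0.25), seed: int = 0
) -> pd.Series:
    """Random train/validation/test assignment at the pair level.

    Pairs are the unit of splitting, so a case and its matched reference
    always share a label.  Deterministic for a fixed seed; split sizes are
    the rounded cumulative fractions (within one pair of exact).
    """
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    pairs = np.asarray(sorted(set(pair_ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    cuts = np.round(np.cumsum(fractions) * len(pairs)).astype(int)
    labels = np.empty(len(pairs), dtype=object)
    names = ["train", "validation", "test"]
    start = 0
    for name, stop in zip(names, cuts):
        labels[perm[start:stop]] = name
        start = stop
    return pd.Series(labels, index=pairs, name="split")


def load_mapping(path) -> pd.DataFrame:
    """Load a (pattern, category, priority) mapping table from CSV.

    Patterns are matched as code prefixes on dotless codes.  Contradictory
    duplicate patterns (same pattern, different category) are a hard error.
    """
    table = pd.read_csv(path, dtype={"pattern": str, "category": str})
    if "priority" not in table.columns:
        table["priority"] = np.arange(len(table))
    dup = table.groupby("pattern")["category"].nunique()
    bad = dup[dup > 1]
    if len(bad):
        raise ValueError(f"contradictory mapping rules for patterns {list(bad.index)}")
    return table.sort_values(["priority", "pattern"], kind="stable").reset_index(drop=True)


def label_severity_and_cause(
    visits: pd.DataFrame,
    severity_map: pd.DataFrame,
    cause_map: pd.DataFrame,
) -> pd.DataFrame:
    """Severity category and cause indicators for each case.

    Severity comes from the first (priority-ordered) severity rule whose
    pattern prefix-matches any event-window code, defaulting to
    ``unspecified``.  Causes are non-exclusive: each cause category's
    indicator is set when any of its patterns matches an event-window code;
    a case matching no cause rule gets ``missing = 1``.
    """
    cases = visits[(visits["role"] == "case") & (visits["phase"] == "event_window")]
    codes_by_patient = (
        _split_codes(cases.set_index("patient_id")["codes"])
        .rename("code")
        .groupby(level=0)
        .agg(lambda s: tuple(sorted(set(s) - {""})))
    )
    all_cases = sorted(visits.loc[visits["role"] == "case", "patient_id"].unique())
    codes_by_patient = codes_by_patient.reindex(all_cases, fill_value=())

    sev_rules = list(severity_map[["pattern", "category"]].itertuples(index=False))
    cause_cats = list(dict.fromkeys(cause_map["category"]))
    cause_patterns = {
        cat: tuple(cause_map.loc[cause_map["category"] == cat, "pattern"])
        for cat in cause_cats
    }

    rows = []
    for pid, codes in codes_by_patient.items():
        severity = "unspecified"
        for pattern, category in sev_rules:
            if any(c.startswith(pattern) for c in codes):
                severity = category
                break
        row = {"patient_id": pid, "severity": severity}
        any_cause = False
        for cat in cause_cats:
            hit = int(any(c.startswith(cause_patterns[cat]) for c in codes))
            row[cat] = hit
            any_cause = any_cause or bool(hit)
        row["missing"] = int(not any_cause)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
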