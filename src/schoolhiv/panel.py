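"""Discrete-time-hazard panel construction from HIV test histories.

Turns per-person test histories (neg/pos by calendar year) into one row per
woman per at-risk year, applying the incidence coding rules for missing
test years and the sample restrictions (ages 15-24, secondary school not
completed, previously HIV-negative).  A woman contributes estimation rows
only from the year after her first negative test: incidence is a hazard,
i.e. a probability conditional on being previously negative, so the
entry test itself establishes at-risk status without being an observation.

Coding schemes for a positive test that follows a testing gap:

* ``main``          - the first positive year is coded 1; the gap years
                      between the last negative and the first positive are
                      coded missing.
* ``strict``        - additionally codes the first positive year missing
                      when there is no negative test the year before.
* ``drop_uncertain``- removes the woman entirely when her infection year
                      is uncertain.

Negative tests after a gap are coded 0, and so are the gap years they
retroactively cover (she was still negative when later tested negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, InvalidParameterError, MalformedHistoryError

__all__ = [
    "CODING_SCHEMES",
    "MISSING",
    "code_incidence",
    "build_panel",
    "panel_from_cohort",
    "apply_restrictions",
    "build_design",
    "DesignMatrices",
    "prune_separated",
]

CODING_SCHEMES = ("main", "strict", "drop_uncertain")
MISSING = -1  # sentinel for "incidence missing" in integer columns
REFERENCE_AGE = 16


def code_incidence(history, scheme: str = "main"):
    """Code one woman's annual incidence sequence from her test history.

    ``history`` is an iterable of (year, result) with result in {"neg","pos"},
    sorted by year.  Returns a dict {year: 0 | 1 | None} (None = missing),
    or None when the scheme is ``drop_uncertain`` and the infection year is
    uncertain.  Years after the first positive are absent.
    """
    if scheme not in CODING_SCHEMES:
        raise InvalidParameterError(f"unknown coding scheme: {scheme!r}")
    years, results = [], []
    for year, result in history:
        if result not in ("neg", "pos"):
            raise MalformedHistoryError(f"unknown test result {result!r}")
        years.append(int(year))
        results.append(result)
    if years != sorted(years) or len(set(years)) != len(years):
        raise MalformedHistoryError("history must be sorted with one test per year")

    neg_years = [t for t, r in zip(years, results) if r == "neg"]
    pos_years = [t for t, r in zip(years, results) if r == "pos"]
    first_pos = min(pos_years) if pos_years else None
    if first_pos is not None and any(t > first_pos for t in neg_years):
        raise MalformedHistoryError("negative test after a positive test")
    if not neg_years:
        return {}  # never observed at risk
    entry, last_neg = neg_years[0], neg_years[-1]

    out: dict[int, int | None] = {}
    for t in range(entry + 1, last_neg + 1):
        out[t] = 0  # covered by a later negative test, gaps included
    if first_pos is not None:
        gap = first_pos - last_neg - 1
        if scheme == "drop_uncertain" and gap > 0:
            return None
        for t in range(last_neg + 1, first_pos):
            out[t] = None
        if scheme == "strict" and gap > 0:
            out[first_pos] = None
        else:
            out[first_pos] = 1
    return out


def _code_all(tests: pd.DataFrame, scheme: str) -> tuple[pd.DataFrame, int]:
    rows = []
    n_dropped_persons = 0
    for pid, grp in tests.sort_values("year").groupby("person_id"):
        coded = code_incidence(zip(grp["year"], grp["result"]), scheme)
        if coded is None:
            n_dropped_persons += 1
            continue
        for year, val in coded.items():
            rows.append((pid, year, MISSING if val is None else val))
    coded_df = pd.DataFrame(rows, columns=["person_id", "year", "incidence"])
    return coded_df, n_dropped_persons


def build_panel(tests: pd.DataFrame, covariates: pd.DataFrame,
                scheme: str = "main", *, education: pd.DataFrame | None = None,
                part_time_counts: bool = False):
    """Join coded incidence with person-year covariates and apply restrictions.

    ``covariates`` needs columns person_id, household_id, year, age,
    attendance, geography, dist_primary_road, dist_secondary_road,
    dist_school, school_gap.  Attendance may be 0/1 or the strings
    none/part/full; under the primary measure part-time maps to 0
    (full-time attendance), flipped by ``part_time_counts``.

    Returns (panel DataFrame, exclusion-log dict).
    """
    coded, dropped_persons = _code_all(tests, scheme)
    log = {"persons_dropped_uncertain": dropped_persons}
    if coded.empty:
        return coded.assign(**{c: [] for c in covariates.columns if c != "person_id"}), log

    cov = covariates.copy()
    if cov["attendance"].dtype == object:
        mapping = {"none": 0, "part": 1 if part_time_counts else 0, "full": 1}
        bad = set(cov["attendance"]) - set(mapping)
        if bad:
            raise InvalidParameterError(f"unknown attendance codes: {sorted(bad)}")
        cov["attendance"] = cov["attendance"].map(mapping)
    merged = coded.merge(cov, on=["person_id", "year"], how="left")
    log["rows_missing_covariates"] = int(merged["household_id"].isna().sum())
    merged = merged.dropna(subset=["household_id", "age", "attendance"])
    merged["age"] = merged["age"].astype(int)
    return apply_restrictions(merged, education=education, log=log)


def panel_from_cohort(cohort, scheme: str = "main", **kwargs):
    """Estimation panel straight from a generated cohort."""
    return build_panel(cohort.observed_tests, cohort.covariate_frame(), scheme,
                       education=cohort.education_frame(), **kwargs)


def apply_restrictions(rows: pd.DataFrame, education: pd.DataFrame | None = None,
                       *, log: dict | None = None):
    """Retain ages 15-24, secondary not completed, certain incidence.

    ``education`` (optional) has columns person_id, completion_year; rows
    from the completion year onward are dropped.  If the rows carry a
    ``completion_year`` column already it is used directly.  Rows with
    missing incidence are removed from the estimation panel but counted in
    the exclusion log.
    """
    log = dict(log or {})
    keep = rows.copy()
    in_age = keep["age"].between(15, 24)
    log["rows_age_out_of_range"] = int((~in_age).sum())
    keep = keep[in_age]

    if education is not None:
        keep = keep.merge(education[["person_id", "completion_year"]],
                          on="person_id", how="left")
    if "completion_year" in keep.columns:
        done = keep["completion_year"].notna() & (keep["year"] >= keep["completion_year"])
        log["rows_after_secondary_completion"] = int(done.sum())
        keep = keep[~done]
    else:
        log["rows_after_secondary_completion"] = 0

    miss = keep["incidence"] == MISSING
    log["rows_uncertain_incidence"] = int(miss.sum())
    keep = keep[~miss]

    # safety: nothing after a person's event year (coding already ensures it)
    event_year = keep.loc[keep["incidence"] == 1].groupby("person_id")["year"].min()
    cut = keep["person_id"].map(event_year)
    keep = keep[cut.isna() | (keep["year"] <= cut)]

    keep = keep.sort_values(["person_id", "year"]).reset_index(drop=True)
    if keep.duplicated(["person_id", "year"]).any():
        raise MalformedHistoryError("duplicate (person, year) rows")
    log["rows_retained"] = int(len(keep))
    return keep, log


@dataclass
class DesignMatrices:
    """Estimation arrays for the hazard models."""

    y: np.ndarray
    s: np.ndarray
    X: np.ndarray
    x_names: list[str]
    Z: np.ndarray | None
    z_names: list[str]
    cluster_ids: np.ndarray
    person_ids: np.ndarray
    notes: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)


def build_design(panel: pd.DataFrame, include_instruments: bool = True) -> DesignMatrices:
    """Build y, s, controls X, optional instruments Z and cluster ids.

    X: constant; age dummies (reference 16); year dummies (reference =
    earliest year); urban and peri-urban dummies (reference rural); the two
    road distances.  Z: the <7 km school-proximity dummy and the
    nearest/second-nearest school gap.  Degenerate categories are dropped
    with a note rather than an error; genuine rank deficiency raises,
    naming the columns involved.
    """
    notes: list[str] = []
    panel = panel.reset_index(drop=True)
    y = panel["incidence"].to_numpy(dtype=float)
    s = panel["attendance"].to_numpy(dtype=float)

    cols = [np.ones(len(panel))]
    names = ["const"]
    ages = sorted(panel["age"].unique())
    ref_age = REFERENCE_AGE if REFERENCE_AGE in ages else ages[0]
    if ref_age != REFERENCE_AGE:
        notes.append(f"reference age {REFERENCE_AGE} absent; using {ref_age}")
    for a in ages:
        if a != ref_age:
            cols.append((panel["age"] == a).to_numpy(dtype=float))
            names.append(f"age_{a}")
    years = sorted(panel["year"].unique())
    for t in years[1:]:
        cols.append((panel["year"] == t).to_numpy(dtype=float))
        names.append(f"year_{t}")
    for g in ("urban", "peri_urban"):
        col = (panel["geography"] == g).to_numpy(dtype=float)
        if col.sum() == 0:
            notes.append(f"geography category {g!r} empty; dummy dropped")
            continue
        cols.append(col)
        names.append(g)
    for c in ("dist_primary_road", "dist_secondary_road"):
        cols.append(panel[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(_collinear_names(X, names))

    Z, z_names = None, []
    if include_instruments:
        Z = np.column_stack([
            (panel["dist_school"] < 7.0).to_numpy(dtype=float),
            panel["school_gap"].to_numpy(dtype=float),
        ])
        z_names = ["school_lt7km", "school_gap"]
        degenerate = [nm for nm, col in zip(z_names, Z.T) if np.ptp(col) == 0]
        if degenerate:
            keepz = [j for j, nm in enumerate(z_names) if nm not in degenerate]
            notes.append(f"constant instrument(s) dropped: {degenerate}")
            Z = Z[:, keepz]
            z_names = [z_names[j] for j in keepz]

    return DesignMatrices(
        y=y, s=s, X=X, x_names=names, Z=Z, z_names=z_names,
        cluster_ids=panel["household_id"].to_numpy(),
        person_ids=panel["person_id"].to_numpy(),
        notes=notes,
    )


def _collinear_names(X, names) -> str:
    offenders = []
    full = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full:
            offenders.append(names[j])
    return "rank-deficient design; involved columns: " + ", ".join(offenders)


def prune_separated(design: DesignMatrices) -> tuple[DesignMatrices, dict]:
    """Drop dummies that perfectly predict the outcome, and their rows.

    A full age-dummy set with an age cell containing no events (the
    youngest ages typically have none) makes those cells perfectly
    predicted; the offending dummy and its rows are removed from the
    likelihood, and the counts reported, mirroring what standard probit
    fitters do by default.  Only exact separation triggers removal.
    """
    from .probit import detect_separation

    y, X, names = design.y, design.X, list(design.x_names)
    dropped: dict[str, int] = {}
    while True:
        bad = detect_separation(y, X, names)
        if not bad:
            break
        name = bad[0]
        j = names.index(name)
        rows = X[:, j] == 1.0
        dropped[name] = int(rows.sum())
        keep = ~rows
        y = y[keep]
        X = np.delete(X[keep], j, axis=1)
        names.pop(j)
        design = DesignMatrices(
            y=y, s=design.s[keep], X=X, x_names=names,
            Z=None if design.Z is None else design.Z[keep],
            z_names=design.z_names,
            cluster_ids=design.cluster_ids[keep],
            person_ids=design.person_ids[keep],
            notes=design.notes + [f"separation: dropped {name} ({dropped[name]} rows)"],
        )
        y, X = design.y, design.X
    return design, dropped
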