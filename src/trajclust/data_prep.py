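"""Derivation of model inputs from raw longitudinal cohort tables.

This module turns raw per-visit cognitive scores and per-subject baseline
measurements into the variables the two modelling stages consume:

* outcome transformations — a logistic transform of the Clinical Dementia
  Rating Sum of Boxes (CDRSB, 0–18 in 0.5 steps) that removes floor/ceiling
  effects, and a curvilinearity-correcting normalisation of the Mini-Mental
  State Examination (MMSE, 0–30) onto a 0–100 scale;
* dichotomisation of radiological reads (medial temporal lobe atrophy,
  Fazekas deep/periventricular, five regional age-related white-matter-change
  scores) and of the CSF pTau/Abeta42 ratio into binary pathology flags;
* annualised change in head-size-adjusted hippocampal and ventricular
  volumes between baseline and the last observed scan;
* eligibility filtering (>= 2 visits; optionally non-missing APOE e4) with a
  per-rule removal log;
* cohort summary tables (counts and percentages among non-missing values)
  and standardisation of continuous covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "FilterLog",
    "PTAU_ABETA_CUTOFF",
    "transform_cdrsb",
    "inverse_transform_cdrsb",
    "load_mmse_lookup",
    "linear_mmse_lookup",
    "normalise_mmse",
    "inverse_normalise_mmse",
    "annualised_change",
    "dichotomise_radiology",
    "filter_eligible",
    "summarise_cohort",
    "standardise",
    "derive_profiles",
]

#: CSF AD-positivity cut-off on the pTau/Abeta42 ratio.
PTAU_ABETA_CUTOFF = 0.024

ARWMC_COLUMNS = ["arwmc_bg", "arwmc_f", "arwmc_it", "arwmc_po", "arwmc_t"]

SUBJECT_COLUMNS = [
    "subject_id", "age", "sex", "education_level", "family_history",
    "apoe4", "cdr_global", "ptau_abeta", "mta_avg", "fsd", "fspv",
    *ARWMC_COLUMNS,
    "hv_baseline", "vv_baseline", "hv_last", "vv_last", "t_last_volume",
]

VISIT_COLUMNS = ["subject_id", "time_years", "cdrsb", "mmse"]


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """A longitudinal cohort: one row per subject plus long-format visits.

    ``subjects`` carries the baseline risk factors and biomarkers; ``visits``
    the repeated cognitive outcomes with time in study (years, baseline 0).
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        subj = self.subjects
        if subj["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        known = set(subj["subject_id"])
        orphan = ~self.visits["subject_id"].isin(known)
        if orphan.any():
            raise ValueError(
                f"{int(orphan.sum())} visits reference unknown subjects"
            )
        if (self.visits["time_years"] < 0).any():
            raise ValueError("negative visit times")
        # visit times strictly increasing within subject
        grp = self.visits.groupby("subject_id")["time_years"]
        if (grp.diff().dropna() <= 0).any():
            raise ValueError("visit times not strictly increasing within subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def visits_per_subject(self) -> pd.Series:
        counts = self.visits.groupby("subject_id").size()
        return counts.reindex(self.subjects["subject_id"], fill_value=0)

    @classmethod
    def from_csv(cls, subjects_path, visits_path) -> "CohortTable":
        subjects = pd.read_csv(subjects_path)
        visits = pd.read_csv(visits_path)
        visits = visits.sort_values(["subject_id", "time_years"], kind="stable")
        return cls(subjects.reset_index(drop=True), visits.reset_index(drop=True))

    def to_csv(self, subjects_path, visits_path) -> None:
        self.subjects.to_csv(subjects_path, index=False)
        self.visits.to_csv(visits_path, index=False)


@dataclass
class FilterLog:
    """Per-rule removal counts from :func:`filter_eligible`."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())


# ---------------------------------------------------------------------------
# outcome transformations
# ---------------------------------------------------------------------------

def transform_cdrsb(cdrsb):
    """Logistic transform of CDRSB: ``-log((c + 0.1) / (18 - c + 0.1))``.

    Strictly decreasing on [0, 18]; higher transformed values mean better
    functioning. The 0.1 offset keeps the endpoints finite. Accepts scalars
    or arrays; NaN propagates.
    """
    c = np.asarray(cdrsb, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((c < 0) | (c > 18)):
            raise ValueError("CDRSB must lie in [0, 18]")
    out = -np.log((c + 0.1) / (18.0 - c + 0.1))
    return out if out.ndim else float(out)


def inverse_transform_cdrsb(t):
    """Inverse of :func:`transform_cdrsb` (continuous, not grid-rounded)."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-t)
    out = (18.1 * e - 0.1) / (1.0 + e)
    return out if out.ndim else float(out)


def load_mmse_lookup() -> np.ndarray:
    """Load the shipped 31-entry MMSE normalisation table (0–30 → 0–100).

    The shipped table is a synthetic stand-in for the published normalisation
    (see the resource file's description): monotone non-decreasing, endpoints
    0 and 100, with the characteristic expansion of score differences near
    the raw-scale ceiling.
    """
    ref = _importlib_resources.files("trajclust.resources").joinpath(
        "mmse_norm_synthetic.json"
    )
    payload = json.loads(ref.read_text())
    table = np.array([payload["table"][str(m)] for m in range(31)], dtype=float)
    if np.any(np.diff(table) < 0):
        raise ValueError("MMSE lookup must be monotone non-decreasing")
    if table[0] != 0.0 or table[30] != 100.0:
        raise ValueError("MMSE lookup endpoints must be 0 and 100")
    return table


def linear_mmse_lookup() -> np.ndarray:
    """Linear-rescaling fallback: nMMSE = mmse / 30 * 100."""
    return np.arange(31, dtype=float) / 30.0 * 100.0


def normalise_mmse(mmse, lookup: np.ndarray | None = None):
    """Map raw MMSE (integer 0–30) to normalised MMSE via the lookup table.

    NaN propagates; non-integer or out-of-range values raise.
    """
    table = load_mmse_lookup() if lookup is None else np.asarray(lookup, float)
    if table.shape != (31,):
        raise ValueError("lookup must have 31 entries")
    m = np.asarray(mmse, dtype=float)
    obs = ~np.isnan(m)
    vals = m[obs] if m.ndim else (np.array([m]) if obs else np.array([]))
    if vals.size:
        if np.any((vals < 0) | (vals > 30)) or np.any(vals != np.round(vals)):
            raise ValueError("MMSE must be an integer in [0, 30]")
    out = np.full(m.shape, np.nan)
    if m.ndim:
        out[obs] = table[m[obs].astype(int)]
        return out
    return float(table[int(m)]) if obs else float("nan")


def inverse_normalise_mmse(nmmse, lookup: np.ndarray | None = None):
    """Map a normalised (0–100) value back to the nearest raw MMSE integer."""
    table = load_mmse_lookup() if lookup is None else np.asarray(lookup, float)
    v = np.atleast_1d(np.asarray(nmmse, dtype=float))
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    if obs.any():
        diffs = np.abs(v[obs, None] - table[None, :])
        out[obs] = np.argmin(diffs, axis=1)
    return out if np.ndim(nmmse) else float(out[0])


# ---------------------------------------------------------------------------
# biomarker derivations
# ---------------------------------------------------------------------------

def annualised_change(v0, v_last, dt):
    """Annualised volume change ``(v_last - v0) / dt`` in mm^3/year.

    ``dt`` must be positive where a change is computed; a missing volume
    yields a missing result.
    """
    scalar = np.ndim(v0) == 0 and np.ndim(v_last) == 0 and np.ndim(dt) == 0
    v0, v_last, dt = np.broadcast_arrays(
        np.asarray(v0, dtype=float),
        np.asarray(v_last, dtype=float),
        np.asarray(dt, dtype=float),
    )
    present = ~(np.isnan(v0) | np.isnan(v_last) | np.isnan(dt))
    if np.any(dt[present] <= 0):
        raise ValueError("time between scans must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(present, (v_last - v0) / dt, np.nan)
    return float(out[()]) if scalar else out


def dichotomise_radiology(subjects: pd.DataFrame) -> pd.DataFrame:
    """Binary pathology flags from radiological reads and the CSF ratio.

    Cut-offs: pTau/Abeta > 0.024 is "AD positive"; MTA average >= 1 positive,
    == 0.5 inconclusive, 0 negative (inconclusive collapses to 0 in the
    binary flag); Fazekas deep >= 2; Fazekas periventricular >= 1; the
    combined ARWMC count is the number of the five regions scoring >= 1,
    flagged positive when >= 3 regions show pathology. Missing inputs
    propagate to missing flags.
    """
    out = pd.DataFrame({"subject_id": subjects["subject_id"]})

    def _flag(series: pd.Series, cond) -> pd.Series:
        vals = series.astype(float)
        res = pd.Series(np.where(cond(vals), 1.0, 0.0), index=series.index)
        res[vals.isna()] = np.nan
        return res

    out["ad_positive"] = _flag(subjects["ptau_abeta"], lambda v: v > PTAU_ABETA_CUTOFF)

    mta = subjects["mta_avg"].astype(float)
    level = pd.Series(
        np.select([mta >= 1, mta == 0.5], ["positive", "inconclusive"], "negative"),
        index=mta.index, dtype=object,
    )
    level[mta.isna()] = np.nan
    out["mta_level"] = level
    out["mta_flag"] = _flag(subjects["mta_avg"], lambda v: v >= 1)

    out["fsd_flag"] = _flag(subjects["fsd"], lambda v: v >= 2)
    out["fspv_flag"] = _flag(subjects["fspv"], lambda v: v >= 1)

    arwmc = subjects[ARWMC_COLUMNS].astype(float)
    count = (arwmc >= 1).sum(axis=1).astype(float)
    count[arwmc.isna().any(axis=1)] = np.nan
    out["arwmc_count"] = count
    out["arwmc_flag"] = pd.Series(
        np.where(count >= 3, 1.0, 0.0), index=count.index
    ).where(count.notna())
    return out


def filter_eligible(
    cohort: CohortTable, require_apoe: bool = False
) -> tuple[CohortTable, FilterLog]:
    """Retain subjects with >= 2 visits (and known APOE e4 if requested).

    Returns the filtered cohort and a log of removals per rule. Idempotent:
    re-filtering a filtered cohort removes nobody.
    """
    log = FilterLog(n_input=cohort.n_subjects)
    counts = cohort.visits_per_subject()
    keep = counts.values >= 2
    log.removed["fewer_than_2_visits"] = int((~keep).sum())
    subjects = cohort.subjects.loc[keep]
    if require_apoe:
        has_apoe = subjects["apoe4"].notna()
        log.removed["missing_apoe4"] = int((~has_apoe).sum())
        subjects = subjects.loc[has_apoe]
    visits = cohort.visits[cohort.visits["subject_id"].isin(subjects["subject_id"])]
    filtered = CohortTable(
        subjects.reset_index(drop=True), visits.reset_index(drop=True)
    )
    return filtered, log


def summarise_cohort(
    values: pd.Series,
    categories: Mapping[str, Callable[[pd.Series], pd.Series]],
) -> pd.DataFrame:
    """Category counts and percentages among non-missing values.

    ``categories`` maps row labels to boolean predicates over the series.
    Percentages use the non-missing total as denominator and are rounded to
    one decimal; an ``unknown`` row carries the missing count with NaN
    percentage. With no non-missing values every percentage is NaN.
    """
    vals = values.astype(float) if values.dtype != object else values
    missing = vals.isna()
    obs = vals[~missing]
    rows = []
    n_obs = len(obs)
    for label, pred in categories.items():
        cnt = int(pred(obs).sum()) if n_obs else 0
        pct = round(100.0 * cnt / n_obs, 1) if n_obs else float("nan")
        rows.append({"category": label, "count": cnt, "percent": pct})
    assigned = sum(r["count"] for r in rows)
    if n_obs and assigned != n_obs:
        raise ValueError(
            f"categories cover {assigned} of {n_obs} non-missing values; "
            "cut rule must partition the observed range"
        )
    rows.append(
        {"category": "unknown", "count": int(missing.sum()), "percent": float("nan")}
    )
    return pd.DataFrame(rows)


def standardise(values) -> np.ndarray:
    """Centre and scale to unit sample (n−1) standard deviation.

    Computed over non-missing entries; missing entries are preserved.
    Requires >= 2 non-missing values with nonzero spread.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = np.std(x[obs], ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardise a constant vector")
    out = x.copy()
    out[obs] = (x[obs] - np.mean(x[obs])) / sd
    return out


def derive_profiles(cohort: CohortTable) -> pd.DataFrame:
    """Full per-subject derived profile for the clustering stage.

    Combines the binary pathology flags with standardised baseline volumes
    and standardised annualised volume-change rates. Standardisation is done
    on the analysis set passed in (post eligibility filtering).
    """
    subj = cohort.subjects
    out = dichotomise_radiology(subj)
    hv_rate = annualised_change(
        subj["hv_baseline"], subj["hv_last"], subj["t_last_volume"]
    )
    vv_rate = annualised_change(
        subj["vv_baseline"], subj["vv_last"], subj["t_last_volume"]
    )
    out["hv_rate_raw"] = hv_rate
    out["vv_rate_raw"] = vv_rate
    out["hv"] = standardise(subj["hv_baseline"])
    out["vv"] = standardise(subj["vv_baseline"])
    out["hv_rate"] = standardise(hv_rate)
    out["vv_rate"] = standardise(vv_rate)
    return out
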