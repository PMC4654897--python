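"""Registry file loading, linkage and cohort assembly.

Consumes two delimited-text files — a twin register (person id, pair id,
zygosity, sex, birth date, optional death/emigration dates) and an
arthroplasty register (person id, operation date, ICD-10 diagnosis code) —
links them on person id, applies the diagnosis whitelist and study-window
exclusion flow, and emits the individual-level analysis cohort together with
an exclusion ledger whose counts reconcile exactly with the input size.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

logger = logging.getLogger(__name__)

__all__ = ["LinkageConfig", "load_twin_register", "load_event_register",
           "build_analysis_cohort"]

_ZYG_ALIASES = {"MZ": "MZ", "DZSS": "DZSS", "SSDZ": "DZSS", "DZ": "DZSS",
                "DZOS": "DZOS", "OSDZ": "DZOS", "OS": "DZOS", "UZ": "UZ"}
_SEX_ALIASES = {"M": "M", "MALE": "M", "F": "F", "FEMALE": "F"}


@dataclass(frozen=True)
class LinkageConfig:
    diagnosis_whitelist: tuple = ("M160", "M161")
    window_start: dt.date = dt.date(1995, 1, 1)
    window_end: dt.date = dt.date(2010, 8, 31)
    zygosity_excluded: frozenset = frozenset({"UZ"})
    dedupe_rule: str = "first_operation"

    def __post_init__(self):
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if not self.diagnosis_whitelist:
            raise ValueError("diagnosis whitelist must be non-empty")
        if self.dedupe_rule != "first_operation":
            raise ValueError("only the first_operation dedupe rule is supported")

    @property
    def normalized_whitelist(self) -> set:
        return {normalize_icd10(c) for c in self.diagnosis_whitelist}


def normalize_icd10(code) -> str:
    """Canonical undotted upper-case ICD-10 form ('M16.0' == 'M160')."""
    return str(code).replace(".", "").replace(" ", "").upper()


def _parse_dates(raw: pd.Series, col: str, required: bool):
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = parsed.isna() & ~blank
    if required:
        bad |= blank
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"unparseable {col} on line(s) {lines}")
    return parsed


def _read_delimited(path, delimiter):
    """CSV/TSV with a sniffed delimiter; falls back to comma."""
    try:
        return pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    except Exception:
        if delimiter is None:
            return pd.read_csv(path, sep=",", dtype=str)
        raise


def load_twin_register(path, delimiter=None) -> pd.DataFrame:
    """Load and validate the twin-register file.

    Raises on missing columns, duplicate person ids, unparseable dates
    (reported with line numbers) and same-sex/opposite-sex zygosity
    contradictions; singleton pair ids are excluded with a logged warning.
    """
    df = _read_delimited(path, delimiter)
    required = {"person_id", "pair_id", "zygosity", "sex", "birth_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"twin register is missing columns: {sorted(missing)}")

    if df["person_id"].duplicated().any():
        dups = df.loc[df["person_id"].duplicated(), "person_id"].tolist()
        raise ValueError(f"duplicate person_id(s): {dups}")

    zyg = df["zygosity"].str.strip().str.upper().map(_ZYG_ALIASES)
    if zyg.isna().any():
        lines = (np.flatnonzero(zyg.isna()) + 2).tolist()
        raise ValueError(f"unknown zygosity code on line(s) {lines}")
    sex = df["sex"].str.strip().str.upper().map(_SEX_ALIASES)
    if sex.isna().any():
        lines = (np.flatnonzero(sex.isna()) + 2).tolist()
        raise ValueError(f"unknown sex code on line(s) {lines}")

    out = pd.DataFrame({
        "person_id": df["person_id"].str.strip(),
        "pair_id": df["pair_id"].str.strip(),
        "zygosity": zyg,
        "sex": sex,
        "birth_date": _parse_dates(df["birth_date"], "birth_date", required=True),
        "death_date": _parse_dates(df.get("death_date", pd.Series([None] * len(df))),
                                   "death_date", required=False),
        "emigration_date": _parse_dates(
            df.get("emigration_date", pd.Series([None] * len(df))),
            "emigration_date", required=False),
    })

    sizes = out.groupby("pair_id")["person_id"].transform("size")
    singles = out.loc[sizes != 2, "pair_id"].unique().tolist()
    if singles:
        msg = f"excluding {len(singles)} pair id(s) without exactly 2 members: {singles[:10]}"
        warnings.warn(msg)
        logger.warning(msg)
        out = out[sizes == 2]

    for pid, grp in out.groupby("pair_id"):
        z = grp["zygosity"].iloc[0]
        if set(grp["zygosity"]) != {z}:
            raise ValueError(f"pair {pid} has inconsistent zygosity codes")
        same_sex = grp["sex"].iloc[0] == grp["sex"].iloc[1]
        if z in ("MZ", "DZSS") and not same_sex:
            raise ValueError(f"pair {pid} is {z} but members have opposite sexes")
        if z == "DZOS" and same_sex:
            raise ValueError(f"pair {pid} is DZOS but members have the same sex")
        if set(grp["birth_date"]) != {grp["birth_date"].iloc[0]}:
            raise ValueError(f"pair {pid} members have different birth dates")
    return out.reset_index(drop=True)


def load_event_register(path, delimiter=None) -> pd.DataFrame:
    """Load the arthroplasty-register file (multiple rows per person allowed)."""
    try:
        df = _read_delimited(path, delimiter)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["person_id", "operation_date", "diagnosis_code"])
    required = {"person_id", "operation_date", "diagnosis_code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event register is missing columns: {sorted(missing)}")
    if not len(df):
        return pd.DataFrame(columns=["person_id", "operation_date", "diagnosis_code"])
    return pd.DataFrame({
        "person_id": df["person_id"].str.strip(),
        "operation_date": _parse_dates(df["operation_date"], "operation_date",
                                       required=True),
        "diagnosis_code": df["diagnosis_code"].str.strip(),
    })


def build_analysis_cohort(twins: pd.DataFrame, events: pd.DataFrame,
                          config: LinkageConfig | None = None):
    """Link the registers and apply the exclusion flow.

    Returns (cohort, ledger). Ages are exact day differences divided by
    365.25. Case status comes from the first whitelisted operation inside
    the study window; a same-age tie between operation and death resolves to
    the operation (a recorded operation implies the patient was alive).
    Pairs with a member dead before the window start are excluded (the study
    base requires both members alive at the start), as are excluded-zygosity
    pairs; every exclusion is counted so that
    cohort size + sum(exclusions) == input size.
    """
    config = config or LinkageConfig()
    start = pd.Timestamp(config.window_start)
    end = pd.Timestamp(config.window_end)
    ledger = {"input_individuals": int(len(twins))}

    t = twins.copy()
    excl_zyg = t["zygosity"].isin(config.zygosity_excluded)
    # pair-level: exclude the co-twin of an excluded-zygosity member too
    excl_zyg = excl_zyg.groupby(t["pair_id"]).transform("any")
    ledger["excluded_zygosity"] = int(excl_zyg.sum())
    t = t[~excl_zyg]

    dead_before = (t["death_date"].notna() & (t["death_date"] < start)) | (
        t["emigration_date"].notna() & (t["emigration_date"] < start))
    dead_before = dead_before.groupby(t["pair_id"]).transform("any")
    ledger["excluded_not_alive_at_start"] = int(dead_before.sum())
    t = t[~dead_before]

    ev = events.copy()
    known = ev["person_id"].isin(set(t["person_id"]))
    ledger["events_unmatched"] = int((~known).sum())
    if (~known).any():
        logger.warning("dropping %d event row(s) with unknown person_id",
                       int((~known).sum()))
    ev = ev[known]
    ev["code_norm"] = ev["diagnosis_code"].map(normalize_icd10)
    in_whitelist = ev["code_norm"].isin(config.normalized_whitelist)
    ledger["events_non_whitelist"] = int((~in_whitelist).sum())
    ev = ev[in_whitelist]
    in_window = (ev["operation_date"] >= start) & (ev["operation_date"] <= end)
    ledger["events_outside_window"] = int((~in_window).sum())
    ev = ev[in_window]
    ev = (ev.sort_values("operation_date")
          .drop_duplicates("person_id", keep="first"))  # first_operation rule

    t = t.merge(ev[["person_id", "operation_date", "code_norm"]],
                on="person_id", how="left")
    # an empty event frame merges as object/float columns
    t["operation_date"] = pd.to_datetime(t["operation_date"])

    birth = t["birth_date"]
    entry_age = np.maximum((start - birth).dt.days / DAYS_PER_YEAR, 0.0)
    admin_age = (end - birth).dt.days / DAYS_PER_YEAR
    case_age = (t["operation_date"] - birth).dt.days / DAYS_PER_YEAR
    death_age = (t["death_date"] - birth).dt.days / DAYS_PER_YEAR
    emig_age = (t["emigration_date"] - birth).dt.days / DAYS_PER_YEAR
    censor_age = np.fmin(admin_age, emig_age.fillna(np.inf))

    has_case = case_age.notna()
    exit_age = np.where(has_case, case_age,
                        np.fmin(death_age.fillna(np.inf), censor_age))
    # ties resolve case > death > censored
    cause = np.where(has_case, "case",
                     np.where(death_age.fillna(np.inf) <= censor_age,
                              "death", "censored"))

    member = t.groupby("pair_id").cumcount() + 1
    cohort = pd.DataFrame({
        "person_id": t["person_id"],
        "pair_id": t["pair_id"],
        "member_index": member,
        "sex": t["sex"],
        "zygosity": t["zygosity"],
        "birth_date": birth.dt.date,
        "entry_age": entry_age,
        "exit_age": exit_age,
        "exit_cause": cause,
        "diagnosis_code": t["code_norm"].fillna(""),
        "admin_censor_age": admin_age,
    }).reset_index(drop=True)

    ledger["cohort_individuals"] = int(len(cohort))
    assert (ledger["cohort_individuals"] + ledger["excluded_zygosity"]
            + ledger["excluded_not_alive_at_start"] == ledger["input_individuals"])
    return cohort, ledger
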