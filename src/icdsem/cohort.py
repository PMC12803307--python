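"""Distinct-day diagnosis counting and threshold-based cohort accounting.

A person's count for an ICD set is the number of distinct *calendar days*
on which any code from the set was recorded — multiple codes from the set
on the same day are one event.  Cohort size at threshold t is the number
of persons with count ≥ t, computed overall and within sex/ancestry
strata; fold change compares an expanded code set against a reference set
at matched (threshold, stratum) cells.

Timestamps are collapsed with their stored date component only (inputs
are assumed pre-localised).  Persons missing from the strata table are
assigned to an "unknown" stratum rather than dropped, so the overall
total always equals the sum over strata.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import Key
from .exceptions import DataError

OVERALL_STRATUM = ("overall", "overall")
UNKNOWN = "unknown"

RECORD_COLUMNS = ("person_id", "vocabulary", "code", "event_time")
STRATA_COLUMNS = ("person_id", "sex", "ancestry")


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise DataError(f"{what} missing columns {missing}")


def distinct_day_counts(records: pd.DataFrame, icd_set: Iterable[Key]) -> pd.Series:
    """Distinct calendar days per person with any code from ``icd_set``.

    Persons with no matching record are absent (implicit zero).
    """
    icd_set = set(icd_set)
    if not icd_set:
        raise DataError("empty ICD set")
    _require_columns(records, RECORD_COLUMNS, "diagnosis records")
    if records.empty:
        return pd.Series(dtype=np.int64, name="distinct_days")
    keys = list(zip(records["vocabulary"].astype(str), records["code"].astype(str)))
    mask = np.fromiter((key in icd_set for key in keys), dtype=bool, count=len(keys))
    matched = records.loc[mask]
    if matched.empty:
        return pd.Series(dtype=np.int64, name="distinct_days")
    times = pd.to_datetime(matched["event_time"], errors="coerce", format="mixed")
    if times.isna().any():
        bad = matched.loc[times.isna()].iloc[0]
        raise DataError(
            f"unparseable timestamp {bad['event_time']!r} for person {bad['person_id']}"
        )
    days = times.dt.normalize()
    counts = (
        pd.DataFrame({"person_id": matched["person_id"].to_numpy(), "day": days.to_numpy()})
        .drop_duplicates()
        .groupby("person_id")
        .size()
    )
    counts.name = "distinct_days"
    return counts


def cohort_sizes(
    counts: pd.Series,
    thresholds: Sequence[int],
    strata: pd.DataFrame,
    icd_set_id: str = "set",
) -> pd.DataFrame:
    """Long-format cohort sizes per (threshold, stratum), plus the overall row.

    Strata are the sex and ancestry labels; persons present in ``counts``
    but absent from ``strata`` fall into the "unknown" stratum.
    """
    if list(thresholds) != sorted(thresholds) or any(t < 1 for t in thresholds):
        raise DataError("thresholds must be ascending positive integers")
    _require_columns(strata, STRATA_COLUMNS, "strata table")
    if strata["person_id"].duplicated().any():
        raise DataError("strata table has duplicated person_id rows")

    frame = counts.rename("n_days").rename_axis("person_id").reset_index()
    merged = frame.merge(strata, on="person_id", how="left")
    n_unknown = int(merged["sex"].isna().sum())
    if n_unknown:
        import logging

        logging.getLogger(__name__).warning(
            "%d persons with diagnosis counts missing from strata; assigned 'unknown'", n_unknown
        )
    merged["sex"] = merged["sex"].fillna(UNKNOWN)
    merged["ancestry"] = merged["ancestry"].fillna(UNKNOWN)

    # stratum levels come from the full strata table, so tables built from
    # different ICD sets stay cell-for-cell comparable (zero sizes included)
    sex_levels = sorted(set(strata["sex"]) | ({UNKNOWN} if n_unknown else set()))
    anc_levels = sorted(set(strata["ancestry"]) | ({UNKNOWN} if n_unknown else set()))
    rows = []
    groups: list[tuple[str, str, pd.Series]] = [("overall", "overall", merged["n_days"])]
    for sex in sex_levels:
        groups.append(("sex", str(sex), merged.loc[merged["sex"] == sex, "n_days"]))
    for anc in anc_levels:
        groups.append(("ancestry", str(anc), merged.loc[merged["ancestry"] == anc, "n_days"]))
    for stratum_type, stratum, values in groups:
        arr = values.to_numpy()
        for t in thresholds:
            rows.append(
                {
                    "icd_set_id": icd_set_id,
                    "threshold": int(t),
                    "stratum_type": stratum_type,
                    "stratum": stratum,
                    "size": int((arr >= t).sum()),
                }
            )
    return pd.DataFrame(rows)


def fold_change(expanded: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fold change expanded/reference with an undefined guard.

    Cells where the reference size is 0 get fold NaN and ``undefined``
    True (never infinity).  The result carries ``fold`` per (threshold,
    stratum) and summary attrs: median and IQR of the defined folds.
    """
    on = ["threshold", "stratum_type", "stratum"]
    left = expanded.rename(columns={"size": "size_expanded", "icd_set_id": "expanded_set"})
    right = reference.rename(columns={"size": "size_reference", "icd_set_id": "reference_set"})
    merged = left.merge(right, on=on, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise DataError("expanded and reference tables have mismatched thresholds/strata")
    merged = merged.drop(columns="_merge")
    undefined = merged["size_reference"] == 0
    merged["fold"] = np.where(
        undefined, np.nan, merged["size_expanded"] / merged["size_reference"].replace(0, np.nan)
    )
    merged["undefined"] = undefined
    defined = merged.loc[~undefined, "fold"]
    merged.attrs["median_fold"] = float(defined.median()) if len(defined) else float("nan")
    if len(defined):
        q1, q3 = defined.quantile([0.25, 0.75])
        merged.attrs["iqr_fold"] = (float(q1), float(q3))
    else:
        merged.attrs["iqr_fold"] = (float("nan"), float("nan"))
    return merged
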