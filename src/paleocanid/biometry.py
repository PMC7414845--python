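"""Log-shape-ratio biometry of postcranial measurements.

Osteometric measurements (von den Driesch measurement codes, mm) of each
specimen are compared with the homologous measurements of a designated
standard skeleton via the classic Simpson log-ratio:

    d = log10(value / standard_value)

Negative d means the specimen is smaller than the standard, positive
larger; base-10 logarithms follow the log-ratio-diagram convention of the
zooarchaeological literature.  Rows flagged as coming from reworked
sediments, burnt (shrinkage-prone) or unmeasurable specimens are excluded
before analysis, with a per-row report of the removals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "specimen_id",
    "population",
    "element",
    "code",
    "value_mm",
]

#: flags whose presence removes a row from the biometric analysis
EXCLUSION_FLAGS = ("reworked", "burnt", "unmeasurable")


def _parse_flags(val) -> set[str]:
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return set()
    if isinstance(val, (set, frozenset, list, tuple)):
        return {str(v).strip() for v in val if str(v).strip()}
    return {p.strip() for p in str(val).split(";") if p.strip()}


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table and normalise its flags column."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df = table.copy()
    if "flags" not in df.columns:
        df["flags"] = [set() for _ in range(len(df))]
    else:
        df["flags"] = df["flags"].map(_parse_flags)
    if (df["value_mm"] <= 0).any():
        bad = df.loc[df["value_mm"] <= 0, "specimen_id"].tolist()
        raise ValueError(f"non-positive measurement values for specimens {bad}")
    dup = df.duplicated(subset=["specimen_id", "code"])
    if dup.any():
        pairs = df.loc[dup, ["specimen_id", "code"]].values.tolist()
        raise ValueError(f"duplicate (specimen, code) rows: {pairs}")
    return df


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove rows flagged reworked / burnt / unmeasurable.

    Returns the filtered table and a report with one row per removal
    (specimen, code, reason).  An empty result is allowed with a warning.
    """
    df = validate_table(table)
    reasons = []
    keep = []
    for _, row in df.iterrows():
        hit = sorted(row["flags"] & set(EXCLUSION_FLAGS))
        if hit:
            reasons.append(
                {
                    "specimen_id": row["specimen_id"],
                    "code": row["code"],
                    "reason": ";".join(hit),
                }
            )
            keep.append(False)
        else:
            keep.append(True)
    report = pd.DataFrame(reasons, columns=["specimen_id", "code", "reason"])
    out = df.loc[keep].reset_index(drop=True)
    if len(out) == 0 and len(df) > 0:
        warnings.warn("all rows were excluded; the filtered table is empty")
    return out, report


def log_shape_ratio(table: pd.DataFrame, standard: pd.DataFrame) -> pd.DataFrame:
    """Per-row log10 ratio against the standard individual.

    ``standard`` must provide one value per measurement code (columns
    ``code`` and ``value_mm``); a code absent from the standard raises a
    KeyError naming every missing code.
    """
    df = validate_table(table)
    std = standard.drop_duplicates(subset="code").set_index("code")["value_mm"]
    missing = sorted(set(df["code"]) - set(std.index))
    if missing:
        raise KeyError(f"measurement codes absent from the standard: {missing}")
    out = df[["specimen_id", "population", "element", "code", "value_mm"]].copy()
    out["standard_mm"] = std.loc[out["code"]].to_numpy()
    out["log_ratio"] = np.log10(out["value_mm"] / out["standard_mm"])
    return out


def summarize_population(
    profile: pd.DataFrame, order: list[str] | None = None
) -> pd.DataFrame:
    """Per (population, code) summary suitable for a log-ratio diagram.

    Columns: n, mean, sd, min, max of the log ratios.  With a single
    specimen the sd is reported as NaN.  Populations appear in ``order``
    when given, otherwise in first-appearance order.
    """
    if len(profile) == 0:
        raise ValueError("empty log-ratio profile")
    grp = profile.groupby(["population", "code"], sort=False)["log_ratio"]
    summary = grp.agg(n="count", mean="mean", sd="std", min="min", max="max")
    summary = summary.reset_index()
    if order is not None:
        known = [p for p in order if p in set(summary["population"])]
        missing = set(summary["population"]) - set(order)
        if missing:
            warnings.warn(f"populations not in requested order: {sorted(missing)}")
        cat = pd.Categorical(
            summary["population"], categories=known + sorted(missing), ordered=True
        )
        summary = summary.assign(_o=cat).sort_values(["_o", "code"]).drop(columns="_o")
        summary = summary.reset_index(drop=True)
    return summary
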