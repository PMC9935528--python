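"""Water-type-stratified outlier screening of water-quality measurements.

Chlorophyll a, TSS, a_CDOM(440) and Secchi depth span several orders of
magnitude and are close to log-normal within an optical water type, so the
screen works on log10-transformed positive values by default: within each
``Water_type`` group and variable, values more than k (default 3) sample
standard deviations from the group mean are flagged for reevaluation.  The
screen is advisory only — it never removes records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleRecord

#: screened water-quality variables (SampleRecord attribute names)
WQ_VARIABLES = ("chla", "tss", "acdom440", "secchi")


@dataclass
class WQOutlierReport:
    """Per (sample, variable) screening outcome.

    ``table`` columns: gloria_id, variable, value (original units),
    z (|value - group mean| / group SD in screen units, NaN when
    undeterminable), flag (nullable: 1 outlier, 0 in range, NA when the
    group is too small or has zero spread), group_n (usable group size).

    ``data_errors`` lists non-positive values that could not enter the log
    transform; they are data problems, not statistical outliers.
    """

    table: pd.DataFrame
    k: float
    log_transform: bool
    data_errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gloria_id", "variable", "value"]
        )
    )

    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == 1]

    def counts_by_water_type(self) -> pd.Series:
        flagged = self.table[self.table["flag"] == 1]
        return flagged.groupby("water_type").size()


def screen_outliers(
    records: list[SampleRecord],
    k: float = 3.0,
    log_transform: bool = True,
) -> WQOutlierReport:
    """Flag water-quality values > k SDs from their water-type group mean.

    Groups are formed by ``water_type``; records without a water type are
    grouped under "(unassigned)".  Within a group, the mean and sample
    (n-1) SD are computed per variable over usable values — log10 of
    positive values when ``log_transform`` (the default), raw values
    otherwise.  Groups with fewer than 2 usable values or zero SD yield NA
    flags.  Missing values simply do not appear in the report.
    """
    if k <= 0:
        raise ValueError(f"threshold k must be positive, got {k}")

    rows = []
    errors = []
    for r in records:
        wt = r.water_type if r.water_type is not None else "(unassigned)"
        for var in WQ_VARIABLES:
            value = getattr(r, var)
            if value is None:
                continue
            if log_transform and value <= 0:
                errors.append(
                    {"gloria_id": r.gloria_id, "variable": var, "value": value}
                )
                continue
            rows.append(
                {
                    "gloria_id": r.gloria_id,
                    "water_type": wt,
                    "variable": var,
                    "value": value,
                    "screen_value": np.log10(value) if log_transform else value,
                }
            )

    if not rows:
        empty = pd.DataFrame(
            columns=["gloria_id", "water_type", "variable", "value", "z", "flag", "group_n"]
        )
        empty["flag"] = empty.get("flag", pd.Series(dtype="Int64")).astype("Int64")
        return WQOutlierReport(
            table=empty, k=k, log_transform=log_transform,
            data_errors=pd.DataFrame(errors, columns=["gloria_id", "variable", "value"]),
        )

    df = pd.DataFrame(rows)
    grp = df.groupby(["water_type", "variable"])["screen_value"]
    df["group_n"] = grp.transform("count").astype(int)
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        df["z"] = (df["screen_value"] - mean).abs() / sd
    determinable = (df["group_n"] >= 2) & (sd > 0)
    flag = pd.array([pd.NA] * len(df), dtype="Int64")
    flag[determinable.to_numpy()] = (
        df.loc[determinable, "z"] > k
    ).astype(int).to_numpy()
    df["flag"] = flag
    df.loc[~determinable, "z"] = np.nan
    # order-invariant output regardless of input record order
    df = df.sort_values(["water_type", "variable", "gloria_id"], kind="stable")
    df = df[
        ["gloria_id", "water_type", "variable", "value", "z", "flag", "group_n"]
    ].reset_index(drop=True)
    return WQOutlierReport(
        table=df,
        k=k,
        log_transform=log_transform,
        data_errors=pd.DataFrame(errors, columns=["gloria_id", "variable", "value"]),
    )


def write_report(report: WQOutlierReport, path) -> None:
    """Write the screening report (gloria_id, variable, z, flag, group_n)."""
    out = report.table[["gloria_id", "variable", "z", "flag", "group_n"]]
    out.to_csv(path, index=False, float_format="%.10g")
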