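"""Immunohistochemistry complex scoring.

The complex score (CS) of one reading is staining intensity (integer grade
0-3, i.e. 0/+/++/+++) times the percentage of positive neoplastic cells,
giving a value in [0, 300] (an H-score-like quantity).  Each slide is read by
several independent readers; per-sample consensus is taken over the readers'
CS values (not over intensities and percentages separately, which would not
commute with the product), by median by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

VALID_INTENSITIES = (0, 1, 2, 3)
AGGREGATION_RULES = ("median", "mean")


@dataclass(frozen=True)
class IHCReading:
    """One reader's evaluation of one marker on one sample."""

    sample_id: str
    marker: str
    reader: str
    intensity: int
    percent_positive: float

    def __post_init__(self):
        if self.intensity not in VALID_INTENSITIES:
            raise ValidationError(
                f"{self.sample_id}/{self.marker}/{self.reader}: intensity "
                f"{self.intensity!r} not in {{0, 1, 2, 3}}"
            )
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValidationError(
                f"{self.sample_id}/{self.marker}/{self.reader}: percent positive "
                f"{self.percent_positive!r} outside [0, 100]"
            )


def complex_score(reading: IHCReading) -> float:
    """CS = intensity x percent positive; in [0, 300]."""
    return float(reading.intensity) * float(reading.percent_positive)


def aggregate_readers(cs_values: Sequence[float], rule: str = "median") -> float:
    """Consensus CS over readers (median by default, mean selectable).

    With an even number of readers the median is the midpoint of the two
    central values.  Raises on zero readings (callers record a missing value).
    """
    if rule not in AGGREGATION_RULES:
        raise ValidationError(f"unknown aggregation rule {rule!r}")
    if len(cs_values) == 0:
        raise ValidationError("no readings to aggregate")
    arr = np.asarray(cs_values, dtype=float)
    return float(np.median(arr) if rule == "median" else arr.mean())


def read_ihc_readings(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "marker", "reader", "intensity", "percent_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"IHC table lacks columns {sorted(missing)}")
    return df


def score_cohort(
    readings: pd.DataFrame,
    design: pd.DataFrame,
    rule: str = "median",
) -> pd.DataFrame:
    """Consensus complex scores per sample x marker, aligned to cohort groups.

    Returns a tidy table (sample_id, marker, group, n_readers, cs).  Raises on
    duplicate (sample, marker, reader) rows and on samples absent from the
    design table; a marker missing for one sample simply yields no row.
    """
    dup = readings.duplicated(subset=["sample_id", "marker", "reader"])
    if dup.any():
        offending = readings.loc[dup, ["sample_id", "marker", "reader"]].iloc[0]
        raise ValidationError(
            "duplicate IHC reading for "
            f"({offending.sample_id}, {offending.marker}, {offending.reader})"
        )
    groups = design.set_index("sample_id")["group"]
    unknown = sorted(set(readings["sample_id"]) - set(groups.index))
    if unknown:
        raise ValidationError(f"IHC sample(s) absent from design: {unknown}")

    rows = []
    for (sample_id, marker), block in readings.groupby(["sample_id", "marker"], sort=True):
        cs_values = [
            complex_score(
                IHCReading(
                    sample_id=str(sample_id), marker=str(marker),
                    reader=str(r.reader), intensity=int(r.intensity),
                    percent_positive=float(r.percent_positive),
                )
            )
            for r in block.itertuples()
        ]
        rows.append(
            (sample_id, marker, groups[sample_id], len(cs_values),
             aggregate_readers(cs_values, rule))
        )
    return pd.DataFrame(rows, columns=["sample_id", "marker", "group", "n_readers", "cs"])


def scores_to_long(scores: pd.DataFrame, measure_suffix: str = "cs") -> pd.DataFrame:
    """Tidy (sample_id, measure, value) view for the comparison battery."""
    out = scores.rename(columns={"cs": "value"}).copy()
    out["measure"] = out["marker"] + ":" + measure_suffix
    return out[["sample_id", "measure", "value"]]
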