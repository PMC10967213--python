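"""Binary survival labels for a chosen horizon.

Overall survival is recast as classification: did the patient survive
beyond the selected time (label 0) or die within it (label 1)? A sample
censored before the horizon carries neither answer and is dropped — e.g.
a patient alive at last follow-up four years in cannot be labeled for a
five-year horizon.

Boundary convention: label 0 requires survival *strictly* beyond the
horizon, so an observation time exactly equal to the horizon goes to
label 1 if the death was observed and is dropped if censored. The
comparison is configurable via ``survive_strictly``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

# Horizon presets in days: short/mid/long-term overall survival at 1/3/5 years.
HORIZON_PRESETS: dict[str, float] = {"short": 365.0, "mid": 1095.0, "long": 1825.0}

# os_time magnitudes are sanity-checked against the horizon; a median time
# under 1/20 of the horizon usually means a unit mismatch (years vs days).
_UNIT_MISMATCH_RATIO = 20.0


class LabelingError(ValueError):
    """Raised for invalid survival records or horizons."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: observed time and event status (1 = death)."""

    sample_id: str
    os_time: float
    event: int

    def __post_init__(self) -> None:
        if not self.os_time >= 0:
            raise LabelingError(f"{self.sample_id}: negative os_time {self.os_time}")
        if self.event not in (0, 1):
            raise LabelingError(f"{self.sample_id}: event must be 0 or 1, got {self.event}")


@dataclass
class LabeledCohort:
    """Kept samples with labels, plus the dropped (unlabelable) ids.

    kept ∪ dropped partitions the input ids; every kept sample has a label
    in {0: survived beyond horizon, 1: died within horizon}.
    """

    sample_ids: list[str]
    labels: list[int]
    horizon: float
    dropped: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise LabelingError("sample_ids and labels length mismatch")

    @property
    def n_kept(self) -> int:
        return len(self.sample_ids)

    def label_of(self, sample_id: str) -> int:
        return self.labels[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels})


def label_samples(
    records: list[SurvivalRecord],
    horizon: float,
    survive_strictly: bool = True,
) -> LabeledCohort:
    """Apply the three-way labeling rule to every record.

    * survived beyond the horizon → label 0 (event status irrelevant);
    * death observed within the horizon → label 1;
    * censored within the horizon → dropped (unlabelable).

    ``survive_strictly`` controls the boundary: when True (default),
    os_time must exceed the horizon strictly for label 0.
    """
    if not horizon > 0:
        raise LabelingError(f"horizon must be positive, got {horizon}")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise LabelingError("duplicate sample ids in survival records")

    kept: list[str] = []
    labels: list[int] = []
    dropped: list[str] = []
    for r in records:
        beyond = r.os_time > horizon if survive_strictly else r.os_time >= horizon
        if beyond:
            kept.append(r.sample_id)
            labels.append(0)
        elif r.event == 1:
            kept.append(r.sample_id)
            labels.append(1)
        else:
            dropped.append(r.sample_id)
    return LabeledCohort(kept, labels, horizon, dropped)


def read_survival(path: str | Path, sep: str | None = None) -> list[SurvivalRecord]:
    """Read a survival table with columns sample_id, os_time, os_event."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise LabelingError(f"{path}: missing columns {sorted(missing)}")
    return [
        SurvivalRecord(str(row.sample_id), float(row.os_time), int(row.os_event))
        for row in df.itertuples(index=False)
    ]


def write_labels(cohort: LabeledCohort, path: str | Path, sep: str = "\t") -> None:
    """Write labels plus a sidecar report of dropped samples."""
    path = Path(path)
    cohort.to_frame().to_csv(path, sep=sep, index=False)
    report = path.with_suffix(path.suffix + ".dropped.txt")
    report.write_text("\n".join(cohort.dropped) + ("\n" if cohort.dropped else ""))


def check_time_units(records: list[SurvivalRecord], horizon: float) -> str | None:
    """Heuristic unit-mismatch warning (e.g. os_time in years, horizon in days).

    Returns a warning message or None. Never raises: units are the caller's
    responsibility.
    """
    times = sorted(r.os_time for r in records if r.os_time > 0)
    if not times:
        return None
    median = times[len(times) // 2]
    if median * _UNIT_MISMATCH_RATIO < horizon:
        return (
            f"median os_time {median:g} is far below horizon {horizon:g}; "
            "check that survival times and horizon use the same unit"
        )
    return None
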