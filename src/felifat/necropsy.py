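"""Necropsy records and the falciform-fat:femur-length ratio (FFR).

FFR = FFPW (g) / FL (cm, recorded to 2 decimals). A below-scale fat pad
weight is stored as 0 g (valid, flagged), not as missing: such animals
stay in the cohort with FFR 0. When femur length was not measured at
necropsy, a CT-derived length substitutes and the source is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_away

FAT_CATEGORIES = (
    "severe_underweight",
    "underweight",
    "normal",
    "overweight",
    "obese",
)
MUSCLE_GRADES = ("atrophic", "normal", "hypertrophic")
FL_SOURCES = ("postmortem", "ct")

_COLUMNS = [
    "cat_id",
    "body_weight",
    "ffpw",
    "fl",
    "visual_fc",
    "muscle_grade",
    "fl_source",
    "below_scale",
]


@dataclass(frozen=True)
class NecropsyRecord:
    cat_id: str
    body_weight: float  # g
    ffpw: float  # g; 0 encodes below recordable scale weight
    fl: float | None  # cm, 2 decimals; None only with a CT fallback
    visual_fc: str
    muscle_grade: str = "normal"
    fl_source: str = "postmortem"
    ct_fl: float | None = None  # cm, CT fallback when postmortem FL missing

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.ffpw < 0:
            raise ValueError("ffpw must be >= 0")
        if self.visual_fc not in FAT_CATEGORIES:
            raise ValueError(f"unknown fat category {self.visual_fc!r}")
        if self.muscle_grade not in MUSCLE_GRADES:
            raise ValueError(f"unknown muscle grade {self.muscle_grade!r}")
        if self.fl_source not in FL_SOURCES:
            raise ValueError(f"unknown fl_source {self.fl_source!r}")
        if self.fl is not None and self.fl <= 0:
            raise ValueError("fl must be positive when present")

    @property
    def below_scale(self) -> bool:
        return self.ffpw == 0

    @property
    def effective_fl(self) -> tuple[float, str]:
        """(femur length, source), preferring the postmortem measurement."""
        if self.fl is not None:
            return self.fl, self.fl_source
        if self.ct_fl is not None:
            return self.ct_fl, "ct"
        raise ValueError(
            f"{self.cat_id}: femur length missing and no CT fallback available"
        )


@dataclass(frozen=True)
class FFRResult:
    cat_id: str
    ffr: float  # g/cm, full precision
    fl_source: str = "postmortem"

    @property
    def ffr_reported(self) -> float:
        """1-decimal reporting precision; comparisons use full precision."""
        return round_half_away(self.ffr, 1)


def compute_ffr(record: NecropsyRecord) -> FFRResult:
    """FFPW / FL with FL first rounded to its 2-decimal recording."""
    fl, source = record.effective_fl
    fl = round_half_away(fl, 2)
    if fl <= 0:
        raise ValueError(f"{record.cat_id}: femur length must be positive")
    return FFRResult(cat_id=record.cat_id, ffr=record.ffpw / fl, fl_source=source)


def records_to_frame(records: list[NecropsyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {c: getattr(r, c, None) for c in _COLUMNS if c != "below_scale"}
        d["below_scale"] = r.below_scale
        d["ct_fl"] = r.ct_fl
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[NecropsyRecord]:
    records = []
    for i, row in df.iterrows():
        fl = row.get("fl")
        ct_fl = row.get("ct_fl")
        try:
            records.append(
                NecropsyRecord(
                    cat_id=str(row["cat_id"]),
                    body_weight=float(row["body_weight"]),
                    ffpw=float(row["ffpw"]),
                    fl=None if pd.isna(fl) else float(fl),
                    visual_fc=str(row["visual_fc"]),
                    muscle_grade=str(row.get("muscle_grade", "normal")),
                    fl_source=str(row.get("fl_source", "postmortem")),
                    ct_fl=None if ct_fl is None or pd.isna(ct_fl) else float(ct_fl),
                )
            )
        except (ValueError, KeyError) as exc:
            # +2: 1-based data rows below a header line
            raise ValueError(f"row {i + 2}: {exc}") from exc
    return records


def read_records(path) -> list[NecropsyRecord]:
    """Read a necropsy CSV; malformed rows are reported by line number."""
    return frame_to_records(pd.read_csv(path))


def write_records(records: list[NecropsyRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
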