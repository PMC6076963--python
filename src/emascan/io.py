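"""Reading and writing the study's file formats.

Activity files are delimited text with columns ``subject,timestamp,counts[,wear]``
holding epoch-accumulated accelerometer counts on a regular grid (typically
1-min epochs).  EMA files carry ``subject,day,timestamp,affect[,covariate...]``.
Scan output is a trio of TSV matrices (slope, p-value, FDR significance) with
one column per window location and one row per window size.

All timestamps are ISO-8601 local clock times; no time-zone arithmetic is
performed because every window is defined in minutes relative to a prompt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    OutOfRangeError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSeries",
    "EmaObservation",
    "SubjectCovariates",
    "read_epoch_series",
    "read_ema_records",
    "align_prompt",
    "write_scan_matrix",
    "read_scan_matrix",
    "ema_to_frame",
]


@dataclass
class EpochSeries:
    """One subject's regularly sampled activity counts.

    ``counts`` uses NaN for missing epochs; ``wear`` is False wherever the
    device was not worn or the epoch was gap-filled.  Epoch ``i`` covers the
    half-open interval ``[start_time + i*epoch, start_time + (i+1)*epoch)``.
    """

    subject_id: str
    start_time: pd.Timestamp
    epoch_length: float  # minutes
    counts: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be positive")
        if self.wear.shape != self.counts.shape:
            raise ValidationError("wear and counts must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(self.counts < 0):
                raise ValidationError(
                    f"negative counts in series for subject {self.subject_id!r}"
                )

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epoch(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.epoch_length)

    def time(self, i: int) -> pd.Timestamp:
        """Start time of epoch ``i``."""
        return self.start_time + i * self.epoch

    @property
    def end_time(self) -> pd.Timestamp:
        """End of the covered span (exclusive)."""
        return self.time(len(self))


@dataclass
class EmaObservation:
    """One timestamped affect rating, nested in a day nested in a subject."""

    subject_id: str
    day_index: int
    prompt_time: pd.Timestamp
    affect: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prompt_time = pd.Timestamp(self.prompt_time)
        if not np.isfinite(self.affect):
            raise ValidationError("affect must be finite")
        if self.day_index < 1:
            raise ValidationError("day_index must be >= 1")


@dataclass
class SubjectCovariates:
    """Between-subject predictors (Z_j), one record per subject."""

    subject_id: str
    values: dict[str, float]


def _epoch_offset(ts: pd.Timestamp, origin: pd.Timestamp, epoch_minutes: float) -> int:
    """Exact integer epoch offset of ts from origin, or raise AlignmentError."""
    delta_min = (ts - origin) / pd.Timedelta(minutes=1)
    k = delta_min / epoch_minutes
    k_round = round(k)
    if abs(k - k_round) > 1e-6:
        raise AlignmentError(f"timestamp {ts} not on the {epoch_minutes}-min epoch grid")
    return int(k_round)


def read_epoch_series(path, epoch_length: float = 1.0) -> dict[str, EpochSeries]:
    """Read an activity CSV into one :class:`EpochSeries` per subject.

    Gaps in a subject's timestamp grid are filled with missing (NaN) counts
    flagged non-wear, so every returned series is complete on its grid.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"subject", "timestamp", "counts"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"activity file missing column(s): {sorted(missing)}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    bad = ts.isna() & raw["timestamp"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"unparseable timestamp at line {line}")
    counts = pd.to_numeric(raw["counts"], errors="coerce")
    bad = counts.isna() & raw["counts"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(f"non-numeric counts at line {line}")
    if (counts.dropna() < 0).any():
        line = int(np.flatnonzero(counts < 0)[0]) + 2
        raise ValidationError(f"negative count at line {line}")

    if "wear" in raw.columns:
        wear_col = raw["wear"].str.strip().str.lower().map(
            {"1": True, "0": False, "true": True, "false": False}
        )
        if wear_col.isna().any():
            line = int(np.flatnonzero(wear_col.isna())[0]) + 2
            raise ParseError(f"unparseable wear flag at line {line}")
    else:
        wear_col = pd.Series(True, index=raw.index)

    out: dict[str, EpochSeries] = {}
    for subject, grp in raw.groupby("subject", sort=True):
        t = ts[grp.index].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise ValidationError(
                f"timestamps for subject {subject!r} are not strictly increasing"
            )
        t0 = pd.Timestamp(t[0])
        offsets = np.array(
            [_epoch_offset(pd.Timestamp(x), t0, epoch_length) for x in t]
        )
        n = offsets[-1] + 1
        c = np.full(n, np.nan)
        w = np.zeros(n, dtype=bool)
        c[offsets] = counts[grp.index].to_numpy()
        w[offsets] = wear_col[grp.index].to_numpy()
        out[str(subject)] = EpochSeries(
            subject_id=str(subject),
            start_time=t0,
            epoch_length=epoch_length,
            counts=c,
            wear=w,
        )
    return out


def read_ema_records(path) -> list[EmaObservation]:
    """Read an EMA CSV into observations sorted by subject then prompt time."""
    try:
        raw = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        logger.warning("EMA file %s is empty", path)
        return []
    if raw.empty:
        logger.warning("EMA file %s is empty", path)
        return []
    required = {"subject", "day", "timestamp", "affect"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"EMA file missing column(s): {sorted(missing)}")

    affect = pd.to_numeric(raw["affect"], errors="coerce")
    bad = affect.isna() & raw["affect"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(f"non-numeric affect at line {line}")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna())[0]) + 2
        raise ParseError(f"unparseable timestamp at line {line}")

    covar_cols = [c for c in raw.columns if c not in required]
    dup = raw.assign(_t=ts).duplicated(subset=["subject", "_t"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate (subject, prompt_time) at line {int(np.flatnonzero(dup)[0]) + 2}"
        )

    obs = []
    for i in raw.index:
        obs.append(
            EmaObservation(
                subject_id=str(raw.at[i, "subject"]),
                day_index=int(raw.at[i, "day"]),
                prompt_time=ts[i],
                affect=float(affect[i]),
                covariates={c: float(raw.at[i, c]) for c in covar_cols},
            )
        )
    obs.sort(key=lambda o: (o.subject_id, o.prompt_time))
    return obs


def ema_to_frame(observations: list[EmaObservation]) -> pd.DataFrame:
    """Flatten EMA observations to a DataFrame (one row per prompt)."""
    rows = [
        {
            "subject": o.subject_id,
            "day": o.day_index,
            "prompt_time": o.prompt_time,
            "affect": o.affect,
            **o.covariates,
        }
        for o in observations
    ]
    cols = ["subject", "day", "prompt_time", "affect"]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def align_prompt(series: EpochSeries, prompt_time) -> int:
    """Index of the epoch whose half-open interval contains ``prompt_time``."""
    prompt_time = pd.Timestamp(prompt_time)
    elapsed = (prompt_time - series.start_time) / pd.Timedelta(minutes=1)
    i = int(np.floor(elapsed / series.epoch_length + 1e-9))
    if i < 0 or i >= len(series):
        raise OutOfRangeError(
            f"prompt {prompt_time} outside recorded span "
            f"[{series.start_time}, {series.end_time}) for {series.subject_id!r}"
        )
    return i


def _format_cell(x, sig_digits: int = 6) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.{sig_digits}g}"


def write_scan_matrix(result, prefix: str) -> None:
    """Serialize a ScanResults object to ``<prefix>.{slope,pval,sig}.tsv``.

    Rows are window sizes with the smallest size on top (the top-left data
    cell is the shortest window at the most negative location); columns are
    locations ascending.  Cells where the model fit failed hold ``NA`` in all
    three files.
    """
    locations = np.asarray(result.grid.locations, dtype=float)
    sizes_disp = np.sort(np.asarray(result.grid.sizes, dtype=float))  # ascending
    header = "size\t" + "\t".join(_format_cell(l) for l in locations)

    def dump(path, matrix, as_flag=False):
        lines = [header]
        for s in sizes_disp:
            r = result.grid.row_of(s)
            cells = []
            for c in range(len(locations)):
                v = matrix[r, c]
                if as_flag:
                    p = result.pvalues[r, c]
                    cells.append("NA" if np.isnan(p) else str(int(bool(v))))
                else:
                    cells.append(_format_cell(v))
            lines.append(_format_cell(s) + "\t" + "\t".join(cells))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    dump(f"{prefix}.slope.tsv", result.slopes)
    dump(f"{prefix}.pval.tsv", result.pvalues)
    dump(f"{prefix}.sig.tsv", result.significant, as_flag=True)


def read_scan_matrix(path) -> pd.DataFrame:
    """Read one scan TSV back (sizes as index, locations as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.columns = [float(c) for c in df.columns]
    return df
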