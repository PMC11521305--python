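"""EDF/EDF+ recording I/O and the CSV sidecar tables.

A study on disk is a directory of single-channel EDF+ files plus a
``metadata.csv`` sidecar mapping each file to (lab, subject, group).  All
physical values are microvolts; all event times are seconds from the start
of the recording.  Zeitgeber time is carried as metadata only.

Reading goes through MNE's EDF reader; writing uses an in-package EDF+C
writer (16-bit, 1-second data records, TAL annotation channel) so that
round trips stay within one digitisation step of the physical range.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ChannelNotFoundError,
    FormatError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_metadata",
    "write_metadata",
    "read_endpoint_table",
    "write_endpoint_table",
    "write_variance_table",
    "DOSE_PATTERN",
]

#: Default pattern for EDF+ annotations that mark dosing; the single capture
#: group becomes the dose label (e.g. "dose MK801_0.2" -> "MK801_0.2").
DOSE_PATTERN = r"^dose\s+(.+)$"

METADATA_COLUMNS = ["lab_id", "subject_id", "group", "file"]
ENDPOINT_COLUMNS = ["lab_id", "subject_id", "group", "endpoint", "value"]


@dataclass
class Recording:
    """One channel of epidural EEG with study metadata.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in microvolts.
    sampling_rate : float
        Samples per second; must be positive.
    dose_events : list of (float, str)
        (seconds from recording start, dose label) pairs.
    start_zt : float or None
        Zeitgeber hour at recording start.  Metadata only; never used in
        any computation.
    """

    lab_id: str
    subject_id: str
    group: str
    samples: np.ndarray
    sampling_rate: float
    start_zt: float | None = None
    dose_events: list[tuple[float, str]] = field(default_factory=list)
    channel_name: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        for t, label in self.dose_events:
            if not 0 <= t <= self.duration:
                raise ValidationError(
                    f"dose event {label!r} at {t} s outside [0, {self.duration}]"
                )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def with_samples(
        self, samples: np.ndarray, sampling_rate: float | None = None
    ) -> "Recording":
        """Copy of this recording with new samples (and optionally rate)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
        )


# ---------------------------------------------------------------------------
# EDF+ writing


def _edf_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")
    if len(out) > width:
        raise ValidationError(f"EDF header field too long: {value!r}")
    return out.ljust(width)


def write_recording(recording: Recording, path) -> None:
    """Write a recording as a 16-bit EDF+C file.

    The physical range spans the data symmetrically, so the quantisation
    error per sample is at most (physical range) / 2**15.  Dose events are
    written as TAL annotations ("dose <label>").  The signal length must be
    a whole number of seconds (the writer uses 1-second data records).
    """
    x = recording.samples
    rate = recording.sampling_rate
    if rate != int(rate):
        raise ValidationError("EDF writer requires an integer sampling rate")
    rate = int(rate)
    if len(x) % rate != 0:
        raise ValidationError(
            "EDF writer requires a whole number of seconds "
            f"({len(x)} samples at {rate} Hz)"
        )
    n_rec = len(x) // rate
    if n_rec == 0:
        raise ValidationError("empty recording")

    amax = float(np.max(np.abs(x)))
    if amax == 0.0:
        amax = 1.0
    pmin, pmax = -amax, amax
    dmin, dmax = -32768, 32767
    digital = np.clip(
        np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin), dmin, dmax
    ).astype("<i2")

    # TAL annotation channel: each record starts with its own timestamp;
    # dose events are appended to the record containing their onset.
    ann_samples = 80  # 2 bytes each -> 160 bytes per record
    payloads = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for t, label in sorted(recording.dose_events):
            if min(int(t), n_rec - 1) == r:
                tal += f"+{t:g}\x14dose {label}\x14\x00".encode("utf-8")
        if len(tal) > 2 * ann_samples:
            raise ValidationError("annotation text too long for record")
        payloads.append(tal + b"\x00" * (2 * ann_samples - len(tal)))

    ns = 2
    zt = "" if recording.start_zt is None else f" ZT{recording.start_zt:g}"
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(f"X X X {recording.subject_id}"[:80], 80),
            _edf_field(f"Startdate X X X X{zt}"[:80], 80),
            _edf_field("01.01.24", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("EDF+C", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
            _edf_field(recording.channel_name[:16], 16),
            _edf_field("EDF Annotations", 16),
            _edf_field("", 80) * ns,  # transducer
            _edf_field("uV", 8),
            _edf_field("", 8),
            _edf_field(f"{pmin:.8g}"[:8], 8),
            _edf_field("-1", 8),
            _edf_field(f"{pmax:.8g}"[:8], 8),
            _edf_field("1", 8),
            _edf_field(str(dmin), 8),
            _edf_field(str(dmin), 8),
            _edf_field(str(dmax), 8),
            _edf_field(str(dmax), 8),
            _edf_field("", 80) * ns,  # prefiltering
            _edf_field(str(rate), 8),
            _edf_field(str(ann_samples), 8),
            _edf_field("", 32) * ns,
        ]
    )
    if len(header) != 256 * (ns + 1):
        raise AssertionError("malformed EDF header")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[r * rate : (r + 1) * rate].tobytes())
            fh.write(payloads[r])


# ---------------------------------------------------------------------------
# EDF reading (via MNE)


def read_recording(
    path,
    metadata_row: dict | pd.Series,
    dose_pattern: str = DOSE_PATTERN,
) -> Recording:
    """Read one EEG channel from an EDF/EDF+ file.

    ``metadata_row`` supplies lab/subject/group and (optionally) the channel
    name under key ``channel`` (default "EEG").  EDF+ annotations whose text
    matches ``dose_pattern`` become dose events; a ``dose_events`` entry in
    the metadata row (list of (seconds, label)) overrides the file's
    annotations, supporting workflows where pre/post segments arrive as
    separate files.
    """
    import mne

    row = dict(metadata_row)
    channel = row.get("channel") or "EEG"
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path} (has {raw.ch_names})"
        )
    data = raw.get_data(picks=[channel])[0] * 1e6  # Volts -> microvolts

    override = row.get("dose_events")
    if override is not None and not (
        isinstance(override, float) and np.isnan(override)
    ):
        dose_events = [(float(t), str(label)) for t, label in override]
    else:
        pat = re.compile(dose_pattern)
        dose_events = []
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            m = pat.match(desc)
            if m:
                dose_events.append((float(onset), m.group(1)))

    start_zt = row.get("start_zt")
    try:
        start_zt = float(start_zt)
        if not np.isfinite(start_zt):
            start_zt = None
    except (TypeError, ValueError):
        start_zt = None

    return Recording(
        lab_id=str(row["lab_id"]),
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        start_zt=None if start_zt is None else float(start_zt),
        dose_events=dose_events,
        channel_name=channel,
    )


# ---------------------------------------------------------------------------
# CSV sidecars


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s) {missing}")


def read_metadata(path) -> pd.DataFrame:
    """Read the study metadata CSV (one row per recording file)."""
    df = pd.read_csv(path, dtype={"lab_id": str, "subject_id": str, "group": str})
    _require_columns(df, METADATA_COLUMNS, "study metadata")
    dup = df.duplicated(subset=["lab_id", "subject_id", "group"])
    if dup.any():
        raise ValidationError(
            "duplicate (lab_id, subject_id, group) rows in metadata: "
            f"{df.loc[dup, ['lab_id', 'subject_id', 'group']].to_dict('records')}"
        )
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    _require_columns(df, METADATA_COLUMNS, "study metadata")
    df.to_csv(path, index=False)


def read_endpoint_table(path) -> pd.DataFrame:
    """Read an endpoint table CSV: (lab_id, subject_id, group, endpoint, value)."""
    df = pd.read_csv(path, dtype={"lab_id": str, "subject_id": str, "group": str})
    _require_columns(df, ENDPOINT_COLUMNS, "endpoint table")
    dup = df.duplicated(subset=["lab_id", "subject_id", "group", "endpoint"])
    if dup.any():
        raise ValidationError("duplicate (lab, subject, group, endpoint) rows")
    df["value"] = df["value"].astype(float)
    return df


def write_endpoint_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, ENDPOINT_COLUMNS, "endpoint table")
    df.to_csv(path, index=False)


def write_variance_table(table: pd.DataFrame, path) -> None:
    """Write a formatted variance-components table (see ``stats_models.variance_table``)."""
    table.to_csv(path)
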