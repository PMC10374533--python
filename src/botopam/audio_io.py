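"""WAV ingestion, resampling to the 96 kHz working rate, and 5-s segmentation.

The analysis band runs from DC to 48 kHz, so every recording is brought to a
common 96 kHz rate before feature extraction.  Recorders in the field run at
96, 128, 192 or 512 kHz; rates above 96 kHz are reduced by low-pass filtering
and rational (polyphase) resampling.  Recordings are then cut into contiguous,
non-overlapping 5-s segments — the unit on which the classifier operates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

WORKING_RATE_HZ = 96_000
SEGMENT_SECONDS = 5
SEGMENT_SAMPLES = WORKING_RATE_HZ * SEGMENT_SECONDS  # 480,000

#: Sample rates used by the recorders this pipeline was designed around.
KNOWN_RATES_HZ = (96_000, 128_000, 192_000, 512_000)

#: Default filename timestamp convention: an ISO-8601-like token such as
#: ``site_20190706T153000.wav`` or ``site_2019-07-06_15-30-00.wav``.
DEFAULT_TIMESTAMP_REGEX = (
    r"(?P<ts>\d{4}-?\d{2}-?\d{2}[T_ ]\d{2}[-:]?\d{2}[-:]?\d{2})"
)


class AudioFormatError(ValueError):
    """Raised when a file is not a readable PCM WAV."""


@dataclass
class Waveform:
    """A mono, full-scale-normalized sample series with provenance.

    ``start_time`` is ``None`` when the recording epoch is unknown (no
    timestamp could be parsed from the filename and none was supplied).
    """

    samples: np.ndarray
    rate_hz: int
    start_time: datetime | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class Segment:
    """Exactly 5 s of audio at 96 kHz; ``index`` is its position in the parent
    recording and ``start_time`` the absolute UTC start (if known)."""

    waveform: Waveform
    index: int
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.waveform.rate_hz != WORKING_RATE_HZ:
            raise ValueError(
                f"segments must be at {WORKING_RATE_HZ} Hz, "
                f"got {self.waveform.rate_hz}"
            )
        if self.waveform.samples.size != SEGMENT_SAMPLES:
            raise ValueError(
                f"segments must hold {SEGMENT_SAMPLES} samples, "
                f"got {self.waveform.samples.size}"
            )

    @property
    def segment_id(self) -> str:
        return f"{self.waveform.source_id}:{self.index:06d}"


@dataclass
class RecordingSchedule:
    """Duty cycle of a recorder, e.g. 1 min on / 9 min off."""

    duty_on_min: float
    duty_off_min: float = 0.0

    def __post_init__(self) -> None:
        if self.duty_on_min <= 0:
            raise ValueError("duty_on_min must be > 0")
        if self.duty_off_min < 0:
            raise ValueError("duty_off_min must be >= 0")

    @property
    def recorded_minutes_per_hour(self) -> float:
        return 60.0 * self.duty_on_min / (self.duty_on_min + self.duty_off_min)

    @property
    def recorded_minutes_per_day(self) -> float:
        return 24.0 * self.recorded_minutes_per_hour


def parse_filename_timestamp(
    path: str | Path, regex: str = DEFAULT_TIMESTAMP_REGEX
) -> datetime | None:
    """Extract a UTC start time from a filename, or ``None`` if absent."""
    m = re.search(regex, Path(path).name)
    if m is None:
        return None
    token = re.sub(r"[-:T_ ]", "", m.group("ts") if m.groupdict().get("ts") else m.group(0))
    try:
        return datetime.strptime(token, "%Y%m%d%H%M%S")
    except ValueError:
        return None


def read_wav(
    path: str | Path,
    *,
    start_time: datetime | None = None,
    source_id: str | None = None,
    timestamp_regex: str = DEFAULT_TIMESTAMP_REGEX,
) -> Waveform:
    """Read a PCM WAV file into a full-scale (±1) normalized :class:`Waveform`.

    Integer PCM is divided by its full-scale value; float WAVs are taken as
    already normalized.  Multi-channel files keep the first channel only (the
    deployed hydrophones are single-channel).  The recording epoch comes from
    ``start_time`` if given, else from the filename timestamp convention;
    failing both, it is left as ``None`` (unknown epoch).
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # wavfile warns on unknown chunks
            rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - normalize into one error type
        raise AudioFormatError(f"unreadable WAV file {path}: {exc}") from exc

    if data.ndim == 2:
        warnings.warn(
            f"{path.name}: {data.shape[1]} channels; using the first",
            stacklevel=2,
        )
        data = data[:, 0]

    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")

    if start_time is None:
        start_time = parse_filename_timestamp(path, timestamp_regex)
    return Waveform(
        samples=samples,
        rate_hz=int(rate),
        start_time=start_time,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV, clipping to full scale."""
    clipped = np.clip(waveform.samples, -1.0, 1.0 - 2.0**-15)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(Path(path), waveform.rate_hz, pcm)


def resample_to_96k(w: Waveform) -> Waveform:
    """Bring a waveform to the 96 kHz working rate.

    Rates above 96 kHz are reduced by polyphase rational resampling (a
    Kaiser-windowed low-pass at the output Nyquist followed by rate
    conversion), which handles every recorder rate exactly: 192 kHz reduces
    to plain decimation by two, while 128 and 512 kHz use ratios 3/4 and
    3/16.  Upsampling is refused — material below 96 kHz lacks the analysis
    band and would only alias the class definitions.
    """
    if w.rate_hz == WORKING_RATE_HZ:
        return w
    if w.rate_hz < WORKING_RATE_HZ:
        raise ValueError(
            f"refusing to upsample {w.rate_hz} Hz to {WORKING_RATE_HZ} Hz"
        )
    if w.rate_hz not in KNOWN_RATES_HZ:
        warnings.warn(
            f"unusual input rate {w.rate_hz} Hz; resampling anyway",
            stacklevel=2,
        )
    ratio = Fraction(WORKING_RATE_HZ, w.rate_hz)
    out = resample_poly(w.samples, ratio.numerator, ratio.denominator)
    return Waveform(
        samples=out,
        rate_hz=WORKING_RATE_HZ,
        start_time=w.start_time,
        source_id=w.source_id,
    )


def segment_waveform(w: Waveform) -> list[Segment]:
    """Cut a 96 kHz waveform into contiguous, non-overlapping 5-s segments.

    The trailing remainder shorter than 5 s is dropped: the classifier
    contract is a fixed-length input and padding would distort class
    statistics.  Segment ``start_time`` advances by exactly 5 s per index;
    duty-cycle gaps must be represented as separate recordings.
    """
    if w.rate_hz != WORKING_RATE_HZ:
        raise ValueError(
            f"segment_waveform expects {WORKING_RATE_HZ} Hz input, "
            f"got {w.rate_hz}; call resample_to_96k first"
        )
    n_segments = w.samples.size // SEGMENT_SAMPLES
    segments = []
    for i in range(n_segments):
        chunk = w.samples[i * SEGMENT_SAMPLES : (i + 1) * SEGMENT_SAMPLES]
        t0 = (
            w.start_time + timedelta(seconds=SEGMENT_SECONDS * i)
            if w.start_time is not None
            else None
        )
        segments.append(
            Segment(
                waveform=Waveform(
                    samples=chunk,
                    rate_hz=WORKING_RATE_HZ,
                    start_time=t0,
                    source_id=w.source_id,
                ),
                index=i,
                start_time=t0,
            )
        )
    return segments


def read_schedule_csv(path: str | Path) -> pd.DataFrame:
    """Read a recording-schedule table.

    Expected columns: ``source_id, date, recorded_minutes, duty_on_min,
    duty_off_min``; ``date`` is parsed to a date.
    """
    df = pd.read_csv(path)
    required = {"source_id", "date", "recorded_minutes", "duty_on_min", "duty_off_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
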