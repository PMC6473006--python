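"""Reading and writing two-channel frontopolar EEG recordings.

The package's in-memory representation is :class:`EEGRecording`: two
voltage series (µV) at a common sampling rate with optional event markers
delimiting test segments.  On disk a recording is either

* a two-column CSV with header ``time_s, af7_fpz_uV, af8_fpz_uV``, or
* a 16-bit EDF file (one data record per second).

Event markers travel in a sidecar CSV (``label, sample_index``) for both
formats.  EDF files are read through :mod:`mne`; writing uses a minimal
EDF writer implemented here, which keeps the write→read round trip an
independent cross-check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CHANNEL_LABELS = ("AF7-FpZ", "AF8-FpZ")
CSV_HEADER = ["time_s", "af7_fpz_uV", "af8_fpz_uV"]

__all__ = [
    "EEGRecording",
    "Segment",
    "FormatError",
    "MarkerError",
    "read_recording",
    "write_recording",
    "extract_segment",
]


from .errors import FormatError, MarkerError  # noqa: E402  (re-exported)


@dataclass
class EEGRecording:
    """Two-channel voltage series in µV with event markers.

    Sample intervals are 0-based and half-open throughout the package.
    """

    data: np.ndarray  # shape (2, n_samples), µV
    fs: float
    channels: tuple[str, str] = CHANNEL_LABELS
    markers: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise FormatError(
                f"expected (2, n_samples) data, got shape {self.data.shape}"
            )
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[1]
        for label, idx in self.markers:
            if not 0 <= idx <= n:
                raise MarkerError(f"marker {label!r} at {idx} outside [0, {n}]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), markers=list(self.markers))


@dataclass(frozen=True)
class Segment:
    """Half-open sample span ``[start_sample, end_sample)`` of a recording."""

    recording: EEGRecording
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        n = self.recording.n_samples
        if not 0 <= self.start_sample < self.end_sample <= n:
            raise MarkerError(
                f"invalid segment [{self.start_sample}, {self.end_sample}) "
                f"for a {n}-sample recording"
            )

    @property
    def data(self) -> np.ndarray:
        return self.recording.data[:, self.start_sample : self.end_sample]

    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(rec: EEGRecording, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    arr = np.column_stack([t, rec.data[0], rec.data[1]])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for row in arr:
            w.writerow([f"{row[0]:.9g}", f"{row[1]:.9g}", f"{row[2]:.9g}"])


def _read_csv(path: Path) -> EEGRecording:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CSV_HEADER:
            raise FormatError(
                f"{path}: expected header {CSV_HEADER}, got {header}"
            )
        try:
            rows = np.array([[float(v) for v in row] for row in reader])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: non-numeric or ragged rows") from exc
    if rows.ndim != 2 or rows.shape[1] != 3 or rows.shape[0] < 2:
        raise FormatError(f"{path}: need >=2 rows of 3 columns")
    dt = np.diff(rows[:, 0])
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: non-uniform sampling in time_s column")
    fs = 1.0 / dt[0]
    # snap to integer Hz when the time stamps were printed at finite precision
    if abs(fs - round(fs)) < 1e-3:
        fs = float(round(fs))
    return EEGRecording(data=rows[:, 1:3].T, fs=fs)


# ---------------------------------------------------------------------------
# EDF (16-bit, one data record per second)
# ---------------------------------------------------------------------------

_DIG_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n = rec.n_samples
    if n % spr != 0:
        raise FormatError(
            "EDF writer requires a whole number of 1-s data records; "
            f"got {n} samples at {spr} Hz"
        )
    n_records = n // spr
    # symmetric physical range; one EDF quantum is pmax/32767
    pmax = float(np.ceil(max(1.0, np.abs(rec.data).max()) + 1.0))
    pmin = -pmax
    ns = 2

    hdr = b"".join([
        _edf_field(0, 8),
        _edf_field("synthetic subject", 80),
        _edf_field("frontopolar qEEG", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(f"EEG {ch}", 16) for ch in rec.channels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{pmin:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{pmax:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(-_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_edf_field(_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(spr, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])

    scale = _DIG_MAX / pmax
    digital = np.clip(np.rint(rec.data * scale), -_DIG_MAX, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # signal 0 then signal 1 per record


def _read_edf(path: Path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed headers
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    wanted = [f"EEG {ch}" for ch in CHANNEL_LABELS]
    names = raw.ch_names
    picks = []
    for w, ch in zip(wanted, CHANNEL_LABELS):
        if w in names:
            picks.append(w)
        elif ch in names:
            picks.append(ch)
        else:
            raise FormatError(f"{path}: missing channel {ch!r} (have {names})")
    data = raw.get_data(picks=picks) * 1e6  # mne loads Volts
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _marker_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".markers.csv")


def write_recording(rec: EEGRecording, path, format: str = "csv") -> Path:
    """Write a recording (and its markers, if any) to disk.

    Returns the path written.  ``format`` is ``"csv"`` or ``"edf"``.
    """
    path = Path(path)
    if format == "csv":
        _write_csv(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if rec.markers:
        with open(_marker_sidecar(path), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "sample_index"])
            for label, idx in rec.markers:
                w.writerow([label, idx])
    return path


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read a recording from CSV or EDF; ``format`` inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    rec = _read_edf(path) if format == "edf" else _read_csv(path)
    sidecar = _marker_sidecar(path)
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            reader = csv.DictReader(fh)
            rec.markers = [
                (row["label"], int(row["sample_index"])) for row in reader
            ]
        # re-validate marker bounds
        EEGRecording(rec.data, rec.fs, rec.channels, rec.markers)
    return rec


def extract_segment(
    rec: EEGRecording, marker_label: str, repeat: str = "first"
) -> Segment:
    """Return the sample span between ``<label>_begin`` and ``<label>_end``.

    When the protocol repeats the test (eyes-closed appears twice in the
    standard sequence), ``repeat`` selects ``"first"`` (default),
    ``"second"``, or ``"concatenate"`` — concatenation returns a segment
    over a new recording whose data is the two spans joined end to end.
    """
    begins = [i for lbl, i in rec.markers if lbl == f"{marker_label}_begin"]
    ends = [i for lbl, i in rec.markers if lbl == f"{marker_label}_end"]
    if not begins or not ends:
        raise MarkerError(f"no {marker_label!r} begin/end marker pair found")
    if len(begins) != len(ends):
        raise MarkerError(
            f"unmatched {marker_label!r} markers: "
            f"{len(begins)} begins vs {len(ends)} ends"
        )
    spans = sorted(zip(begins, ends))
    for b, e in spans:
        if not b < e:
            raise MarkerError(f"crossed markers: begin {b} !< end {e}")
    if repeat == "first":
        b, e = spans[0]
        return Segment(rec, b, e)
    if repeat == "second":
        if len(spans) < 2:
            raise MarkerError("repeat='second' but only one span present")
        b, e = spans[1]
        return Segment(rec, b, e)
    if repeat == "concatenate":
        joined = np.concatenate([rec.data[:, b:e] for b, e in spans], axis=1)
        cat = EEGRecording(joined, rec.fs, rec.channels)
        return Segment(cat, 0, joined.shape[1])
    raise ValueError(f"unknown repeat policy {repeat!r}")
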