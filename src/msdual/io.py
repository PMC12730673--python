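"""EEG container, EDF+ input/output and minimal signal conditioning.

The analysis operates on multichannel scalp EEG stored in EDF/EDF+ files.
Preprocessing is deliberately minimal: a zero-phase 0.5-50 Hz band-pass
and conversion to the common average reference, which the topographic
quantities (global field power, spatial correlation, map dissimilarity)
mathematically require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._edf import write_edf


@dataclass
class EEGRecording:
    """A channels x samples voltage matrix with metadata.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels, in storage order.
    annotations : list of (onset_s, duration_s, label)
        Event markers (e.g. rest/task windows).
    reference : {"raw", "average"}
        Whether the data have been re-referenced to the common average.
    """

    data: np.ndarray
    fs: float
    ch_names: list
    annotations: list = field(default_factory=list)
    reference: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel-name count does not match data")
        for onset, dur, _ in self.annotations:
            if onset < 0 or onset + dur > self.duration + 1e-9:
                raise ValueError("annotation outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def copy(self) -> "EEGRecording":
        return replace(
            self, data=self.data.copy(), annotations=list(self.annotations)
        )

    def sample_window(self, onset_s: float, duration_s: float) -> np.ndarray:
        """Slice (view) of the data for a time window."""
        i0 = int(round(onset_s * self.fs))
        i1 = int(round((onset_s + duration_s) * self.fs))
        return self.data[:, i0:i1]


def read_recording(path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    Channel order and annotations are preserved as stored.  Raises
    ``ValueError`` for unreadable or truncated files and for mixed
    per-channel sampling rates.
    """
    import os

    import mne

    # validate the declared record count against the file size: a
    # truncated file must fail loudly, not be read as a shorter recording
    try:
        with open(path, "rb") as fh:
            head = fh.read(256)
            if len(head) < 256:
                raise ValueError("EDF header truncated")
            header_bytes = int(head[184:192].decode("ascii", "replace"))
            n_rec = int(head[236:244].decode("ascii", "replace"))
            n_sig = int(head[252:256].decode("ascii", "replace"))
            sig_head = fh.read(header_bytes - 256)
            spr_field = sig_head[n_sig * 216: n_sig * 216 + n_sig * 8]
            spr = [int(spr_field[i * 8:(i + 1) * 8]) for i in range(n_sig)]
    except (OSError, UnicodeDecodeError) as exc:
        raise ValueError(f"could not read EDF header of {path}: {exc}") from exc
    expected = header_bytes + n_rec * 2 * sum(spr)
    actual = os.path.getsize(path)
    if actual < expected:
        raise ValueError(
            f"EDF file {path} is truncated ({actual} < {expected} bytes)")

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various concrete types
        raise ValueError(f"could not read EDF file {path}: {exc}") from exc
    if getattr(raw, "_raw_extras", None):
        extras = raw._raw_extras[0]
        n_samps = extras.get("n_samps")
        if n_samps is not None:
            sel = [i for i, ch in enumerate(extras.get("ch_names", raw.ch_names))
                   if ch != "EDF Annotations"]
            rates = {int(n_samps[i]) for i in sel} if len(n_samps) else set()
            if len(rates) > 1:
                raise ValueError("mixed per-channel sampling rates are unsupported")
    annotations = [
        (float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        annotations=annotations,
        reference="raw",
    )


def write_recording(rec: EEGRecording, path) -> None:
    """Write a recording as a 16-bit EDF+C file (physical units uV)."""
    write_edf(path, rec.data, rec.fs, rec.ch_names, rec.annotations)


def bandpass_filter(rec: EEGRecording, low: float = 0.5, high: float = 50.0,
                    order: int = 5) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    ``high`` must lie below the Nyquist frequency.  The default passband
    (0.5-50 Hz) is the conventional broad-band EEG range; the default
    order (5 per band edge, doubled by the forward-backward pass) is the
    lowest that attenuates 60 Hz line noise by more than 20 dB when
    sampling at 250 Hz.
    """
    if high >= rec.fs / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist ({rec.fs / 2} Hz)")
    if low <= 0 or low >= high:
        raise ValueError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return out


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous channel mean from every sample."""
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    out.reference = "average"
    return out


def to_csv(rec: EEGRecording, path) -> None:
    """Export as samples x channels CSV with a channel-label header row."""
    pd.DataFrame(rec.data.T, columns=rec.ch_names).to_csv(path, index=False)


def from_csv(path, fs: float, annotations=None) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(
        data=df.to_numpy().T,
        fs=fs,
        ch_names=list(df.columns),
        annotations=list(annotations or []),
    )
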