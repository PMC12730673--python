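"""Minimal EDF+ (continuous) writer.

Writes 16-bit EDF+C files with one annotation channel carrying
time-stamped annotation lists (TALs).  Data records are one second long;
recordings whose length is not a whole number of seconds are zero-padded
in the final record (the reader cannot distinguish padding, so callers
should stick to whole-second recordings).

Reading is delegated to :func:`mne.io.read_raw_edf` elsewhere; this module
only exists because no EDF *writer* is part of the dependency stack.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # try shortened float representation
        s = f"{float(value):.{max(0, width - 8)}g}"[:width]
    return s.ljust(width).encode("ascii")


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("non-finite values cannot be written to EDF")
    if hi - lo < 1e-9:
        lo, hi = lo - 1.0, hi + 1.0
    # keep the printed header representation short but lossless enough
    return lo, hi


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    ch_names,
    annotations=(),
    physical_dim: str = "uV",
) -> None:
    """Write ``data`` (n_channels, n_samples, physical units) as EDF+C.

    ``annotations`` is an iterable of (onset_s, duration_s, label).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel-name count does not match data")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = int(math.ceil(n_samp / spr))

    # --- per-record annotation TALs -------------------------------------
    tals = []
    for k in range(n_rec):
        chunks = [f"+{k}\x14\x14\x00".encode("ascii")]
        for onset, dur, label in annotations:
            if k <= onset < k + 1:
                chunks.append(
                    f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("utf-8")
                )
        tals.append(b"".join(chunks))
    ann_bytes = max(max(len(t) for t in tals) + 2, 16)
    ann_bytes += ann_bytes % 2  # int16 alignment
    ann_spr = ann_bytes // 2

    n_sig = n_ch + 1
    phys = [_phys_range(data[c]) for c in range(n_ch)]

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate 01-JAN-2000 X X X", 80),
            _fixed(now.strftime("%d.%m.%y"), 8),
            _fixed(now.strftime("%H.%M.%S"), 8),
            _fixed(256 * (n_sig + 1), 8),
            _fixed("EDF+C", 44),
            _fixed(n_rec, 8),
            _fixed(1, 8),
            _fixed(n_sig, 4),
        ]
    )

    labels = [str(c)[:16] for c in ch_names] + ["EDF Annotations"]
    fields = [
        b"".join(_fixed(lab, 16) for lab in labels),
        b"".join(_fixed("", 80) for _ in range(n_sig)),
        b"".join(_fixed(physical_dim, 8) for _ in range(n_ch)) + _fixed("", 8),
        b"".join(_fixed(f"{lo:.8g}"[:8], 8) for lo, _ in phys) + _fixed(-1, 8),
        b"".join(_fixed(f"{hi:.8g}"[:8], 8) for _, hi in phys) + _fixed(1, 8),
        b"".join(_fixed(_DIG_MIN, 8) for _ in range(n_sig)),
        b"".join(_fixed(_DIG_MAX, 8) for _ in range(n_sig)),
        b"".join(_fixed("", 80) for _ in range(n_sig)),
        b"".join(_fixed(spr, 8) for _ in range(n_ch)) + _fixed(ann_spr, 8),
        b"".join(_fixed("", 32) for _ in range(n_sig)),
    ]

    # --- digitize --------------------------------------------------------
    # re-read the printed physical range so quantization is self-consistent
    phys_hdr = [(float(f"{lo:.8g}"[:8]), float(f"{hi:.8g}"[:8])) for lo, hi in phys]
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    digital = np.empty_like(padded, dtype="<i2")
    for c in range(n_ch):
        lo, hi = phys_hdr[c]
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        dig = np.rint((np.clip(padded[c], lo, hi) - lo) * scale) + _DIG_MIN
        digital[c] = dig.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for k in range(n_rec):
            fh.write(digital[:, k * spr : (k + 1) * spr].tobytes())
            fh.write(tals[k].ljust(ann_bytes, b"\x00"))
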