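"""Minimal EDF (16-bit) writer.

Covers the plain-EDF subset needed to archive sessions: one fixed sampling
rate for all signals, physical dimensions µV (EEG/EMG) or V (force), 1 s data
records when the rate is integer (one whole-file record otherwise).
"""

from __future__ import annotations

import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.3g}"):
        if len(fmt) <= width:
            return _fixed(fmt, width)
    raise ValueError(f"cannot format {value} in {width} EDF header chars")


def write_edf(rec, path: str | Path, phys_range=None) -> None:
    """Write ``rec`` to ``path`` as 16-bit EDF.

    phys_range : optional (min, max) per file; samples outside are clipped
        with a warning. Defaults to the per-channel data range.
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    if n_samp == 0:
        raise ValueError("empty recording")

    if float(rec.fs).is_integer() and n_samp % int(rec.fs) == 0:
        spr = int(rec.fs)  # samples per 1 s record
        n_rec, rec_dur = n_samp // spr, 1.0
    else:
        spr, n_rec, rec_dur = n_samp, 1, n_samp / rec.fs

    data = rec.data.copy()
    pmins = np.empty(n_ch)
    pmaxs = np.empty(n_ch)
    clipped = 0
    for i in range(n_ch):
        if phys_range is not None:
            lo, hi = phys_range
            n_out = int(np.sum((data[i] < lo) | (data[i] > hi)))
            if n_out:
                clipped += n_out
                data[i] = np.clip(data[i], lo, hi)
        else:
            lo, hi = data[i].min(), data[i].max()
            if hi - lo < 1e-12:  # constant channel: widen to a valid range
                lo, hi = lo - 1.0, hi + 1.0
        span = max(hi - lo, 1e-9)
        lo, hi = lo - 2e-3 * span, hi + 2e-3 * span
        # store the range exactly as the 8-char header field will carry it,
        # so writer quantization and reader dequantization use the same gain
        pmins[i] = float(_num(lo, 8))
        pmaxs[i] = float(_num(hi, 8))
        if pmaxs[i] <= pmins[i]:
            pmaxs[i] = pmins[i] + 1.0
    if clipped:
        warnings.warn(
            f"EDF physical range clipped {clipped} samples", RuntimeWarning
        )
        rec.meta.setdefault("edf_clipped_samples", clipped)

    gains = (pmaxs - pmins) / (DIG_MAX - DIG_MIN)
    digital = np.round((data - pmins[:, None]) / gains[:, None]) + DIG_MIN
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    now = datetime.now(timezone.utc)
    header = b"".join([
        _fixed("0", 8),
        _fixed("X X X X", 80),
        _fixed("Startdate X X X X", 80),
        _fixed(now.strftime("%d.%m.%y"), 8),
        _fixed(now.strftime("%H.%M.%S"), 8),
        _num(256 * (1 + n_ch), 8),
        _fixed("", 44),
        _num(n_rec, 8),
        _num(rec_dur, 8),
        _num(n_ch, 4),
    ])
    dims = ["uV" if t in ("EEG", "EMG") else "V" for t in rec.ch_types]
    per_sig = b"".join([
        b"".join(_fixed(l, 16) for l in rec.labels),
        b"".join(_fixed("", 80) for _ in range(n_ch)),
        b"".join(_fixed(d, 8) for d in dims),
        b"".join(_num(v, 8) for v in pmins),
        b"".join(_num(v, 8) for v in pmaxs),
        b"".join(_num(DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_num(DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_fixed("", 80) for _ in range(n_ch)),
        b"".join(_num(spr, 8) for _ in range(n_ch)),
        b"".join(_fixed("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())  # signal-major within each record
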