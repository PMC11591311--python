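"""Tri-axial acceleration to per-minute body rhythm.

A badge records acceleration near the upper body at 50 Hz on three axes.
The per-sample Euclidean norm is reduced, per 10-second window, to the
number of times it crosses the window mean; the per-minute *body rhythm*
(BR, in Hz) is the mean over the minute's windows of

    crossings / (2 * window_seconds)

so that a pure f-Hz sinusoid maps to f.  The convention places everyday
activities on an interpretable scale: 0-1 Hz sedentary screen work,
1-2 Hz talking or typing, 2-3 Hz animated talking or walking, 3-4 Hz
excited discussion or rushed walking, >4 Hz running.

Samples exactly equal to the window mean neither create nor absorb
crossings: a crossing is counted when the nearest non-mean samples on
each side have opposite signs.  This keeps the count stable on quantized
sensors that can sit exactly on the mean for several samples.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 50.0
WINDOW_SECONDS = 10.0
#: A sinusoid crosses its mean twice per cycle.
CROSSINGS_PER_CYCLE = 2.0
WINDOWS_PER_MINUTE = 6


def euclidean_norm(samples: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of an (n, 3) acceleration array."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("empty acceleration window")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) tri-axial samples, got shape {arr.shape}")
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


def mean_crossing_count(values: Sequence[float] | np.ndarray) -> int:
    """Count sign alternations of ``values`` about their own mean.

    Samples equal to the mean are skipped; the count is the number of
    strict sign changes in the remaining sequence.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d series of length >= 2 to count crossings")
    signs = np.sign(x - x.mean())
    signs = signs[signs != 0.0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def body_rhythm_window(values: Sequence[float] | np.ndarray,
                       window_seconds: float = WINDOW_SECONDS) -> float:
    """BR contribution of one window: crossings / (2 * window_seconds)."""
    return mean_crossing_count(values) / (CROSSINGS_PER_CYCLE * window_seconds)


def body_rhythm_minute(windows: Iterable[Sequence[float] | np.ndarray],
                       window_seconds: float = WINDOW_SECONDS) -> float:
    """Average the per-window BR of one minute's windows (1-6 of them).

    Partial minutes are valid: the mean is over the windows present.
    Raises ``ValueError`` when no window is available (the minute is then
    absent from the series, never zero-filled).
    """
    rates = [body_rhythm_window(w, window_seconds) for w in windows]
    if not rates:
        raise ValueError("no windows in minute; minute must be absent, not zero")
    return float(np.mean(rates))


def minute_series_from_norm(norm: np.ndarray,
                            sample_rate_hz: float = SAMPLE_RATE_HZ,
                            window_seconds: float = WINDOW_SECONDS,
                            start_minute: int = 0) -> dict[int, float]:
    """Reduce a contiguous norm-acceleration stream to per-minute BR.

    The stream is cut into ``window_seconds`` windows; each group of six
    windows forms one minute starting at ``start_minute``.  Trailing
    windows with fewer than two samples are dropped.
    """
    per_window = int(round(sample_rate_hz * window_seconds))
    n_windows = int(np.ceil(norm.size / per_window))
    out: dict[int, list[np.ndarray]] = {}
    for w in range(n_windows):
        chunk = norm[w * per_window:(w + 1) * per_window]
        if chunk.size < 2:
            continue
        minute = start_minute + (w * int(window_seconds)) // 60
        out.setdefault(minute, []).append(chunk)
    return {m: body_rhythm_minute(chunks, window_seconds)
            for m, chunks in sorted(out.items())}


def minute_series_from_raw(raw: pd.DataFrame,
                           sample_rate_hz: float = SAMPLE_RATE_HZ,
                           window_seconds: float = WINDOW_SECONDS) -> pd.DataFrame:
    """Per-minute BR from a raw stream with columns minute, ax, ay, az.

    Samples are grouped by their minute stamp; each minute is split into
    consecutive 10-s windows by sample order.  Returns a frame with
    columns ``minute`` and ``br_hz``.
    """
    required = {"minute", "ax", "ay", "az"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw acceleration frame missing columns {sorted(missing)}")
    rows = []
    per_window = int(round(sample_rate_hz * window_seconds))
    for minute, grp in raw.groupby("minute", sort=True):
        norm = euclidean_norm(grp[["ax", "ay", "az"]].to_numpy())
        windows = [norm[k:k + per_window] for k in range(0, norm.size, per_window)]
        windows = [w for w in windows if w.size >= 2]
        if not windows:
            continue
        rows.append((int(minute), body_rhythm_minute(windows, window_seconds)))
    return pd.DataFrame(rows, columns=["minute", "br_hz"])


def read_rhythm_csv(path) -> pd.DataFrame:
    """Read a (person_id, minute, br_hz) delimited-text body-rhythm table."""
    df = pd.read_csv(path)
    required = {"person_id", "minute", "br_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rhythm table missing columns {sorted(missing)}")
    return df


def write_rhythm_csv(series: Mapping[int, Mapping[int, float]] | pd.DataFrame, path) -> None:
    """Write body-rhythm series as delimited text (person_id, minute, br_hz)."""
    if isinstance(series, pd.DataFrame):
        df = series
    else:
        rows = [(pid, m, v) for pid, vals in series.items() for m, v in sorted(vals.items())]
        df = pd.DataFrame(rows, columns=["person_id", "minute", "br_hz"])
    df.to_csv(path, index=False)
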