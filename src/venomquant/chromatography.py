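"""Chromatogram processing: baseline estimation, peak picking, integration.

The trace is a 214 nm absorbance signal sampled along time.  The baseline
is a rolling-minimum envelope interpolated linearly between its anchor
points; peaks are local maxima of the baseline-corrected signal with a
prominence threshold, bounded at the deepest valley between adjacent
apexes; areas are trapezoidal integrals of the corrected (non-negative)
signal.  Peaks flagged as contaminants can be excluded, after which the
remaining fractions are renormalised — excluded material simply leaves the
denominator, as when a non-venom impurity elutes in its own peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks as _scipy_find_peaks

from .records import InputError, ParameterError

PEAK_COLUMNS = [
    "peak_id", "start_min", "apex_min", "end_min",
    "start_idx", "apex_idx", "end_idx",
    "raw_area", "corrected_area", "excluded", "fraction",
]


@dataclass(frozen=True)
class ChromatogramTrace:
    """A validated time/absorbance trace (minutes, mAU at 214 nm)."""

    time: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise InputError("time and absorbance must be equal-length vectors")
        if len(t) < 3:
            raise InputError("trace needs at least 3 samples")
        if not np.all(np.diff(t) > 0):
            raise InputError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)

    @property
    def span_min(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


def read_trace(path) -> ChromatogramTrace:
    """Read a two-column (time_min, absorbance) CSV into a trace.

    The header row is optional.  Malformed rows raise a parse error naming
    the offending line.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    rows = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln:
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise InputError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1:  # header
                continue
            raise InputError(f"line {lineno}: non-numeric value in {ln!r}") from None
    if not rows:
        raise InputError("no samples")
    t, a = zip(*rows)
    return ChromatogramTrace(np.array(t), np.array(a))


def estimate_baseline(trace: ChromatogramTrace, window: float = 6.0) -> np.ndarray:
    """Rolling-minimum baseline with linear interpolation between minima.

    ``window`` is in minutes and should exceed the widest peak's footprint;
    a window that does not cover at least one sample degenerates to
    ``baseline == trace``.  The result is clipped to lie at or below the
    trace pointwise.
    """
    if window <= 0:
        raise ParameterError("window must be > 0")
    if window > trace.span_min:
        raise ParameterError(
            f"window {window} min exceeds trace span {trace.span_min:.3g} min"
        )
    dt = float(np.median(np.diff(trace.time)))
    k = int(round(window / dt))
    if k <= 1:
        return trace.absorbance.copy()
    sig = trace.absorbance
    if k % 2 == 0:  # symmetric window, else the opening shifts by a sample
        k += 1
    # Anchor points are samples that realise the minimum of at least one
    # window, i.e. where the morphological opening equals the signal; under
    # a peak the opening drops below the signal and no anchor exists, so the
    # baseline is interpolated straight across from the flanking minima.
    opened = maximum_filter1d(
        minimum_filter1d(sig, size=k, mode="nearest"), size=k, mode="nearest"
    )
    tol = 1e-9 * (1.0 + np.abs(sig))
    anchors = np.flatnonzero(sig <= opened + tol)
    # the endpoints can never be window minima on a sloping baseline; a
    # trace is assumed to start and end off-peak
    anchors = np.union1d(anchors, [0, len(sig) - 1])
    baseline = np.interp(trace.time, trace.time[anchors], sig[anchors])
    return np.minimum(baseline, sig)


def detect_peaks(
    trace: ChromatogramTrace,
    baseline: np.ndarray,
    min_prominence: float | None = None,
    min_area_fraction: float = 0.001,
) -> pd.DataFrame:
    """Detect peaks in the baseline-corrected signal (areas left unfilled).

    Apexes are local maxima with prominence at least ``min_prominence``
    (default: 1% of the maximum corrected signal).  Peak boundaries sit at
    the deepest valley between adjacent apexes (earliest sample on ties);
    the outermost boundaries at the deepest points flanking the first and
    last apex.  ``min_area_fraction`` is applied later, at integration.
    """
    if min_prominence is not None and min_prominence < 0:
        raise ParameterError("min_prominence must be >= 0")
    if not 0 <= min_area_fraction < 1:
        raise ParameterError("min_area_fraction must be in [0, 1)")
    corrected = trace.absorbance - np.asarray(baseline, dtype=float)
    if min_prominence is None:
        top = float(corrected.max(initial=0.0))
        min_prominence = 0.01 * top
    empty = pd.DataFrame(columns=PEAK_COLUMNS)
    empty.attrs["min_area_fraction"] = min_area_fraction
    if not np.any(corrected > 0):
        return empty
    apexes, _ = _scipy_find_peaks(corrected, prominence=min_prominence or None)
    if len(apexes) == 0:
        return empty

    bounds = [int(np.argmin(corrected[: apexes[0] + 1]))]
    for a, b in zip(apexes, apexes[1:]):
        bounds.append(int(a + np.argmin(corrected[a : b + 1])))
    bounds.append(int(apexes[-1] + np.argmin(corrected[apexes[-1] :])))

    rows = []
    for i, apex in enumerate(apexes):
        rows.append(
            {
                "peak_id": f"P{i + 1}",
                "start_min": trace.time[bounds[i]],
                "apex_min": trace.time[apex],
                "end_min": trace.time[bounds[i + 1]],
                "start_idx": bounds[i],
                "apex_idx": int(apex),
                "end_idx": bounds[i + 1],
                "raw_area": np.nan,
                "corrected_area": np.nan,
                "excluded": False,
                "fraction": np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    table.attrs["min_area_fraction"] = min_area_fraction
    return table


def integrate_peaks(
    trace: ChromatogramTrace, baseline: np.ndarray, peaks: pd.DataFrame
) -> pd.DataFrame:
    """Fill in trapezoidal areas and fractions for detected peaks.

    ``corrected_area`` integrates the baseline-corrected signal clipped at
    zero over [start, end]; adjacent peaks share the valley sample, which
    conserves total area exactly under the trapezoid rule.  Peaks whose
    fraction falls below the table's ``min_area_fraction`` are dropped and
    fractions recomputed over the survivors.
    """
    if len(peaks) == 0:
        raise InputError("no integrable signal: empty peak table")
    corrected = np.clip(trace.absorbance - np.asarray(baseline, dtype=float), 0, None)
    peaks = peaks.copy()
    raw_areas, areas = [], []
    n = len(trace)
    for _, row in peaks.iterrows():
        s, e = int(row["start_idx"]), int(row["end_idx"])
        if not (0 <= s < e < n):
            raise InputError(f"peak {row['peak_id']}: boundaries outside trace")
        raw_areas.append(float(np.trapezoid(trace.absorbance[s : e + 1],
                                            trace.time[s : e + 1])))
        areas.append(float(np.trapezoid(corrected[s : e + 1],
                                        trace.time[s : e + 1])))
    peaks["raw_area"] = raw_areas
    peaks["corrected_area"] = areas
    total = sum(areas)
    if total <= 0:
        raise InputError("no integrable signal")
    peaks["fraction"] = peaks["corrected_area"] / total

    min_frac = peaks.attrs.get("min_area_fraction", 0.0)
    if min_frac > 0:
        keep = peaks["fraction"] >= min_frac
        if not keep.any():
            raise InputError("no integrable signal above min_area_fraction")
        peaks = peaks.loc[keep].reset_index(drop=True)
        peaks["fraction"] = peaks["corrected_area"] / peaks["corrected_area"].sum()
    peaks.attrs["min_area_fraction"] = min_frac
    return peaks


def exclude_and_renormalize(peaks: pd.DataFrame, excluded_ids) -> pd.DataFrame:
    """Flag the given peaks as excluded and renormalise the rest.

    Excluded peaks keep their areas but lose their fraction (set to NaN);
    the remaining fractions are renormalised to sum to 1.  Excluding every
    peak is an error.
    """
    peaks = peaks.copy()
    excluded_ids = list(excluded_ids)
    known = set(peaks["peak_id"])
    missing = [p for p in excluded_ids if p not in known]
    if missing:
        raise InputError(f"unknown peak ids in exclusion list: {missing}")
    mask = peaks["peak_id"].isin(excluded_ids)
    peaks.loc[mask, "excluded"] = True
    rest = ~peaks["excluded"].astype(bool)
    if not rest.any():
        raise InputError("cannot exclude every peak")
    total = peaks.loc[rest, "corrected_area"].sum()
    if total <= 0:
        raise InputError("no integrable signal among non-excluded peaks")
    peaks.loc[rest, "fraction"] = peaks.loc[rest, "corrected_area"] / total
    peaks.loc[~rest, "fraction"] = np.nan
    return peaks


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False)


def apply_manual_boundaries(
    trace: ChromatogramTrace, peaks: pd.DataFrame, boundaries: pd.DataFrame
) -> pd.DataFrame:
    """Override or add peak boundaries from a manual-boundaries table.

    ``boundaries`` has columns peak_id, start_min, end_min.  This supports
    operator-defined sub-peaks (shoulders the picker cannot separate);
    areas must be (re)computed afterwards with :func:`integrate_peaks`.
    """
    peaks = peaks.copy()
    for _, row in boundaries.iterrows():
        s_idx = int(np.searchsorted(trace.time, row["start_min"], side="left"))
        e_idx = int(np.searchsorted(trace.time, row["end_min"], side="right")) - 1
        if not (0 <= s_idx < e_idx < len(trace)):
            raise InputError(
                f"manual boundaries for {row['peak_id']} outside trace span"
            )
        apex = s_idx + int(np.argmax(trace.absorbance[s_idx : e_idx + 1]))
        new = {
            "peak_id": row["peak_id"],
            "start_min": trace.time[s_idx],
            "apex_min": trace.time[apex],
            "end_min": trace.time[e_idx],
            "start_idx": s_idx,
            "apex_idx": apex,
            "end_idx": e_idx,
            "raw_area": np.nan,
            "corrected_area": np.nan,
            "excluded": False,
            "fraction": np.nan,
        }
        if (peaks["peak_id"] == row["peak_id"]).any():
            peaks.loc[peaks["peak_id"] == row["peak_id"], list(new)] = list(
                new.values()
            )
        else:
            peaks = pd.concat([peaks, pd.DataFrame([new])], ignore_index=True)
    peaks = peaks.sort_values("start_min", ignore_index=True)
    return peaks
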