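"""Within-band MS1 intensity partitioning.

When a single gel band contains more than one toxin, its density fraction
is split among the co-banded toxins in proportion to their summed MS1
extracted-ion intensities.  Ion counts are only comparable within a single
LC-MS run, so rows mixing run ids are rejected outright; no normalisation
across bands or runs is ever performed.
"""

from __future__ import annotations

import pandas as pd

from .records import InputError

MS1_COLUMNS = ["band_id", "run_id", "toxin_id", "intensity"]


def partition_band(features: pd.DataFrame) -> pd.Series:
    """Per-toxin intensity fractions for one band's MS1 features.

    Rows are summed per toxin before ratio-taking (a toxin may contribute
    several peptide features).  Requires a single run id and at least one
    non-zero intensity.
    """
    if len(features) == 0:
        raise InputError("no MS1 features for band")
    runs = features["run_id"].unique()
    if len(runs) > 1:
        raise InputError(
            f"cross-run comparison forbidden: band has run ids {sorted(runs)}"
        )
    if (features["intensity"] < 0).any():
        raise InputError("MS1 intensities must be non-negative")
    sums = features.groupby("toxin_id", sort=True)["intensity"].sum()
    total = sums.sum()
    if total <= 0:
        raise InputError("all-zero MS1 intensities for band")
    out = sums / total
    out.name = "fraction"
    return out


def read_ms1(path) -> pd.DataFrame:
    """Read the MS1 features TSV."""
    ms1 = pd.read_csv(path, sep="\t")
    missing = [c for c in MS1_COLUMNS if c not in ms1.columns]
    if missing:
        raise InputError(f"MS1 table missing columns: {missing}")
    return ms1


def partition_all(ms1: pd.DataFrame) -> dict:
    """Partition every (peak, band) group in an MS1 table.

    Returns ``{(peak_id, band_id): {toxin_id: fraction}}``; the peak key
    falls back to the band id alone when no peak_id column is present.
    """
    keys = ["peak_id", "band_id"] if "peak_id" in ms1.columns else ["band_id"]
    out = {}
    for key, grp in ms1.groupby(keys):
        k = key if isinstance(key, tuple) else (key,)
        out[k] = partition_band(grp).to_dict()
    return out
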