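"""Gel-band densitometry: within-lane band fractions.

One gel lane corresponds to one chromatogram peak.  Band densities arrive
as already-integrated numbers from the gel imager; here they are turned
into within-lane fractions.  Unidentified bands count in the denominator —
material that ran on the gel but could not be matched to a protein keeps
its mass share and is routed to the uncharacterized remainder downstream.
"""

from __future__ import annotations

import pandas as pd

from .records import InputError

LANE_COLUMNS = ["lane_id", "peak_id", "band_id", "mass_kda", "density", "identified"]


def validate_lane(lane: pd.DataFrame) -> pd.DataFrame:
    """Validate a single lane's band rows."""
    if len(lane) == 0:
        raise InputError("lane has no bands")
    if lane["band_id"].duplicated().any():
        dup = lane.loc[lane["band_id"].duplicated(), "band_id"].tolist()
        raise InputError(f"duplicate band ids within lane: {dup}")
    if (lane["density"] < 0).any():
        raise InputError("band densities must be non-negative")
    return lane


def band_fractions(lane: pd.DataFrame) -> pd.Series:
    """Fraction of lane density per band (identified or not).

    Fractions sum to 1 over all bands in the lane; a lane with zero total
    density is an error ("empty lane").  Scale-invariant: multiplying all
    densities by a constant leaves the result unchanged.
    """
    validate_lane(lane)
    total = lane["density"].sum()
    if total <= 0:
        raise InputError("empty lane: zero total density")
    return pd.Series(
        (lane["density"] / total).to_numpy(),
        index=pd.Index(lane["band_id"], name="band_id"),
        name="fraction",
    )


def read_lanes(path) -> pd.DataFrame:
    """Read the lanes TSV (one row per band; lanes keyed by peak id)."""
    lanes = pd.read_csv(path, sep="\t")
    missing = [c for c in LANE_COLUMNS if c not in lanes.columns]
    if missing:
        raise InputError(f"lanes table missing columns: {missing}")
    for _, lane in lanes.groupby("lane_id"):
        validate_lane(lane)
    return lanes
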