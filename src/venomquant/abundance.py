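"""Hierarchical allocation of whole-venom abundance to toxins and families.

The three-case rule: a peak with a single toxin is quantified by peak
integration alone; a peak with several gel bands splits its fraction by
densitometry; a band with several toxins splits its share further by
within-run MS1 intensity.  Formally, for toxin t:

    fraction(t) = sum over (peak p, band b) of
                  peak_fraction(p) * band_fraction(b | p) * ms1_fraction(t | b)

with the last two factors equal to 1 whenever the corresponding level is a
singleton.  Unidentified bands and peaks without a lane keep their mass
share and accumulate into the *uncharacterized* remainder, so the toxin
fractions plus uncharacterized always sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import densitometry
from .records import InputError

CONSERVATION_TOL = 1e-9


class ConservationError(AssertionError):
    """Internal consistency failure: allocated fractions do not sum to 1."""


@dataclass
class AbundanceTable:
    """Per-toxin fractions of whole venom plus the uncharacterized remainder.

    ``provenance`` maps toxin id to the list of ``(peak_id, band_id,
    contribution)`` terms that were summed into its fraction.
    """

    fractions: dict  # toxin id -> fraction of whole venom
    uncharacterized: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions.values()) or self.uncharacterized < 0:
            raise InputError("fractions must be non-negative")
        total = math.fsum(self.fractions.values()) + self.uncharacterized
        if abs(total - 1.0) > CONSERVATION_TOL:
            raise ConservationError(
                f"toxin fractions + uncharacterized sum to {total!r}, not 1"
            )

    def to_frame(self, family_map: dict | None = None) -> pd.DataFrame:
        rows = [
            {
                "toxin_id": tid,
                "family": (family_map or {}).get(tid, ""),
                "fraction": frac,
                "provenance": ";".join(
                    f"{p}:{b}:{c:.6g}" for p, b, c in self.provenance.get(tid, [])
                ),
            }
            for tid, frac in sorted(
                self.fractions.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(rows)


def allocate(
    peaks: pd.DataFrame,
    lanes: pd.DataFrame,
    band_partitions: dict,
    band_toxins: dict,
) -> AbundanceTable:
    """Allocate peak fractions down the peak → band → toxin hierarchy.

    Parameters
    ----------
    peaks : DataFrame
        Integrated peak table with ``fraction`` filled and exclusions
        applied (excluded peaks have NaN fractions and are skipped).
    lanes : DataFrame
        Band rows for all lanes; lanes are keyed by ``peak_id``.
    band_partitions : dict
        ``(peak_id, band_id) -> {toxin_id: fraction}`` MS1 partitions;
        required for every band identified with more than one toxin.
    band_toxins : dict
        ``(peak_id, band_id) -> sequence of toxin ids`` identifications;
        a missing key or empty sequence marks the band unidentified.
    """
    by_peak = {pid: grp for pid, grp in lanes.groupby("peak_id")}
    contributions: dict[str, list] = {}
    unchar_terms: list[float] = []

    active = peaks.loc[~peaks["excluded"].astype(bool)]
    for _, peak in active.iterrows():
        pid = peak["peak_id"]
        pf = float(peak["fraction"])
        if math.isnan(pf):
            raise InputError(f"peak {pid}: fraction not computed")
        lane = by_peak.get(pid)
        if lane is None:
            # no gel lane for this peak: nothing identifiable in it
            unchar_terms.append(pf)
            continue
        bfs = densitometry.band_fractions(lane)
        for band_id, bf in bfs.items():
            toxins = list(band_toxins.get((pid, band_id), ()))
            term = pf * float(bf)
            if not toxins:
                unchar_terms.append(term)
            elif len(toxins) == 1:
                contributions.setdefault(toxins[0], []).append(
                    (pid, band_id, term)
                )
            else:
                part = band_partitions.get((pid, band_id))
                if part is None:
                    raise InputError(
                        f"band {pid}:{band_id} holds {len(toxins)} toxins "
                        "but has no MS1 partition"
                    )
                present = {t: part[t] for t in toxins if t in part}
                if not present:
                    raise InputError(
                        f"band {pid}:{band_id}: MS1 partition covers none of "
                        f"its toxins {toxins}"
                    )
                norm = math.fsum(present.values())
                for tid in toxins:
                    share = present.get(tid, 0.0) / norm
                    contributions.setdefault(tid, []).append(
                        (pid, band_id, term * share)
                    )

    fractions = {
        tid: math.fsum(c for _, _, c in terms)
        for tid, terms in contributions.items()
    }
    return AbundanceTable(
        fractions=fractions,
        uncharacterized=math.fsum(unchar_terms),
        provenance=contributions,
    )


def family_rollup(table: AbundanceTable, family_map: dict) -> pd.Series:
    """Exact per-family sums of member toxin fractions.

    Every toxin in the table must have a family label; the rollup is a
    plain sum with no re-rounding, so reported family totals are exactly
    the totals of their reported members.
    """
    sums: dict[str, list] = {}
    for tid, frac in table.fractions.items():
        fam = family_map.get(tid)
        if fam is None:
            raise InputError(f"toxin {tid!r} has no family assignment")
        sums.setdefault(fam, []).append(frac)
    rolled = pd.Series(
        {fam: math.fsum(v) for fam, v in sums.items()}, name="fraction", dtype=float
    )
    return rolled.sort_values(ascending=False)


def percent(x: float, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero (the convention used when a
    composition is reported to one decimal, e.g. 59.8%)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x) * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def report_text(
    table: AbundanceTable, family_map: dict, decimals: int = 1
) -> str:
    """One-page text report with percentages at the given precision."""
    lines = ["Venom composition (fraction of whole venom)", ""]
    lines.append("Per toxin:")
    for tid, frac in sorted(table.fractions.items(), key=lambda kv: -kv[1]):
        fam = family_map.get(tid, "?")
        lines.append(f"  {tid:<12} {fam:<8} {percent(frac, decimals):>6.{decimals}f}%")
    lines.append("")
    lines.append("Per family:")
    fams = family_rollup(table, family_map)
    for fam, frac in fams.items():
        lines.append(f"  {fam:<12} {percent(frac, decimals):>6.{decimals}f}%")
    lines.append("")
    lines.append(
        f"  {'uncharacterized':<12} "
        f"{percent(table.uncharacterized, decimals):>6.{decimals}f}%"
    )
    characterized = math.fsum(table.fractions.values())
    lines.append(f"  {'characterized':<12} {percent(characterized, decimals):>6.{decimals}f}%")
    return "\n".join(lines) + "\n"
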