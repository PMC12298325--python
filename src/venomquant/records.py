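"""Domain types shared across the quantification pipeline.

The controlled family vocabulary covers the toxin families recognised in
elapid venom-gland transcriptomes plus nerve growth factor (a minor venom
component) and a ``non-toxin`` label for everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

TOXIN_FAMILIES = (
    "PLA2",
    "3FTx",
    "SVMP",
    "SVSP",
    "CRiSP",
    "LAAO",
    "NP",
    "DIS",
    "KUN",
    "CTL",
    "endonuclease",
    "aminopeptidase",
    "kazal-type inhibitor",
    "insulin-like growth factor",
    "endopeptidase",
    "AChE",
    "peroxiredoxin",
    "aspartic protease",
    "sulfhydryl oxidase",
    "glutaminyl cyclase",
    "prokineticin",
    "NGF",
)
NON_TOXIN = "non-toxin"
FAMILY_VOCABULARY = TOXIN_FAMILIES + (NON_TOXIN,)


class ParameterError(ValueError):
    """A parameter violates its documented range or type."""


class InputError(ValueError):
    """An input object or file violates the pipeline's contracts."""


@dataclass(frozen=True)
class ToxinRecord:
    """A toxin (or contaminant protein) entry from the sequence database.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header id).
    family : str
        One of the controlled family labels (``FAMILY_VOCABULARY``).
    precursor : str
        Full precursor amino-acid sequence (signal peptide + mature chain).
    mature_start : int
        0-based index where the mature chain begins in ``precursor``.
    mass_kda : float
        Average mass of the mature chain in kDa.
    """

    id: str
    family: str
    precursor: str
    mature_start: int
    mass_kda: float

    def __post_init__(self) -> None:
        if not self.precursor:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.precursor) - set(AA_ALPHABET)
        if bad:
            raise InputError(
                f"record {self.id!r}: illegal residue letters {sorted(bad)}"
            )
        if not 0 <= self.mature_start < len(self.precursor):
            raise InputError(
                f"record {self.id!r}: mature_start {self.mature_start} outside "
                f"sequence of length {len(self.precursor)}"
            )
        if self.family not in FAMILY_VOCABULARY:
            raise InputError(f"record {self.id!r}: unknown family {self.family!r}")

    @property
    def mature(self) -> str:
        """Mature-chain sequence (precursor with the signal/propeptide trimmed)."""
        return self.precursor[self.mature_start :]


@dataclass(frozen=True)
class GradientProgram:
    """A piecewise-linear binary solvent gradient.

    ``segments`` is a sequence of ``(duration_min, start_pct_b, end_pct_b)``
    triples; consecutive segments must join continuously in %B.
    """

    segments: tuple
    flow_ml_min: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("gradient needs at least one segment")
        prev_end = None
        for dur, b0, b1 in self.segments:
            if dur <= 0:
                raise ParameterError("gradient segment durations must be > 0")
            for b in (b0, b1):
                if not 0 <= b <= 100:
                    raise ParameterError("%B must lie in [0, 100]")
            if prev_end is not None and not math.isclose(b0, prev_end, abs_tol=1e-9):
                raise ParameterError("gradient %B must be piecewise continuous")
            prev_end = b1
        if self.flow_ml_min <= 0:
            raise ParameterError("flow rate must be positive")

    @property
    def total_time_min(self) -> float:
        return sum(d for d, _, _ in self.segments)

    def percent_b(self, t: float) -> float:
        """%B at time ``t`` minutes (clamped to the program's ends)."""
        if t <= 0:
            return self.segments[0][1]
        t0 = 0.0
        for dur, b0, b1 in self.segments:
            if t <= t0 + dur:
                return b0 + (b1 - b0) * (t - t0) / dur
            t0 += dur
        return self.segments[-1][2]

    def time_at_percent_b(self, b: float) -> float:
        """First time at which the program reaches ``b`` %B.

        Raises :class:`ParameterError` if ``b`` is never reached.
        """
        t0 = 0.0
        for dur, b0, b1 in self.segments:
            lo, hi = min(b0, b1), max(b0, b1)
            if lo <= b <= hi and b1 != b0:
                return t0 + dur * (b - b0) / (b1 - b0)
            if b == b0:
                return t0
            t0 += dur
        raise ParameterError(f"gradient never reaches {b} %B")


#: The fractionation program used for the mock venom: 0→5 %B over 10 min,
#: 5→15 over 20 min, 15→45 over 120 min, 45→70 over 20 min, 70→100 over 15 min
#: at 1 mL/min.
DEFAULT_GRADIENT = GradientProgram(
    segments=(
        (10.0, 0.0, 5.0),
        (20.0, 5.0, 15.0),
        (120.0, 15.0, 45.0),
        (20.0, 45.0, 70.0),
        (15.0, 70.0, 100.0),
    ),
    flow_ml_min=1.0,
)


@dataclass(frozen=True)
class MockVenom:
    """Ground truth for a synthetic venom: toxins, abundances, peak layout.

    ``peak_split`` maps each toxin id to ``{peak_id: share}`` with shares
    summing to 1 over that toxin's peaks (a toxin may elute in several
    peaks).  ``peak_percent_b`` gives each peak's nominal %B at elution,
    which the chromatogram simulator converts to a retention time.
    """

    toxins: tuple  # tuple[ToxinRecord, ...]
    true_abundance: dict  # toxin id -> fraction
    peak_split: dict  # toxin id -> {peak id -> share}
    impurity_peaks: tuple  # peak ids carrying no toxin
    peak_percent_b: dict  # peak id -> %B at elution
    response_factors: dict  # toxin id -> detector response factor
    seed: int

    def __post_init__(self) -> None:
        ids = {t.id for t in self.toxins}
        total = math.fsum(self.true_abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"true abundances sum to {total!r}, not 1")
        if set(self.true_abundance) != ids:
            raise InputError("true_abundance keys must match toxin ids")
        if set(self.peak_split) != ids:
            raise InputError("peak_split keys must match toxin ids")
        toxin_peaks = set()
        for tid, split in self.peak_split.items():
            s = math.fsum(split.values())
            if abs(s - 1.0) > 1e-9:
                raise InputError(f"peak shares for {tid!r} sum to {s!r}, not 1")
            toxin_peaks |= set(split)
        if toxin_peaks & set(self.impurity_peaks):
            raise InputError("impurity peaks must be disjoint from toxin peaks")
        all_peaks = toxin_peaks | set(self.impurity_peaks)
        if not all_peaks <= set(self.peak_percent_b):
            raise InputError("every peak needs an elution %B")

    @property
    def peak_assignment(self) -> dict:
        """Map toxin id → list of peak ids (derived from ``peak_split``)."""
        return {tid: sorted(split) for tid, split in self.peak_split.items()}

    @property
    def peak_ids(self) -> list:
        """All peak ids in elution order (ascending %B)."""
        return sorted(self.peak_percent_b, key=lambda p: self.peak_percent_b[p])
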