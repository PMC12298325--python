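"""Synthetic "mock venom" generator.

Produces a complete, internally consistent dataset with known ground truth:
a toxin catalogue with Dirichlet-distributed true abundances, an RP-HPLC
chromatogram of exponentially modified Gaussian (EMG) peaks placed along a
binary solvent gradient, per-peak gel lanes with bands and densitometry
values, within-run MS1 feature intensities for co-banded toxins, tryptic
peptide observations per band, a protein database (FASTA + annotation
sidecar), and a two-replicate venom-gland expression table.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from pyteomics import mass as pmass
from scipy.stats import exponnorm

from .digest import tryptic_digest
from .records import (
    AA_ALPHABET,
    DEFAULT_GRADIENT,
    GradientProgram,
    InputError,
    MockVenom,
    NON_TOXIN,
    ParameterError,
    ToxinRecord,
)

# Sampling weights for family labels in a mock venom (not abundances); they
# echo a small-elapid venom dominated by 3FTx and PLA2 with a tail of
# secondary/minor families.
DEFAULT_FAMILY_WEIGHTS = {
    "3FTx": 0.40,
    "PLA2": 0.22,
    "CTL": 0.10,
    "NGF": 0.08,
    "CRiSP": 0.08,
    "LAAO": 0.07,
    "AChE": 0.05,
}

# Family-specific conserved motifs embedded in every mature sequence so that
# naive keyword/motif classification has something to find, plus a typical
# mature-chain length range (residues).
_FAMILY_MOTIFS = {
    "3FTx": ("CYKKTWSDHRG", (60, 74)),
    "PLA2": ("CCFVHDCCYG", (118, 134)),
    "CTL": ("WIGLNDQTKE", (125, 140)),
    "NGF": ("WVGDKTTATD", (112, 126)),
    "CRiSP": ("HNDFRRSVKP", (200, 230)),
    "LAAO": ("GGRLRFAGAG", (460, 500)),
    "AChE": ("FGGDPGSVTL", (520, 560)),
    "SVMP": ("HELGHNLGME", (190, 420)),
    "SVSP": ("GDSGGPLIC", (230, 260)),
    "KUN": ("GPCRAAIPRW", (57, 65)),
    "NP": ("GCFGGRLDRI", (35, 45)),
}
_IMPURITY_LENGTH = (120, 160)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = rng.integers(0, len(AA_ALPHABET), size=length)
    return "".join(AA_ALPHABET[i] for i in letters)


def _make_sequence(rng: np.random.Generator, family: str) -> tuple[str, int]:
    """Random precursor with a family motif; returns (precursor, mature_start)."""
    motif, (lo, hi) = _FAMILY_MOTIFS.get(family, ("", _IMPURITY_LENGTH))
    mature_len = int(rng.integers(lo, hi + 1))
    signal_len = int(rng.integers(18, 25))
    mature = list(_random_sequence(rng, mature_len))
    if motif:
        pos = int(rng.integers(1, mature_len - len(motif)))
        mature[pos : pos + len(motif)] = motif
    precursor = _random_sequence(rng, signal_len) + "".join(mature)
    return precursor, signal_len


def _average_mass_kda(sequence: str) -> float:
    return pmass.calculate_mass(sequence=sequence, average=True) / 1000.0


def generate_mock_venom(
    n_toxins: int,
    family_weights: dict | None = None,
    dirichlet_concentration: float = 0.5,
    seed: int = 0,
    *,
    n_impurity_peaks: int = 1,
    dominant_extra_peaks: int = 3,
    coelution_prob: float = 0.25,
    response_factor_sd: float = 0.0,
    ensure_all_families: bool = False,
) -> MockVenom:
    """Draw a mock venom: toxins, true abundances and a peak layout.

    Abundances are drawn from a symmetric Dirichlet with the given
    concentration (small values give sparse, dominated mixtures) and sorted
    so toxin 1 is the most abundant.  The dominant toxin elutes in
    ``1 + dominant_extra_peaks`` peaks; each further toxin either gets its
    own peak or, with probability ``coelution_prob``, co-elutes in an
    existing one.  Peaks are ordered along the gradient's shallow segment by
    a hydrophobicity proxy (Kyte–Doolittle GRAVY of the mature chain).
    """
    if n_toxins < 1:
        raise ParameterError("n_toxins must be >= 1")
    if dirichlet_concentration <= 0:
        raise ParameterError("dirichlet_concentration must be positive")
    weights = dict(family_weights or DEFAULT_FAMILY_WEIGHTS)
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ParameterError("family weights must be non-negative, not all zero")
    for fam in weights:
        if fam not in _FAMILY_MOTIFS:
            raise ParameterError(f"no sequence model for family {fam!r}")

    rng = np.random.default_rng(seed)

    fams = sorted((f for f in weights if weights[f] > 0), key=lambda f: -weights[f])
    probs = np.array([weights[f] for f in fams], dtype=float)
    probs /= probs.sum()
    if ensure_all_families and n_toxins >= len(fams):
        families = list(fams) + [
            fams[i] for i in rng.choice(len(fams), size=n_toxins - len(fams), p=probs)
        ]
    else:
        families = [fams[i] for i in rng.choice(len(fams), size=n_toxins, p=probs)]

    abundances = np.sort(
        rng.dirichlet(np.full(n_toxins, dirichlet_concentration))
    )[::-1]
    # Renormalise exactly (Dirichlet draws already sum to 1 up to fp error).
    abundances = abundances / abundances.sum()

    toxins = []
    for i, fam in enumerate(families):
        precursor, mstart = _make_sequence(rng, fam)
        toxins.append(
            ToxinRecord(
                id=f"t{i + 1:02d}",
                family=fam,
                precursor=precursor,
                mature_start=mstart,
                mass_kda=_average_mass_kda(precursor[mstart:]),
            )
        )

    # --- peak layout -----------------------------------------------------
    # peaks: list of dicts {members: {toxin_id: share}, gravy: float}
    peaks: list[dict] = []
    peak_split: dict[str, dict[int, float]] = {}

    def _gravy(rec: ToxinRecord) -> float:
        return ProteinAnalysis(rec.mature).gravy()

    for i, rec in enumerate(toxins):
        if i == 0 and dominant_extra_peaks > 0 and n_toxins > 1:
            k = 1 + dominant_extra_peaks
            shares = np.sort(rng.dirichlet(np.full(k, 2.0)))[::-1]
            split = {}
            for j, sh in enumerate(shares):
                peaks.append(
                    {"members": {rec.id: sh}, "gravy": _gravy(rec) + 0.12 * j}
                )
                split[len(peaks) - 1] = float(sh)
            peak_split[rec.id] = split
        elif i > 0 and len(peaks) > 0 and rng.random() < coelution_prob:
            host = int(rng.integers(0, len(peaks)))
            peaks[host]["members"][rec.id] = 1.0
            peak_split[rec.id] = {host: 1.0}
        else:
            peaks.append({"members": {rec.id: 1.0}, "gravy": _gravy(rec)})
            peak_split[rec.id] = {len(peaks) - 1: 1.0}

    # Rank peaks by hydrophobicity and place them evenly (with jitter) over
    # the shallow gradient segment, 17-43 %B; impurities elute early (5-13 %B).
    order = np.argsort([p["gravy"] + 1e-9 * i for i, p in enumerate(peaks)])
    n_tp = len(peaks)
    pct_b_toxin = {}
    for rank, idx in enumerate(order):
        base = 17.0 + 26.0 * (rank + 0.5) / n_tp
        jitter = float(rng.uniform(-0.15, 0.15)) * 26.0 / n_tp
        pct_b_toxin[int(idx)] = base + jitter

    impurity_pct = [
        5.0 + 8.0 * (j + 0.5) / n_impurity_peaks for j in range(n_impurity_peaks)
    ]

    # Assign final peak ids in elution (ascending %B) order.
    entries = [("imp", j, b) for j, b in enumerate(impurity_pct)] + [
        ("tox", i, b) for i, b in pct_b_toxin.items()
    ]
    entries.sort(key=lambda e: e[2])
    peak_percent_b: dict[str, float] = {}
    index_to_id: dict[int, str] = {}
    impurity_ids = []
    for n, (kind, idx, b) in enumerate(entries, start=1):
        pid = f"P{n}"
        peak_percent_b[pid] = float(b)
        if kind == "imp":
            impurity_ids.append(pid)
        else:
            index_to_id[idx] = pid

    split_by_id = {
        tid: {index_to_id[i]: sh for i, sh in split.items()}
        for tid, split in peak_split.items()
    }

    if response_factor_sd > 0:
        rf = {
            t.id: float(np.exp(rng.normal(0.0, response_factor_sd))) for t in toxins
        }
    else:
        rf = {t.id: 1.0 for t in toxins}

    return MockVenom(
        toxins=tuple(toxins),
        true_abundance={t.id: float(a) for t, a in zip(toxins, abundances)},
        peak_split=split_by_id,
        impurity_peaks=tuple(impurity_ids),
        peak_percent_b=peak_percent_b,
        response_factors=rf,
        seed=seed,
    )


def peak_amounts(venom: MockVenom) -> dict[str, dict[str, float]]:
    """Per-peak toxin amounts (abundance x response x peak share), normalised
    so all toxin amounts sum to 1 over the whole venom."""
    raw = {
        tid: venom.true_abundance[tid] * venom.response_factors[tid]
        for tid in venom.true_abundance
    }
    total = math.fsum(raw.values())
    out: dict[str, dict[str, float]] = {}
    for tid, split in venom.peak_split.items():
        for pid, sh in split.items():
            out.setdefault(pid, {})[tid] = raw[tid] * sh / total
    return out


def peak_retention_times(
    venom: MockVenom, gradient: GradientProgram = DEFAULT_GRADIENT
) -> dict[str, float]:
    """Retention time of each peak: the time the gradient reaches its %B."""
    return {
        pid: gradient.time_at_percent_b(b) for pid, b in venom.peak_percent_b.items()
    }


@dataclass(frozen=True)
class ChromatogramTruth:
    """Analytic ground truth for a simulated chromatogram."""

    peaks: pd.DataFrame  # peak_id, rt_min, sigma_min, tau_min, area
    composition: dict  # peak_id -> {toxin_id: share of peak area}

    @property
    def peak_areas(self) -> dict[str, float]:
        return dict(zip(self.peaks["peak_id"], self.peaks["area"]))


def simulate_chromatogram(
    venom: MockVenom,
    gradient: GradientProgram = DEFAULT_GRADIENT,
    sampling_interval: float = 0.01,
    noise_sd: float = 0.2,
    baseline_drift: float = 0.02,
    seed: int = 0,
    *,
    total_area: float = 1000.0,
    sigma_range: tuple = (0.15, 0.3),
    tau_range: tuple = (0.08, 0.18),
    impurity_area_fraction: float = 0.02,
) -> tuple[pd.DataFrame, ChromatogramTruth]:
    """Simulate a 214 nm absorbance trace for a mock venom.

    Each peak is an EMG whose analytic area equals ``total_area`` times the
    summed normalised amount of its toxins (impurity peaks get
    ``impurity_area_fraction`` of ``total_area`` each); a linear baseline
    drift and white noise are added on top.  Returns the trace (columns
    ``time_min``, ``absorbance_mau``) and the analytic ground truth.
    """
    if not venom.toxins:
        raise InputError("empty venom: no toxins to simulate")
    if sampling_interval <= 0:
        raise ParameterError("sampling_interval must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    amounts = peak_amounts(venom)
    rts = peak_retention_times(venom, gradient)

    rows = []
    composition = {}
    for pid in venom.peak_ids:
        if pid in venom.impurity_peaks:
            area = impurity_area_fraction * total_area
            composition[pid] = {}
        else:
            a = amounts[pid]
            area = total_area * math.fsum(a.values())
            s = math.fsum(a.values())
            composition[pid] = {tid: v / s for tid, v in a.items()}
        rows.append(
            {
                "peak_id": pid,
                "rt_min": rts[pid],
                "sigma_min": float(rng.uniform(*sigma_range)),
                "tau_min": float(rng.uniform(*tau_range)),
                "area": area,
            }
        )
    truth = ChromatogramTruth(peaks=pd.DataFrame(rows), composition=composition)

    t = np.arange(0.0, gradient.total_time_min + sampling_interval / 2,
                  sampling_interval)
    signal = np.zeros_like(t)
    for row in rows:
        k = row["tau_min"] / row["sigma_min"]
        signal += row["area"] * exponnorm.pdf(
            t, K=k, loc=row["rt_min"], scale=row["sigma_min"]
        )
    signal += baseline_drift * t
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=t.shape)

    trace = pd.DataFrame({"time_min": t, "absorbance_mau": signal})
    return trace, truth


def default_mass_to_mobility(mass_kda: float) -> float:
    """Relative electrophoretic mobility for an average mass (log-linear)."""
    lo, hi = math.log10(2.0), math.log10(700.0)
    x = (math.log10(max(mass_kda, 2.0)) - lo) / (hi - lo)
    return float(np.clip(1.0 - x, 0.0, 1.0))


@dataclass(frozen=True)
class GelMs1Tables:
    """Simulated gel lanes, MS1 features and peptide observations."""

    lanes: pd.DataFrame  # lane_id, peak_id, rt_min, band_id, mass_kda, density, identified
    ms1: pd.DataFrame  # band_id, run_id, toxin_id, intensity (+ peak_id)
    peptides: pd.DataFrame  # peak_id, band_id, peptide
    band_truth: dict  # (peak_id, band_id) -> {toxin_id: share of band amount}


def simulate_gel_and_ms1(
    venom: MockVenom,
    mass_to_mobility=default_mass_to_mobility,
    ms1_dynamic_range: float = 1e4,
    seed: int = 0,
    *,
    gradient: GradientProgram = DEFAULT_GRADIENT,
    resolvable_kda: float = 2.0,
    ms1_noise_sigma: float = 0.15,
    density_noise_cv: float = 0.05,
    unidentified_band_fraction: float = 0.0,
    max_missed_cleavages: int = 2,
    peptide_length_range: tuple = (7, 30),
) -> GelMs1Tables:
    """Simulate per-peak gel lanes and within-run MS1 intensities.

    Toxins co-eluting in a peak land in the same band when their masses
    differ by at most ``resolvable_kda`` (single-linkage on the sorted mass
    ladder).  Band density is proportional to the within-peak amount of its
    toxins with multiplicative noise; co-banded toxins additionally get MS1
    intensities proportional to amount with log-normal noise, all under a
    single run id per band.  MS1 features fainter than the strongest feature
    divided by ``ms1_dynamic_range`` are dropped (undetected).

    ``unidentified_band_fraction`` > 0 adds one unidentifiable band per lane
    carrying that fraction of the lane's density (no peptides, no MS1).
    """
    if ms1_dynamic_range < 1:
        raise ParameterError("ms1_dynamic_range must be >= 1")
    masses = sorted(t.mass_kda for t in venom.toxins)
    mobil = [mass_to_mobility(m) for m in masses]
    if any(b > a + 1e-12 for a, b in zip(mobil, mobil[1:])):
        raise ParameterError("mass_to_mobility must be monotone non-increasing")

    rng = np.random.default_rng(seed)
    amounts = peak_amounts(venom)
    rts = peak_retention_times(venom, gradient)
    by_id = {t.id: t for t in venom.toxins}

    lane_rows, ms1_rows, pep_rows = [], [], []
    band_truth: dict = {}
    for pid in venom.peak_ids:
        if pid in venom.impurity_peaks:
            # contaminant-only lane: one band, nothing identifiable as toxin
            lane_rows.append(
                {
                    "lane_id": pid,
                    "peak_id": pid,
                    "rt_min": rts[pid],
                    "band_id": "a",
                    "mass_kda": round(float(rng.uniform(12, 30)), 2),
                    "density": 500.0,
                    "identified": 0,
                }
            )
            continue
        members = amounts[pid]
        # cluster member toxins into bands on the mass ladder
        ordered = sorted(members, key=lambda tid: -by_id[tid].mass_kda)
        bands: list[list[str]] = [[ordered[0]]]
        for tid in ordered[1:]:
            if by_id[bands[-1][-1]].mass_kda - by_id[tid].mass_kda <= resolvable_kda:
                bands[-1].append(tid)
            else:
                bands.append([tid])
        densities = []
        for letter, band in zip("abcdefghij", bands):
            amount = math.fsum(members[tid] for tid in band)
            noise = math.exp(rng.normal(0.0, density_noise_cv)) if density_noise_cv else 1.0
            density = 1000.0 * amount * noise
            densities.append(density)
            app_mass = math.fsum(
                by_id[tid].mass_kda * members[tid] for tid in band
            ) / amount
            lane_rows.append(
                {
                    "lane_id": pid,
                    "peak_id": pid,
                    "rt_min": rts[pid],
                    "band_id": letter,
                    "mass_kda": round(app_mass, 2),
                    "density": density,
                    "identified": 1,
                }
            )
            band_truth[(pid, letter)] = {
                tid: members[tid] / amount for tid in band
            }
            # MS1 features: one run per band, one feature per detectable
            # peptide, so per-toxin intensities are sums over several
            # features (as the partitioning step expects)
            run_id = f"{pid}{letter}-r1"
            lo, hi = peptide_length_range
            band_rows = []
            for tid in band:
                seen = set()
                for pep, _s, _e, _mc in tryptic_digest(
                    by_id[tid].mature, max_missed_cleavages
                ):
                    if lo <= len(pep) <= hi and pep not in seen:
                        seen.add(pep)
                        pep_rows.append(
                            {"peak_id": pid, "band_id": letter, "peptide": pep}
                        )
                n_feat = min(len(seen), 10) or 1
                w = rng.dirichlet(np.full(n_feat, 2.0))
                inten = (
                    1e7 * (members[tid] / amount) * w
                    * np.exp(rng.normal(0.0, ms1_noise_sigma, size=n_feat))
                )
                for ii in inten:
                    band_rows.append(
                        {
                            "peak_id": pid,
                            "band_id": letter,
                            "run_id": run_id,
                            "toxin_id": tid,
                            "intensity": float(ii),
                        }
                    )
            floor = max(r["intensity"] for r in band_rows) / ms1_dynamic_range
            ms1_rows.extend(r for r in band_rows if r["intensity"] >= floor)
        if unidentified_band_fraction > 0:
            f = unidentified_band_fraction
            extra = f / (1.0 - f) * math.fsum(densities)
            lane_rows.append(
                {
                    "lane_id": pid,
                    "peak_id": pid,
                    "rt_min": rts[pid],
                    "band_id": "u",
                    "mass_kda": round(float(rng.uniform(20, 40)), 2),
                    "density": extra,
                    "identified": 0,
                }
            )

    return GelMs1Tables(
        lanes=pd.DataFrame(lane_rows),
        ms1=pd.DataFrame(ms1_rows),
        peptides=pd.DataFrame(pep_rows),
        band_truth=band_truth,
    )


# --- expression table ----------------------------------------------------

DEFAULT_EXPRESSION_PROFILE = {"3FTx": 0.72, "PLA2": 0.16, "other": 0.12}

_OTHER_FAMILIES = ("CTL", "CRiSP", "LAAO", "NGF", "AChE", "SVSP", "endonuclease",
                   "SVMP", "KUN", "NP")

_FAMILY_KEYWORDS = {
    "3FTx": "three-finger toxin",
    "PLA2": "phospholipase A2",
    "CTL": "C-type lectin",
    "NGF": "nerve growth factor",
    "CRiSP": "cysteine-rich secretory protein",
    "LAAO": "L-amino acid oxidase",
    "AChE": "acetylcholinesterase",
    "SVSP": "snake venom serine protease",
    "SVMP": "snake venom metalloproteinase",
    "KUN": "kunitz-type inhibitor",
    "NP": "natriuretic peptide",
    "endonuclease": "venom endonuclease",
}


def simulate_expression_table(
    n_genes: int = 5000,
    n_toxin_genes: int = 250,
    family_expression_profile: dict | None = None,
    seed: int = 0,
    *,
    toxin_expression_share: float = 0.30,
    zero_fraction: float = 0.15,
    ambiguous_fraction: float = 0.02,
    replicate_cv: float = 0.05,
) -> pd.DataFrame:
    """Simulate a two-replicate venom-gland cpm table.

    Toxin-family cpm shares follow ``family_expression_profile`` (an
    ``"other"`` key is spread over a set of minor families); the toxin genes
    as a whole carry ``toxin_expression_share`` of total expression.
    ``zero_fraction`` of genes get 0 cpm in both replicates (inactive) and
    ``ambiguous_fraction`` get sub-1 cpm in at least one replicate.  Both
    replicate columns are normalised to 1e6 cpm.
    """
    if n_toxin_genes > n_genes:
        raise ParameterError("n_toxin_genes must be <= n_genes")
    profile = dict(family_expression_profile or DEFAULT_EXPRESSION_PROFILE)
    tot = math.fsum(profile.values())
    if abs(tot - 1.0) > 1e-6:
        raise ParameterError(f"family expression shares sum to {tot!r}, not 1")
    if "other" in profile:
        other = profile.pop("other")
        spread = _OTHER_FAMILIES[: max(1, min(len(_OTHER_FAMILIES), 6))]
        for fam in spread:
            profile[fam] = profile.get(fam, 0.0) + other / len(spread)

    rng = np.random.default_rng(seed)
    fams = sorted(profile, key=lambda f: -profile[f])
    # gene counts: spread toxin genes over the families roughly evenly, so
    # high-share families come out strongly upregulated per gene
    counts = np.full(len(fams), n_toxin_genes // len(fams), dtype=int)
    counts[: n_toxin_genes % len(fams)] += 1
    counts = np.maximum(counts, 1)

    gene_rows = []
    g = 0
    for fam, cnt in zip(fams, counts):
        for j in range(cnt):
            g += 1
            gene_rows.append(
                {
                    "gene_id": f"g{g:06d}",
                    "family": fam,
                    "description": f"{_FAMILY_KEYWORDS.get(fam, fam)} precursor {j + 1}",
                }
            )
    n_nt = n_genes - len(gene_rows)
    for j in range(n_nt):
        g += 1
        gene_rows.append(
            {
                "gene_id": f"g{g:06d}",
                "family": NON_TOXIN,
                "description": f"housekeeping protein {j + 1}",
            }
        )

    # inactive genes are decided first; expression budgets are then spread
    # over the *expressed* genes only, so family shares hold regardless of
    # which genes happen to be silent
    n = len(gene_rows)
    families_arr = np.array([r["family"] for r in gene_rows])
    zero_mask = rng.random(n) < zero_fraction
    base = np.zeros(n)
    for fam, cnt in zip(fams, counts):
        idx = np.flatnonzero((families_arr == fam) & ~zero_mask)
        if len(idx):
            w = rng.dirichlet(np.full(len(idx), 0.5))
            base[idx] = w * profile[fam] * toxin_expression_share
    nt_idx = np.flatnonzero((families_arr == NON_TOXIN) & ~zero_mask)
    if len(nt_idx):
        nt_w = rng.lognormal(0.0, 1.5, size=len(nt_idx))
        base[nt_idx] = nt_w / nt_w.sum() * (1.0 - toxin_expression_share)

    rep1 = base * np.exp(rng.normal(0.0, replicate_cv, size=n))
    rep2 = base * np.exp(rng.normal(0.0, replicate_cv, size=n))
    for rep in (rep1, rep2):
        s = rep.sum()
        if s > 0:
            rep *= 1e6 / s
    # inject sub-1-cpm ambiguity into a few non-zero genes
    amb = (rng.random(n) < ambiguous_fraction) & ~zero_mask
    rep1[amb] = rng.uniform(0.05, 0.95, size=amb.sum())

    table = pd.DataFrame(gene_rows)
    table["cpm_rep1"] = rep1
    table["cpm_rep2"] = rep2
    return table


# --- writers --------------------------------------------------------------


def write_chromatogram_csv(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False, columns=["time_min", "absorbance_mau"])


def write_lanes_tsv(lanes: pd.DataFrame, path) -> None:
    lanes.to_csv(path, sep="\t", index=False)


def write_ms1_tsv(ms1: pd.DataFrame, path) -> None:
    ms1.to_csv(path, sep="\t", index=False)


def write_peptides_tsv(peptides: pd.DataFrame, path) -> None:
    peptides.to_csv(path, sep="\t", index=False)


def write_fasta(records, path) -> None:
    seq_records = [
        SeqRecord(Seq(r.precursor), id=r.id, description=r.family) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_annotations_tsv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "family": r.family,
                "mature_start": r.mature_start,
                "mass_kda": round(r.mass_kda, 4),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_expression_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_manifest(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


# --- packaged fixture -----------------------------------------------------

AA_FIXTURE_SEED = 42


def aa_fixture(seed: int = AA_FIXTURE_SEED) -> MockVenom:
    """The packaged default fixture: 12 toxins over 7 families, the dominant
    3FTx eluting in several peaks, and 2 early impurity peaks."""
    return generate_mock_venom(
        n_toxins=12,
        dirichlet_concentration=0.3,
        seed=seed,
        n_impurity_peaks=2,
        dominant_extra_peaks=3,
        coelution_prob=0.3,
        ensure_all_families=True,
    )


def write_fixture(
    out_dir,
    venom: MockVenom | None = None,
    seed: int = AA_FIXTURE_SEED,
    *,
    noise_sd: float = 0.2,
    baseline_drift: float = 0.02,
    sampling_interval: float = 0.01,
    unidentified_band_fraction: float = 0.0,
    expression_seed: int | None = None,
) -> dict:
    """Write a complete input set for the pipeline to ``out_dir``.

    Returns a dict of paths plus the ground truth (venom, chromatogram
    truth, band truth) for recovery testing.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if venom is None:
        venom = aa_fixture(seed)
    obs_seed = (seed * 1000003 + 1) % (2**31)
    trace, truth = simulate_chromatogram(
        venom,
        sampling_interval=sampling_interval,
        noise_sd=noise_sd,
        baseline_drift=baseline_drift,
        seed=obs_seed,
    )
    gel = simulate_gel_and_ms1(
        venom,
        seed=obs_seed + 1,
        unidentified_band_fraction=unidentified_band_fraction,
    )
    expr = simulate_expression_table(seed=expression_seed if expression_seed
                                     is not None else obs_seed + 2)

    paths = {
        "trace": out / "chromatogram.csv",
        "lanes": out / "lanes.tsv",
        "ms1": out / "ms1.tsv",
        "peptides": out / "peptides.tsv",
        "fasta": out / "proteins.fasta",
        "annotations": out / "annotations.tsv",
        "expression": out / "expression.tsv",
        "manifest": out / "manifest.yaml",
    }
    write_chromatogram_csv(trace, paths["trace"])
    write_lanes_tsv(gel.lanes, paths["lanes"])
    write_ms1_tsv(gel.ms1, paths["ms1"])
    write_peptides_tsv(gel.peptides, paths["peptides"])
    write_fasta(venom.toxins, paths["fasta"])
    write_annotations_tsv(venom.toxins, paths["annotations"])
    write_expression_tsv(expr, paths["expression"])
    write_manifest(
        {
            "seed": seed,
            "observation_seed": obs_seed,
            "noise_sd": noise_sd,
            "baseline_drift": baseline_drift,
            "sampling_interval": sampling_interval,
            "unidentified_band_fraction": unidentified_band_fraction,
            "n_toxins": len(venom.toxins),
            "impurity_peaks": list(venom.impurity_peaks),
        },
        paths["manifest"],
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "venom": venom,
        "chromatogram_truth": truth,
        "gel": gel,
        "expression": expr,
    }
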