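import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from venomquant.records import MockVenom, ToxinRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_toxin(tid, family="3FTx", mature="ACDEFGHIKMNPQSTVWY" * 4,
               signal="MKTLLLTLVV", mass_kda=None):
    precursor = signal + mature
    if mass_kda is None:
        mass_kda = 0.11 * len(mature)  # ~110 Da per residue
    return ToxinRecord(
        id=tid, family=family, precursor=precursor,
        mature_start=len(signal), mass_kda=mass_kda,
    )


def make_venom(abundances, families=None, masses=None, peak_split=None,
               impurity_peaks=(), seed=0):
    """Hand-built MockVenom with one peak per toxin unless peak_split given."""
    n = len(abundances)
    families = families or ["3FTx"] * n
    masses = masses or [7.0 + i for i in range(n)]
    toxins = tuple(
        make_toxin(f"t{i + 1:02d}", family=families[i], mass_kda=masses[i])
        for i in range(n)
    )
    if peak_split is None:
        peak_split = {t.id: {f"P{i + 1}": 1.0} for i, t in enumerate(toxins)}
    peaks = {p for split in peak_split.values() for p in split}
    peaks |= set(impurity_peaks)
    pct_b = {p: 15.0 + 2.0 * i for i, p in enumerate(sorted(peaks))}
    return MockVenom(
        toxins=toxins,
        true_abundance={t.id: a for t, a in zip(toxins, abundances)},
        peak_split=peak_split,
        impurity_peaks=tuple(impurity_peaks),
        peak_percent_b=pct_b,
        response_factors={t.id: 1.0 for t in toxins},
        seed=seed,
    )


@pytest.fixture(scope="session")
def fixture_venom():
    from venomquant.synthio import aa_fixture

    return aa_fixture()


@pytest.fixture(scope="session")
def clean_run_dir(tmp_path_factory, fixture_venom):
    """Fixture inputs with every nuisance (noise, drift) switched off."""
    from venomquant import synthio

    out = tmp_path_factory.mktemp("clean_fixture")
    gen = synthio.write_fixture(out, venom=fixture_venom, seed=7,
                                noise_sd=0.0, baseline_drift=0.0)
    gel = synthio.simulate_gel_and_ms1(
        fixture_venom, seed=1, ms1_noise_sigma=0.0, density_noise_cv=0.0
    )
    synthio.write_lanes_tsv(gel.lanes, out / "lanes.tsv")
    synthio.write_ms1_tsv(gel.ms1, out / "ms1.tsv")
    synthio.write_peptides_tsv(gel.peptides, out / "peptides.tsv")
    return gen


@pytest.fixture(scope="session")
def noisy_run_dir(tmp_path_factory, fixture_venom):
    """Fixture inputs at default noise levels."""
    from venomquant import synthio

    out = tmp_path_factory.mktemp("noisy_fixture")
    return synthio.write_fixture(out, venom=fixture_venom, seed=11)


def lane_frame(rows):
    return pd.DataFrame(
        rows, columns=["lane_id", "peak_id", "band_id", "mass_kda",
                       "density", "identified"]
    )


def peaks_frame(fractions, excluded=()):
    """Minimal integrated PeakTable for allocation tests."""
    rows = []
    for i, (pid, frac) in enumerate(fractions.items()):
        rows.append(
            {
                "peak_id": pid,
                "start_min": float(i), "apex_min": i + 0.5, "end_min": i + 1.0,
                "start_idx": 10 * i, "apex_idx": 10 * i + 5,
                "end_idx": 10 * i + 10,
                "raw_area": frac, "corrected_area": frac,
                "excluded": pid in excluded,
                "fraction": np.nan if pid in excluded else frac,
            }
        )
    return pd.DataFrame(rows)
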