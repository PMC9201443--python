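import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddadia.models import Mode, Peak, Spectrum

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_spectrum(spectrum_id, precursor_mz, peaks, rt_min=10.0, mode=Mode.DDA):
    return Spectrum(spectrum_id, precursor_mz,
                    rt_min, [Peak(mz, i) for mz, i in peaks], mode=mode)


def random_spectrum(rng: np.random.Generator, spectrum_id: str,
                    n_peaks: int | None = None, mode=Mode.DDA) -> Spectrum:
    n = n_peaks if n_peaks is not None else int(rng.integers(1, 9))
    mz = np.sort(rng.uniform(100.0, 900.0, n))
    intensity = rng.lognormal(7.0, 1.0, n)
    return Spectrum(spectrum_id, float(rng.uniform(200.0, 1000.0)),
                    float(rng.uniform(0.5, 35.0)),
                    [Peak(float(a), float(b)) for a, b in zip(mz, intensity)],
                    mode=mode)


def brute_force_max_assignment(pairs):
    """Exhaustive maximum-weight one-to-one assignment over candidate pairs.

    Independent oracle: enumerates every subset extension recursively.
    Returns (best_total_weight, n_pairs_in_best). Feasible for tiny inputs.
    """
    best = {"w": 0.0, "n": 0}

    def recurse(i, used_a, used_b, total, count):
        if total > best["w"] + 1e-15:
            best["w"], best["n"] = total, count
        if i == len(pairs):
            return
        # skip pair i
        recurse(i + 1, used_a, used_b, total, count)
        c = pairs[i]
        if c.index_a not in used_a and c.index_b not in used_b:
            recurse(i + 1, used_a | {c.index_a}, used_b | {c.index_b},
                    total + c.weight, count + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return best["w"], best["n"]


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic benchmark (shared across tests; treat as read-only)."""
    from ddadia.simgen import SimConfig, simulate
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    from ddadia.pipeline import run_all
    ds = default_dataset
    return ds, run_all({s.spectrum_id: s for s in ds.dda_spectra}, ds.dda_table,
                       {s.spectrum_id: s for s in ds.dia_spectra}, ds.dia_table)


@pytest.fixture()
def demo_library():
    """A small synthetic in-house library (10 entries) built programmatically."""
    rng = np.random.default_rng(7)
    from ddadia.models import LibraryEntry
    entries = []
    for i in range(10):
        n = int(rng.integers(5, 10))
        mz = np.sort(rng.uniform(100.0, 600.0, n))
        intensity = rng.lognormal(8.0, 0.8, n)
        entries.append(LibraryEntry(
            name=f"compound_{i:02d}",
            precursor_mz=float(200.0 + 60.0 * i + rng.uniform(0, 30)),
            peaks=tuple(Peak(float(a), float(b)) for a, b in zip(mz, intensity)),
            formula=None, compound_class="synthetic"))
    return entries
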