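import numpy as np
import pytest

from cagesense.qc_io import OrbitalLevel, SpeciesRecord


@pytest.fixture
def c60_record() -> SpeciesRecord:
    """Minimal species with the pristine-cage frontier pair."""
    return SpeciesRecord(
        label="C60",
        total_energy=-2285.123456789,
        levels=(OrbitalLevel(-5.38, 2), OrbitalLevel(-3.70, 0)),
        dipole_vector=(0.0, 0.0, 0.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_species(rng: np.random.Generator, label: str = "rand") -> SpeciesRecord:
    """A random but valid species record for round-trip tests."""
    n_occ = int(rng.integers(1, 6))
    n_vir = int(rng.integers(1, 6))
    occ = np.sort(rng.uniform(-12.0, -4.0, size=n_occ))
    vir = np.sort(rng.uniform(-3.9, 2.0, size=n_vir))
    levels = tuple(OrbitalLevel(float(e), 2) for e in occ) + \
        tuple(OrbitalLevel(float(e), 0) for e in vir)
    return SpeciesRecord(
        label=label,
        total_energy=float(rng.uniform(-3000.0, -10.0)),
        levels=levels,
        dipole_vector=tuple(float(x) for x in rng.normal(0, 5, size=3)),
        bsse=float(rng.uniform(0, 20)) if rng.random() < 0.5 else None,
    )
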