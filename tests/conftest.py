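import numpy as np
import pytest

from dimerdyn import synthetic_data as sd
from dimerdyn.core_io import AtomRecord, Structure, select


@pytest.fixture(scope="session")
def toy_dimer():
    return sd.build_toy_dimer(seed=0)


@pytest.fixture(scope="session")
def ideal_helix():
    return sd.build_ideal_peptide("helix", 12)


@pytest.fixture(scope="session")
def ideal_hairpin():
    return sd.build_ideal_peptide("hairpin", 12)


@pytest.fixture
def tripeptide():
    """Hand-built 3-residue Cα-only peptide on chains A/B for selections."""
    atoms = []
    serial = 0
    for chain, resid in [("A", 1), ("B", 304), ("B", 305), ("B", 306)]:
        for name, element in [("N", "N"), ("CA", "C")]:
            serial += 1
            atoms.append(AtomRecord(
                serial, name, element, resid, "GLY", chain,
                np.array([serial * 1.5, float(resid % 7), 0.5 * serial]),
            ))
    return Structure(atoms)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
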