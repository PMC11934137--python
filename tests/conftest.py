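import numpy as np
import pytest

from qssr.structures import Atom, Molecule, RadiiTable


@pytest.fixture(scope="session")
def bondi() -> RadiiTable:
    return RadiiTable.bondi()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_molecule(rng: np.random.Generator, n_atoms: int = 10,
                    elements=("H", "C", "N", "O", "F", "Cl", "S")) -> Molecule:
    coords = rng.uniform(-4, 4, size=(n_atoms, 3))
    atoms = [Atom(elements[rng.integers(len(elements))], *xyz) for xyz in coords]
    return Molecule(atoms=atoms, title="random")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix via QR of a Gaussian."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
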