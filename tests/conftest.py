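import numpy as np
import pytest

from aqpka import Atom, SpeciesRecord


@pytest.fixture
def diatomic_record():
    """CO-like diatomic, one mode at 500 cm^-1, solvated electronic energy."""
    return SpeciesRecord(
        label="diatomic",
        charge=0,
        multiplicity=1,
        atoms=[Atom("C", 0.0, 0.0, 0.0), Atom("O", 0.0, 0.0, 1.128)],
        frequencies=[500.0],
        electronic_energy=-300.0e6,  # J/mol
        symmetry_number=1,
    )


@pytest.fixture
def water_xyz(tmp_path):
    path = tmp_path / "water.xyz"
    path.write_text(
        "3\nwater, angstrom\n"
        "O 0.0000 0.0000 0.1173\n"
        "H 0.0000 0.7572 -0.4692\n"
        "H 0.0000 -0.7572 -0.4692\n"
    )
    return path


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation matrix via QR."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
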