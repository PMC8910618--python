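import numpy as np
import pytest

from specbind.synthetic import GroundTruth

IONIC_GRID = [0.001, 0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7]


@pytest.fixture
def truth_noise_free() -> GroundTruth:
    """Default study conditions, zero noise, fixed seed."""
    return GroundTruth(kd=9.5e-5, noise_shift=0.0, noise_cd=0.0, seed=1)


@pytest.fixture
def ionic_grid() -> np.ndarray:
    return np.array(IONIC_GRID)


@pytest.fixture
def tiny_pdb(tmp_path):
    """A minimal synthetic three-residue PDB file (not a real structure)."""
    lines = []
    serial = 1
    for i, (resname, resseq) in enumerate(
        [("ARG", 456), ("THR", 457), ("ALA", 458)]
    ):
        for atom in ("N", "CA", "C"):
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}{resname} A{resseq:4d}    "
                f"{1.0 * i:8.3f}{2.0 * i:8.3f}{3.0 * i:8.3f}  1.00 10.00"
                f"           {atom[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "synthetic_three_residues.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
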