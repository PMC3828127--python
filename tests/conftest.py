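import numpy as np
import pytest

from bridgescope.cd_unfold import UnfoldingFit
from bridgescope.structure_io import FrameEnsemble


def _pdb_atom(serial, name, resname, chain, resnum, x, y, z):
    return (
        f"ATOM  {serial:>5} {name:<4}{resname:>3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
        f"{name.strip()[0]:>2}"
    )


@pytest.fixture
def two_model_pdb(tmp_path):
    """Hand-written 2-model, 3-atom PDB with exactly known coordinates."""
    coords = {
        1: [(1.0, 2.0, 3.0), (4.0, 5.0, 6.0), (7.0, 8.0, 9.0)],
        2: [(1.5, 2.5, 3.5), (4.5, 5.5, 6.5), (7.5, 8.5, 9.5)],
    }
    lines = []
    for model, xyz in coords.items():
        lines.append(f"MODEL     {model:>4}")
        for i, (name, (x, y, z)) in enumerate(zip((" N  ", " CA ", " C  "), xyz), 1):
            lines.append(_pdb_atom(i, name, "ALA", "A", 1, x, y, z))
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path, coords


@pytest.fixture
def single_model_pdb(tmp_path):
    lines = [
        _pdb_atom(1, " N  ", "GLY", "A", 1, 0.0, 0.0, 0.0),
        _pdb_atom(2, " CA ", "GLY", "A", 1, 1.5, 0.0, 0.0),
        _pdb_atom(3, " C  ", "GLY", "A", 1, 2.0, 1.4, 0.0),
        "END",
    ]
    path = tmp_path / "single.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def table1_wildtype():
    """Two-state unfolding parameters of a well-behaved cooperative folder
    (normalized CD signal, 25 °C)."""
    return UnfoldingFit(y_f=0.016, m_f=0.0346, y_u=0.66, m_u=0.035,
                        m=1.24, dG_H2O=7.4)


@pytest.fixture
def table1_mutant():
    return UnfoldingFit(y_f=-0.003, m_f=0.054, y_u=0.64, m_u=0.035,
                        m=1.32, dG_H2O=7.5)


def make_ensemble(frames, names, resnums, resnames=None, chain="A"):
    """Shorthand FrameEnsemble constructor for hand-built test geometries."""
    frames = np.asarray(frames, dtype=float)
    if resnames is None:
        resnames = ["ALA"] * len(names)
    return FrameEnsemble(frames, names, resnums, resnames, [chain] * len(names))
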