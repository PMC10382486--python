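import numpy as np
import pytest

from petprofiler.synthetic_data import GeneratorConfig, make_ideal_structure


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.0, bfac=0.0, altloc=" ", icode=" ", record="ATOM  "):
    """One fixed-width PDB ATOM/HETATM line (wwPDB v3.3 columns)."""
    element = name.strip()[0]
    return (f"{record}{serial:5d} {name:^4s}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {element:>2s}")


def make_tripeptide_lines(resnames=("ALA", "CYS", "ASP"), c_n_gap=None):
    """ATOM lines for a 3-residue chain with idealized-ish geometry.

    ``c_n_gap`` displaces residue 3 along +x so that the C(2)-N(3) distance
    exceeds a chain-break cutoff.
    """
    lines = []
    serial = 1
    # simple trans-ish backbone: residues spaced 3.8 A along x
    for i, resname in enumerate(resnames):
        shift = np.array([3.8 * i, 0.0, 0.0])
        if c_n_gap is not None and i == 2:
            shift = shift + np.array([c_n_gap, 0.0, 0.0])
        atoms = {
            "N": np.array([0.0, 0.0, 0.0]) + shift,
            "CA": np.array([1.458, 0.0, 0.0]) + shift,
            "C": np.array([2.0, 1.4, 0.0]) + shift,
            "O": np.array([2.0, 2.6, 0.0]) + shift,
        }
        for name, xyz in atoms.items():
            lines.append(pdb_atom_line(serial, name, resname, "A", i + 1, *xyz))
            serial += 1
    return lines


@pytest.fixture
def tripeptide_pdb(tmp_path):
    path = tmp_path / "tri.pdb"
    path.write_text("\n".join(make_tripeptide_lines() + ["TER", "END"]) + "\n")
    return path


@pytest.fixture
def helix30():
    return make_ideal_structure(30, "helix", GeneratorConfig(seed=0))
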