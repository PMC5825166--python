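import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


def pdb_atom_line(
    serial, name, resname, chain, resseq, x, y, z,
    occ=1.0, element="C", altloc=" ", icode=" ", record="ATOM",
):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} "
        f"{chain}{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


def make_pdb_text(residues):
    """residues: list of (resname, resseq, [(atomname, element, xyz), ...])."""
    lines = []
    serial = 0
    for resname, resseq, atoms in residues:
        for name, element, (x, y, z) in atoms:
            serial += 1
            lines.append(
                pdb_atom_line(serial, name, resname, "A", resseq, x, y, z,
                              element=element)
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb():
    return make_pdb_text(
        [
            ("ALA", 1, [("N", "N", (0.0, 1.0, 0.0)), ("CA", "C", (0.0, 0.0, 0.0))]),
            ("GLY", 2, [("CA", "C", (3.8, 0.0, 0.0))]),
            ("SER", 3, [("CA", "C", (7.6, 0.0, 0.0)), ("OG", "O", (8.0, 1.0, 0.0))]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
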