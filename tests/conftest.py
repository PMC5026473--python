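import numpy as np
import pytest

from erisq.structure_io import Atom

# A hand-written miniature PDB: one lysine with an NZ atom, one water (must
# be dropped), one zero-occupancy atom (dropped), one atom with altloc A/B
# (only the first conformer kept), one hydrogen (dropped).
MINI_PDB = """\
ATOM      1  N   LYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  LYS A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  LYS A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  NZ  LYS A   1       5.000   2.000   0.000  1.00  0.00           N
ATOM      5  O   HOH A   2      10.000  10.000  10.000  1.00  0.00           O
ATOM      6  C1  LIG B   1       3.000   3.000   3.000  0.00  0.00           C
ATOM      7  C2 ALIG B   2       4.000   4.000   4.000  0.60  0.00           C
ATOM      8  C2 BLIG B   2       4.100   4.000   4.000  0.40  0.00           C
ATOM      9  H1  LIG B   2       4.000   4.000   5.000  1.00  0.00           H
ATOM     10  C3 BLIG B   3       6.000   6.000   6.000  1.00  0.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


def make_atom(pos, element="C", chain="X", resnum=1, resname="OBS", name=None, radius=None):
    from erisq.structure_io import vdw_radius_for

    return Atom(
        position=tuple(float(x) for x in pos),
        element=element,
        vdw_radius=radius if radius is not None else vdw_radius_for(element),
        chain_id=chain,
        residue_number=resnum,
        residue_name=resname,
        atom_name=name or element,
    )


def hemisphere_wall(radius=6.0, n=2000, rng_seed=7):
    """Obstacle atoms covering the z<0 hemisphere at the given radius."""
    rng = np.random.default_rng(rng_seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v = v[v[:, 2] < 0]
    return [make_atom(radius * p, resnum=i + 10) for i, p in enumerate(v)]
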