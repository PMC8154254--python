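import numpy as np
import pytest

import lretpath as lp
from lretpath import synthetic_data as syn


@pytest.fixture
def chain10():
    """10-bond covalent chain with its closed-form ground truth."""
    return syn.make_covalent_chain(10)


@pytest.fixture
def mini_protein_pdb(tmp_path):
    """Tiny heme protein: His ligating Fe, one Tyr, one Trp (heavy atoms).

    Hand-placed coordinates with idealized bond lengths; the Trp indole
    sits closer to the heme than the solvent-side Tyr hydroxyl.
    """
    text = """\
ATOM      1  N   HIS A   1       0.000   0.000   8.000  1.00  0.00           N
ATOM      2  CA  HIS A   1       1.450   0.000   8.000  1.00  0.00           C
ATOM      3  C   HIS A   1       2.000   0.000   9.400  1.00  0.00           C
ATOM      4  O   HIS A   1       1.300   0.000  10.400  1.00  0.00           O
ATOM      5  CB  HIS A   1       2.000   1.250   7.300  1.00  0.00           C
ATOM      6  CG  HIS A   1       1.700   1.350   5.850  1.00  0.00           C
ATOM      7  ND1 HIS A   1       0.800   2.230   5.320  1.00  0.00           N
ATOM      8  CD2 HIS A   1       2.200   0.650   4.800  1.00  0.00           C
ATOM      9  CE1 HIS A   1       0.850   2.080   4.000  1.00  0.00           C
ATOM     10  NE2 HIS A   1       1.700   1.100   3.650  1.00  0.00           N
ATOM     11  N   TYR A   2       3.330   0.000   9.500  1.00  0.00           N
ATOM     12  CA  TYR A   2       4.000   0.000  10.800  1.00  0.00           C
ATOM     13  C   TYR A   2       5.500   0.000  10.600  1.00  0.00           C
ATOM     14  O   TYR A   2       6.000   0.000   9.480  1.00  0.00           O
ATOM     15  CB  TYR A   2       3.600  -1.230  11.620  1.00  0.00           C
ATOM     16  CG  TYR A   2       4.200  -1.250  13.000  1.00  0.00           C
ATOM     17  CD1 TYR A   2       5.400  -1.900  13.250  1.00  0.00           C
ATOM     18  CD2 TYR A   2       3.560  -0.620  14.060  1.00  0.00           C
ATOM     19  CE1 TYR A   2       5.960  -1.930  14.520  1.00  0.00           C
ATOM     20  CE2 TYR A   2       4.110  -0.640  15.330  1.00  0.00           C
ATOM     21  CZ  TYR A   2       5.310  -1.300  15.560  1.00  0.00           C
ATOM     22  OH  TYR A   2       5.860  -1.320  16.820  1.00  0.00           O
ATOM     23  N   TRP A   3       6.250   0.000  11.700  1.00  0.00           N
ATOM     24  CA  TRP A   3       7.700   0.000  11.700  1.00  0.00           C
ATOM     25  C   TRP A   3       8.250   0.000  13.120  1.00  0.00           C
ATOM     26  O   TRP A   3       7.550   0.000  14.140  1.00  0.00           O
ATOM     27  CB  TRP A   3       8.250   1.230  10.950  1.00  0.00           C
ATOM     28  CG  TRP A   3       7.900   1.300   9.500  1.00  0.00           C
ATOM     29  CD1 TRP A   3       7.150   2.280   8.930  1.00  0.00           C
ATOM     30  CD2 TRP A   3       8.250   0.400   8.440  1.00  0.00           C
ATOM     31  NE1 TRP A   3       7.060   2.050   7.580  1.00  0.00           N
ATOM     32  CE2 TRP A   3       7.740   0.870   7.230  1.00  0.00           C
ATOM     33  CE3 TRP A   3       8.990  -0.780   8.450  1.00  0.00           C
ATOM     34  CZ2 TRP A   3       7.950   0.180   6.030  1.00  0.00           C
ATOM     35  CZ3 TRP A   3       9.200  -1.460   7.260  1.00  0.00           C
ATOM     36  CH2 TRP A   3       8.690  -0.980   6.070  1.00  0.00           C
HETATM   37 FE   HEM A 100       1.700   1.100   1.550  1.00  0.00          FE
HETATM   38  NA  HEM A 100       0.000   0.250   1.550  1.00  0.00           N
HETATM   39  NB  HEM A 100       2.550  -0.600   1.550  1.00  0.00           N
HETATM   40  NC  HEM A 100       3.400   1.950   1.550  1.00  0.00           N
HETATM   41  ND  HEM A 100       0.850   2.800   1.550  1.00  0.00           N
HETATM   42  C1A HEM A 100      -1.100   1.050   1.550  1.00  0.00           C
HETATM   43  C2A HEM A 100      -2.350   0.400   1.550  1.00  0.00           C
HETATM   44  C3A HEM A 100      -2.100  -0.950   1.550  1.00  0.00           C
HETATM   45  C4A HEM A 100      -0.700  -1.050   1.550  1.00  0.00           C
HETATM   46  CMA HEM A 100      -3.100  -2.050   1.550  1.00  0.00           C
HETATM   47  C1B HEM A 100       2.100  -1.900   1.550  1.00  0.00           C
HETATM   48  C2B HEM A 100       3.150  -2.850   1.550  1.00  0.00           C
HETATM   49  C3B HEM A 100       4.300  -2.100   1.550  1.00  0.00           C
HETATM   50  C4B HEM A 100       3.900  -0.750   1.550  1.00  0.00           C
HETATM   51  CMB HEM A 100       3.000  -4.330   1.550  1.00  0.00           C
HETATM   52  C1C HEM A 100       4.500   2.750   1.550  1.00  0.00           C
HETATM   53  C2C HEM A 100       5.750   2.100   1.550  1.00  0.00           C
HETATM   54  C3C HEM A 100       5.500   4.350   1.550  1.00  0.00           C
HETATM   55  C4C HEM A 100       4.100   4.450   1.550  1.00  0.00           C
HETATM   56  CMC HEM A 100       6.500   5.450   1.550  1.00  0.00           C
HETATM   57  C1D HEM A 100       1.300   4.100   1.550  1.00  0.00           C
HETATM   58  C2D HEM A 100       0.250   5.050   1.550  1.00  0.00           C
HETATM   59  C3D HEM A 100      -0.900   4.300   1.550  1.00  0.00           C
HETATM   60  C4D HEM A 100      -0.500   2.950   1.550  1.00  0.00           C
HETATM   61  CMD HEM A 100       0.400   6.530   1.550  1.00  0.00           C
END
"""
    path = tmp_path / "mini_protein.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def bridge_toggle_trajectory():
    """Three polar atoms; the middle one bridges donor and acceptor in
    "on" frames and is displaced far away in "off" frames.

    On frames: X-P and P-Y hydrogen-bond jumps at 2.4 Å (heavy-atom
    fallback) beat the direct 4.8 Å space jump. Off frames: only the direct
    space edge remains. Both route scores are closed-form.
    """
    def build(pattern):
        atoms = [
            lp.Atom(serial=1, name="O", element="O", residue_name="HOH",
                    residue_number=1, chain_id="W", position=np.zeros(3),
                    is_het=True, is_water=True),
            lp.Atom(serial=2, name="O", element="O", residue_name="HOH",
                    residue_number=2, chain_id="W", position=np.array([2.4, 0.0, 0.0]),
                    is_het=True, is_water=True),
            lp.Atom(serial=3, name="O", element="O", residue_name="HOH",
                    residue_number=3, chain_id="W", position=np.array([4.8, 0.0, 0.0]),
                    is_het=True, is_water=True),
        ]
        topo = lp.Structure(atoms=atoms, identifier="bridge_toggle")
        frames = []
        for on in pattern:
            p = [2.4, 0.0, 0.0] if on else [2.4, 9.0, 0.0]
            frames.append(np.array([[0.0, 0.0, 0.0], p, [4.8, 0.0, 0.0]]))
        return lp.Trajectory(topology=topo, frames=frames)

    return build
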