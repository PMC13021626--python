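"""Shared fixtures: tiny compendium tables and programmatically built structures."""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from phosphocoreg import SiteID, Thresholds, read_compendium


# ---------------------------------------------------------------- compendium

HEADER = "dataset_id\tpmid\tcondition_code\tkind\tgene_symbol\tuniprot_acc\tresidue\tposition\tfold_change\tp_value"


def compendium_text(rows: list[str]) -> str:
    return HEADER + "\n" + "\n".join(rows) + "\n"


@pytest.fixture
def small_compendium(tmp_path):
    """2 profiling + 2 differential datasets over two proteins.

    TNIK_S640 is UP in ds1 and DOWN in ds2; OTHER_S10 follows it in both
    (one concordant UP pair, one concordant DOWN pair); OTHER_T20 is NS.
    """
    rows = [
        "pf1\tP01\tcA\tprofiling\tTNIK\tQ9UKE5\tS\t640\t\t",
        "pf1\tP01\tcA\tprofiling\tOTHER\tO00001\tS\t10\t\t",
        "pf2\tP01\tcB\tprofiling\tTNIK\tQ9UKE5\tS\t640\t\t",
        "ds1\tP02\tcA\tdifferential\tTNIK\tQ9UKE5\tS\t640\t2.0\t0.01",
        "ds1\tP02\tcA\tdifferential\tOTHER\tO00001\tS\t10\t1.8\t0.02",
        "ds1\tP02\tcA\tdifferential\tOTHER\tO00001\tT\t20\t1.1\t0.5",
        "ds2\tP03\tcB\tdifferential\tTNIK\tQ9UKE5\tS\t640\t0.5\t0.02",
        "ds2\tP03\tcB\tdifferential\tOTHER\tO00001\tS\t10\t0.6\t0.01",
        "ds2\tP03\tcB\tdifferential\tOTHER\tO00001\tT\t20\t1.0\t0.9",
    ]
    path = tmp_path / "compendium.tsv"
    path.write_text(compendium_text(rows))
    return read_compendium(path)


@pytest.fixture
def anchor():
    return SiteID("TNIK", 640, "S", "Q9UKE5")


@pytest.fixture
def default_thresholds():
    return Thresholds()


# ----------------------------------------------------------------- structure


def _atoms(coords, res_ids, res_names, atom_names, b_factors, elements=None):
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = res_ids
    arr.res_name[:] = res_names
    arr.atom_name[:] = atom_names
    arr.element[:] = elements if elements is not None else [a[0] for a in atom_names]
    arr.hetero[:] = False
    arr.set_annotation("b_factor", np.asarray(b_factors, dtype=np.float32))
    return arr


def write_pdb(path, array) -> None:
    f = PDBFile()
    f.set_structure(array)
    f.write(str(path))


def ca_trace(coords, b_factors=None, res_name="ALA"):
    n = len(coords)
    if b_factors is None:
        b_factors = [50.0] * n
    return _atoms(coords, list(range(1, n + 1)), [res_name] * n, ["CA"] * n, b_factors)


def ideal_helix_coords(n: int) -> np.ndarray:
    """CA positions of an ideal alpha helix (2.3 A radius, 1.5 A rise, 100 deg/residue)."""
    theta = np.deg2rad(100.0 * np.arange(n))
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)])


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    return radius * np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@pytest.fixture
def helix_pdb(tmp_path):
    """15-residue ideal helix, CA trace, pLDDT 90 everywhere."""
    path = tmp_path / "helix.pdb"
    write_pdb(path, ca_trace(ideal_helix_coords(15), b_factors=[90.0] * 15))
    return path


@pytest.fixture
def coil_pdb(tmp_path):
    """Straight extended CA trace: assigned coil everywhere (all-loop model)."""
    path = tmp_path / "coil.pdb"
    coords = np.column_stack([3.8 * np.arange(10), np.zeros(10), np.zeros(10)])
    write_pdb(path, ca_trace(coords, b_factors=[37.75] * 10))
    return path


@pytest.fixture
def single_residue_pdb(tmp_path):
    """One free serine: its ASA exceeds the folded-chain maximum (RSA clips to 1)."""
    path = tmp_path / "single.pdb"
    coords = [[0.0, 0.0, 0.0], [1.46, 0.0, 0.0], [2.0, 1.42, 0.0], [3.2, 1.6, 0.2], [2.0, -0.8, 1.2]]
    arr = _atoms(coords, [1] * 5, ["SER"] * 5, ["N", "CA", "C", "O", "OG"], [80.0] * 5)
    write_pdb(path, arr)
    return path


@pytest.fixture
def buried_pdb(tmp_path):
    """A central glycine CA enclosed by a dense shell of glycine CA atoms."""
    path = tmp_path / "buried.pdb"
    shell = fibonacci_sphere(120, 4.0)
    coords = np.vstack([[[0.0, 0.0, 0.0]], shell])
    n = len(coords)
    arr = _atoms(coords, list(range(1, n + 1)), ["GLY"] * n, ["CA"] * n, [50.0] * n)
    write_pdb(path, arr)
    return path


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.10           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 90.10           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 90.10           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 90.10           O
ATOM      5  N   SER A   2       3.332   1.536   0.000  1.00 37.75           N
ATOM      6  CA  SER A   2       3.988   2.839   0.000  1.00 37.75           C
ATOM      7  C   SER A   2       5.504   2.693   0.000  1.00 37.75           C
ATOM      8  O   SER A   2       6.030   1.581   0.000  1.00 37.75           O
ATOM      9  N   GLY A   3       6.223   3.812   0.000  1.00 55.20           N
ATOM     10  CA  GLY A   3       7.675   3.789   0.000  1.00 55.20           C
ATOM     11  C   GLY A   3       8.260   5.190   0.000  1.00 55.20           C
ATOM     12  O   GLY A   3       7.530   6.180   0.000  1.00 55.20           O
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def hetatm_pdb(tmp_path):
    path = tmp_path / "hetatm.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


# -------------------------------------------------------------- conservation


@pytest.fixture
def toy_taxonomy_tables():
    """NCBI-style pruned tree: mammals, fish and fly under Bilateria."""
    edges = [
        ("Euteleostomi", "Bilateria"),
        ("Tetrapoda", "Euteleostomi"),
        ("Mammalia", "Tetrapoda"),
        ("Boreoeutheria", "Mammalia"),
        ("human", "Boreoeutheria"),
        ("mouse", "Boreoeutheria"),
        ("zebrafish", "Euteleostomi"),
        ("fly", "Bilateria"),
    ]
    species = [(s, s) for s in ("human", "mouse", "zebrafish", "fly")]
    return edges, species


@pytest.fixture
def toy_taxonomy(toy_taxonomy_tables):
    import pandas as pd

    from phosphocoreg import TaxonomyTable

    edges, species = toy_taxonomy_tables
    return TaxonomyTable.from_tables(
        pd.DataFrame(edges, columns=["child", "parent"]),
        pd.DataFrame(species, columns=["species", "leaf"]),
    )
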