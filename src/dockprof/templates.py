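"""Residue chemistry tables and idealized side-chain coordinates.

Two kinds of knowledge live here:

* ``RESIDUE_CHEMISTRY`` — which atoms of each standard amino acid act as
  H-bond donors/acceptors, charged groups, aromatic rings and hydrophobic
  carbons. Used by interaction typing on any receptor frame (coordinates
  come from the frame, only the atom names come from the table).
* ``RESIDUE_COORDS`` — idealized free-standing residue geometries (probe
  atom near the origin, body extending towards +x) used by the synthetic
  pocket builder. Bond lengths are approximate; the fixtures are
  geometric, not physical.

Hydrogens are not required anywhere: donor/acceptor roles are assigned to
heavy atoms, matching docking outputs that carry no hydrogens.
"""

from __future__ import annotations

__all__ = ["ResidueChemistry", "RESIDUE_CHEMISTRY", "RESIDUE_COORDS", "STANDARD_AA"]

from dataclasses import dataclass


@dataclass(frozen=True)
class ResidueChemistry:
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    cation_groups: tuple[tuple[str, ...], ...] = ()
    anion_groups: tuple[tuple[str, ...], ...] = ()
    rings: tuple[tuple[str, ...], ...] = ()
    hydrophobic: tuple[str, ...] = ()


_BB_DONOR = ("N",)
_BB_ACC = ("O", "OXT")


def _chem(donors=(), acceptors=(), cations=(), anions=(), rings=(), hydrophobic=(),
          backbone_donor=True) -> ResidueChemistry:
    return ResidueChemistry(
        donors=(_BB_DONOR if backbone_donor else ()) + tuple(donors),
        acceptors=_BB_ACC + tuple(acceptors),
        cation_groups=tuple(tuple(g) for g in cations),
        anion_groups=tuple(tuple(g) for g in anions),
        rings=tuple(tuple(r) for r in rings),
        hydrophobic=tuple(hydrophobic),
    )


STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

RESIDUE_CHEMISTRY: dict[str, ResidueChemistry] = {
    "ALA": _chem(hydrophobic=("CB",)),
    "ARG": _chem(donors=("NE", "NH1", "NH2"),
                 cations=(("CZ", "NE", "NH1", "NH2"),),
                 hydrophobic=("CB", "CG")),
    "ASN": _chem(donors=("ND2",), acceptors=("OD1",), hydrophobic=("CB",)),
    "ASP": _chem(acceptors=("OD1", "OD2"), anions=(("CG", "OD1", "OD2"),),
                 hydrophobic=("CB",)),
    "CYS": _chem(hydrophobic=("CB",)),
    "GLN": _chem(donors=("NE2",), acceptors=("OE1",), hydrophobic=("CB", "CG")),
    "GLU": _chem(acceptors=("OE1", "OE2"), anions=(("CD", "OE1", "OE2"),),
                 hydrophobic=("CB", "CG")),
    "GLY": _chem(),
    # neutral His by default: both ring nitrogens listed as donor and acceptor
    "HIS": _chem(donors=("ND1", "NE2"), acceptors=("ND1", "NE2"),
                 rings=(("CG", "ND1", "CD2", "CE1", "NE2"),),
                 hydrophobic=("CB",)),
    "ILE": _chem(hydrophobic=("CB", "CG1", "CG2", "CD1")),
    "LEU": _chem(hydrophobic=("CB", "CG", "CD1", "CD2")),
    "LYS": _chem(donors=("NZ",), cations=(("NZ",),),
                 hydrophobic=("CB", "CG", "CD")),
    "MET": _chem(hydrophobic=("CB", "CG", "CE")),
    "PHE": _chem(rings=(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
                 hydrophobic=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "PRO": _chem(hydrophobic=("CB", "CG"), backbone_donor=False),
    "SER": _chem(donors=("OG",), acceptors=("OG",)),
    "THR": _chem(donors=("OG1",), acceptors=("OG1",), hydrophobic=("CG2",)),
    "TRP": _chem(donors=("NE1",),
                 rings=(("CG", "CD1", "NE1", "CE2", "CD2"),
                        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
                 hydrophobic=("CB", "CG", "CD1", "CD2", "CE2", "CE3",
                              "CZ2", "CZ3", "CH2")),
    "TYR": _chem(donors=("OH",), acceptors=("OH",),
                 rings=(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
                 hydrophobic=("CB", "CG", "CD1", "CD2", "CE1", "CE2")),
    "VAL": _chem(hydrophobic=("CB", "CG1", "CG2")),
}


# ---------------------------------------------------------------------------
# Idealized coordinates for the synthetic pocket builder
# ---------------------------------------------------------------------------
# Each entry: list of (atom_name, element, (x, y, z)). The conventional
# probe atom (the one the builder places at a prescribed distance from a
# ligand feature) sits at/near the origin and the rest of the residue
# extends towards +x, i.e. away from the ligand.

RESIDUE_COORDS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "SER": [
        ("OG", "O", (0.0, 0.0, 0.0)),
        ("CB", "C", (1.40, 0.30, 0.00)),
        ("CA", "C", (2.80, -0.30, 0.20)),
        ("N", "N", (3.60, 0.90, 0.50)),
        ("C", "C", (3.50, -1.50, -0.40)),
        ("O", "O", (3.00, -2.60, -0.60)),
    ],
    "THR": [
        ("OG1", "O", (0.0, 0.0, 0.0)),
        ("CB", "C", (1.43, 0.00, 0.00)),
        ("CG2", "C", (2.10, 1.30, 0.10)),
        ("CA", "C", (2.20, -1.30, 0.10)),
        ("N", "N", (1.60, -2.50, 0.20)),
        ("C", "C", (3.70, -1.30, 0.20)),
        ("O", "O", (4.40, -2.30, 0.20)),
    ],
    "LYS": [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CE", "C", (1.50, 0.20, 0.00)),
        ("CD", "C", (2.90, -0.40, 0.10)),
        ("CG", "C", (4.30, 0.30, 0.20)),
        ("CB", "C", (5.70, -0.30, 0.30)),
        ("CA", "C", (7.10, 0.30, 0.40)),
        ("N", "N", (7.80, 1.50, 0.60)),
        ("C", "C", (7.90, -0.90, 0.20)),
        ("O", "O", (7.40, -2.00, 0.10)),
    ],
    "ARG": [
        ("NH1", "N", (0.0, 0.0, 0.0)),
        ("CZ", "C", (1.33, 0.00, 0.00)),
        ("NH2", "N", (2.00, 1.10, 0.00)),
        ("NE", "N", (2.00, -1.10, 0.00)),
        ("CD", "C", (3.40, -1.40, 0.10)),
        ("CG", "C", (4.50, -0.40, 0.20)),
        ("CB", "C", (5.90, -0.90, 0.30)),
        ("CA", "C", (7.00, 0.10, 0.40)),
        ("N", "N", (6.80, 1.40, 0.50)),
        ("C", "C", (8.40, -0.40, 0.40)),
        ("O", "O", (9.30, 0.40, 0.50)),
    ],
    "ASP": [
        ("OD1", "O", (0.0, 1.10, 0.0)),
        ("OD2", "O", (0.0, -1.10, 0.0)),
        ("CG", "C", (0.70, 0.00, 0.00)),
        ("CB", "C", (2.20, 0.00, 0.10)),
        ("CA", "C", (3.60, 0.50, 0.20)),
        ("N", "N", (4.30, 1.70, 0.30)),
        ("C", "C", (4.50, -0.70, 0.10)),
        ("O", "O", (4.20, -1.90, 0.00)),
    ],
    "ASN": [
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (1.23, 0.00, 0.00)),
        ("ND2", "N", (1.90, 1.10, 0.00)),
        ("CB", "C", (2.00, -1.30, 0.10)),
        ("CA", "C", (3.50, -1.40, 0.20)),
        ("N", "N", (4.20, -0.20, 0.30)),
        ("C", "C", (4.10, -2.70, 0.20)),
        ("O", "O", (3.50, -3.80, 0.10)),
    ],
    "LEU": [
        ("CD1", "C", (0.0, 0.0, 0.0)),
        ("CG", "C", (1.50, 0.30, 0.00)),
        ("CD2", "C", (2.20, 1.50, 0.30)),
        ("CB", "C", (2.30, -0.90, -0.10)),
        ("CA", "C", (3.80, -0.80, 0.00)),
        ("N", "N", (4.50, 0.40, 0.20)),
        ("C", "C", (4.40, -2.10, -0.20)),
        ("O", "O", (3.80, -3.20, -0.40)),
    ],
    # ring centroid at origin, ring in the y-z plane, normal along +x
    "PHE": [
        ("CG", "C", (0.0, 1.39, 0.0)),
        ("CD1", "C", (0.0, 0.695, 1.204)),
        ("CE1", "C", (0.0, -0.695, 1.204)),
        ("CZ", "C", (0.0, -1.39, 0.0)),
        ("CE2", "C", (0.0, -0.695, -1.204)),
        ("CD2", "C", (0.0, 0.695, -1.204)),
        ("CB", "C", (0.40, 2.85, 0.00)),
        ("CA", "C", (1.20, 3.90, 0.20)),
        ("N", "N", (0.80, 5.20, 0.30)),
        ("C", "C", (2.70, 3.70, 0.20)),
        ("O", "O", (3.40, 4.70, 0.30)),
    ],
    "ZN": [("ZN", "ZN", (0.0, 0.0, 0.0))],
    "HOH": [("O", "O", (0.0, 0.0, 0.0))],
}
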