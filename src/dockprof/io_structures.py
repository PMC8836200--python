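"""Structure I/O: receptor frames (PDB), docked ligand poses (SDF) and moiety schemes.

This module establishes the two correspondence guarantees everything
downstream relies on:

* every pose of a given ligand has the same atom count, element sequence
  and bond list, so atom ``i`` in one pose corresponds to atom ``i`` in
  any other pose (and in a reference pose);
* every pose carries the id of the receptor frame it was docked into, and
  that id resolves to a loaded frame.

Conventions: residue numbers are taken verbatim from the PDB (1-based,
author chain ids); atom indices used in moiety configs and in all outputs
are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml
from rdkit import Chem

__all__ = [
    "ResidueId",
    "ReceptorFrame",
    "LigandPose",
    "MoietyScheme",
    "StructureError",
    "read_receptor_frames",
    "write_receptor_frame",
    "read_poses",
    "write_poses",
    "load_moiety_scheme",
    "check_pose_frame_links",
]

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SPC", "H2O"}

#: elements treated as metal centres when found in a receptor frame
METAL_ELEMENTS = {"ZN", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CD"}


class StructureError(ValueError):
    """Hard error raised for unparseable or inconsistent structure input."""


@dataclass(frozen=True)
class ResidueId:
    """Author-style residue identity: chain, number, insertion code, name."""

    chain: str
    resnum: int
    icode: str
    resname: str

    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}:{self.resname}{self.resnum}{ic}"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    residue_ref: int
    formal_charge: int = 0
    is_aromatic: bool = False


@dataclass
class ReceptorFrame:
    """One receptor conformation: residues, atoms and (optionally) waters.

    Water oxygens are routed to :attr:`waters` and never appear in
    :attr:`atoms`; metal ions stay in :attr:`atoms` (their residue is kept)
    and are recognised by element downstream.
    """

    frame_id: str
    atoms: list[Atom] = field(default_factory=list)
    residues: list[ResidueId] = field(default_factory=list)
    waters: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_atoms(self) -> dict[int, list[int]]:
        """Map residue index -> indices into ``atoms``."""
        out: dict[int, list[int]] = {i: [] for i in range(len(self.residues))}
        for i, a in enumerate(self.atoms):
            out[a.residue_ref].append(i)
        return out

    def validate(self) -> None:
        ids = [(r.chain, r.resnum, r.icode) for r in self.residues]
        if len(set(ids)) != len(ids):
            raise StructureError(f"frame {self.frame_id}: duplicate residue identities")
        for i, a in enumerate(self.atoms):
            if not (0 <= a.residue_ref < len(self.residues)):
                raise StructureError(
                    f"frame {self.frame_id}: atom {i} has invalid residue_ref {a.residue_ref}"
                )
            if not np.all(np.isfinite(a.coords)):
                raise StructureError(f"frame {self.frame_id}: atom {i} has non-finite coordinates")


@dataclass
class LigandPose:
    """One docked conformer of a ligand.

    All poses of the same ``ligand_name`` must share atom count, element
    sequence, formal charges and bond list — only the coordinates differ.
    """

    pose_id: str
    ligand_name: str
    frame_id: str
    rank: int
    score: float
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Å, heavy and H in file order
    formal_charges: list[int]
    aromatic_flags: list[bool]
    bonds: list[tuple[int, int, float]]  # (i, j, order); aromatic order = 1.5

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if e != "H"]

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices()]

    def topology_key(self) -> tuple:
        return (
            tuple(self.elements),
            tuple(self.formal_charges),
            tuple(sorted((min(i, j), max(i, j), o) for i, j, o in self.bonds)),
        )


@dataclass
class MoietyScheme:
    """Partition of a ligand's heavy atoms into named moieties.

    ``assignment`` maps heavy-atom index (0-based, counted over heavy atoms
    in pose order) to a moiety label; every heavy atom must be covered
    exactly once and every label used at least once.
    """

    ligand_name: str
    labels: list[str]
    assignment: dict[int, str]

    def validate(self, pose: LigandPose) -> None:
        heavy = pose.heavy_indices()
        n_heavy = len(heavy)
        missing = [i for i in range(n_heavy) if i not in self.assignment]
        if missing:
            raise StructureError(
                f"moiety scheme for {self.ligand_name!r} leaves heavy atoms uncovered: {missing}"
            )
        out_of_range = [i for i in self.assignment if i < 0 or i >= n_heavy]
        if out_of_range:
            raise StructureError(
                f"moiety scheme for {self.ligand_name!r} has out-of-range indices: "
                f"{sorted(out_of_range)} (ligand has {n_heavy} heavy atoms)"
            )
        used = set(self.assignment.values())
        unused = [lab for lab in self.labels if lab not in used]
        if unused:
            raise StructureError(
                f"moiety scheme for {self.ligand_name!r} declares unused labels: {unused}"
            )
        unknown = sorted(used - set(self.labels))
        if unknown:
            raise StructureError(
                f"moiety scheme for {self.ligand_name!r} assigns undeclared labels: {unknown}"
            )


# ---------------------------------------------------------------------------
# PDB frames
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Check ATOM/HETATM coordinate fields parse as floats.

    gemmi is deliberately tolerant of malformed records; the pipeline wants
    a hard error naming the offending line instead of silently corrupted
    coordinates.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureError(f"{path}:{lineno}: truncated coordinate record: {line.rstrip()!r}")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fldtxt = line[lo:hi]
                try:
                    float(fldtxt)
                except ValueError:
                    raise StructureError(
                        f"{path}:{lineno}: malformed coordinate field {fldtxt!r} in {line.rstrip()!r}"
                    ) from None


def read_receptor_frames(paths: Sequence[str | Path]) -> list[ReceptorFrame]:
    """Read one :class:`ReceptorFrame` per single-model PDB file.

    Frame ids are the filename stems; input order is preserved. Water
    residues (HOH/WAT/...) are routed to ``frame.waters``. Alternate
    locations other than blank/'A' are discarded with a warning.
    """
    frames: list[ReceptorFrame] = []
    seen_ids: set[str] = set()
    for path in paths:
        path = Path(path)
        frame_id = path.stem
        if frame_id in seen_ids:
            raise StructureError(f"duplicate frame_id {frame_id!r} (from {path})")
        seen_ids.add(frame_id)
        _validate_pdb_text(path)
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
        if len(st) == 0:
            raise StructureError(f"{path}: no model found")
        if len(st) > 1:
            raise StructureError(f"{path}: multi-model PDB files are not supported")
        frame = ReceptorFrame(frame_id=frame_id)
        waters: list[list[float]] = []
        dropped_altloc = 0
        for chain in st[0]:
            for res in chain:
                resname = res.name.strip()
                if resname in WATER_RESNAMES:
                    for atom in res:
                        if atom.element.name == "O":
                            waters.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    continue
                rid = ResidueId(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or " ").strip() or "",
                    resname=resname,
                )
                frame.residues.append(rid)
                ridx = len(frame.residues) - 1
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        dropped_altloc += 1
                        continue
                    frame.atoms.append(
                        Atom(
                            name=atom.name,
                            element=atom.element.name.upper(),
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            residue_ref=ridx,
                        )
                    )
        if dropped_altloc:
            warnings.warn(
                f"{path}: discarded {dropped_altloc} alternate-location atoms (kept altloc ''/'A')",
                stacklevel=2,
            )
        frame.waters = np.array(waters, dtype=float) if waters else np.zeros((0, 3))
        frame.validate()
        frames.append(frame)
    return frames


def write_receptor_frame(frame: ReceptorFrame, path: str | Path) -> None:
    """Write a frame back to a single-model PDB file (waters as HOH)."""
    st = gemmi.Structure()
    st.name = frame.frame_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    atoms_by_res = frame.residue_atoms()
    for ridx, rid in enumerate(frame.residues):
        if rid.chain not in chains:
            chains[rid.chain] = gemmi.Chain(rid.chain)
        res = gemmi.Residue()
        res.name = rid.resname
        res.seqid = gemmi.SeqId(rid.resnum, rid.icode or " ")
        res.het_flag = "A" if rid.resname.upper() in _STANDARD_AA else "H"
        # attach atoms before add_residue: gemmi residue handles go stale
        # when the chain's residue vector reallocates
        for ai in atoms_by_res[ridx]:
            atom = frame.atoms[ai]
            a = gemmi.Atom()
            a.name = atom.name
            a.element = gemmi.Element(atom.element.capitalize())
            a.pos = gemmi.Position(*atom.coords)
            a.occ = 1.0
            res.add_atom(a)
        chains[rid.chain].add_residue(res)
    if len(frame.waters):
        wchain = chains.setdefault("W", gemmi.Chain("W"))
        for i, w in enumerate(frame.waters, start=1):
            res = gemmi.Residue()
            res.name = "HOH"
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "H"
            a = gemmi.Atom()
            a.name = "O"
            a.element = gemmi.Element("O")
            a.pos = gemmi.Position(*w)
            a.occ = 1.0
            res.add_atom(a)
            wchain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# SDF poses
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def _pose_from_mol(mol: Chem.Mol, record_idx: int, frame_key: str, rank_key: str,
                   score_key: str) -> LigandPose:
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"ligand{record_idx}"
    if not mol.HasProp(frame_key):
        raise StructureError(
            f"SDF record {record_idx} ({name!r}): missing frame property {frame_key!r}"
        )
    frame_id = mol.GetProp(frame_key).strip()
    rank = int(mol.GetProp(rank_key)) if mol.HasProp(rank_key) else record_idx + 1
    score = float(mol.GetProp(score_key)) if mol.HasProp(score_key) else float("nan")
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    aromatic = [a.GetIsAromatic() for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
        for b in mol.GetBonds()
    ]
    return LigandPose(
        pose_id=f"{name}/{frame_id}/r{rank}",
        ligand_name=name,
        frame_id=frame_id,
        rank=rank,
        score=score,
        elements=elements,
        coords=coords,
        formal_charges=charges,
        aromatic_flags=aromatic,
        bonds=bonds,
    )


def read_poses(path: str | Path, frame_key: str = "frame_id", rank_key: str = "rank",
               score_key: str = "score") -> list[LigandPose]:
    """Read docked poses from an SDF file, in file order.

    Each record must carry the receptor-frame id under ``frame_key``;
    ``rank_key``/``score_key`` are optional per record. Atom-order
    invariance across records of the same ligand name is enforced: two
    records of one ligand with differing element sequence, charges or bond
    list are a hard error ("atom correspondence broken").

    Heavy-atom count per pose must be >= 3 (an RMSD/superposition
    requirement downstream).
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses: list[LigandPose] = []
    topo_by_ligand: dict[str, tuple] = {}
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: SDF record {idx} could not be parsed")
        try:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            )
        except Exception as exc:  # pragma: no cover - rdkit error classes vary
            raise StructureError(f"{path}: SDF record {idx} failed sanitization: {exc}") from exc
        pose = _pose_from_mol(mol, idx, frame_key, rank_key, score_key)
        if len(pose.heavy_indices()) < 3:
            raise StructureError(
                f"{path}: pose {pose.pose_id} has fewer than 3 heavy atoms"
            )
        key = pose.topology_key()
        ref = topo_by_ligand.setdefault(pose.ligand_name, key)
        if key != ref:
            raise StructureError(
                f"{path}: atom correspondence broken for ligand {pose.ligand_name!r} "
                f"at record {idx} (element sequence, charges or bonds differ)"
            )
        poses.append(pose)
    # disambiguate pose ids when several records share (ligand, frame, rank)
    seen: dict[str, int] = {}
    for pose in poses:
        n = seen.get(pose.pose_id, 0)
        seen[pose.pose_id] = n + 1
        if n:
            pose.pose_id = f"{pose.pose_id}.{n}"
    return poses


def write_poses(poses: Iterable[LigandPose], path: str | Path,
                frame_key: str = "frame_id", rank_key: str = "rank",
                score_key: str = "score") -> None:
    """Write poses to SDF V2000 with frame/rank/score data properties."""
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in poses:
            rw = Chem.RWMol()
            for el, q in zip(pose.elements, pose.formal_charges):
                a = Chem.Atom(el)
                a.SetFormalCharge(int(q))
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            for i, j, order in pose.bonds:
                bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                      3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}[order]
                rw.AddBond(int(i), int(j), bt)
            for i, flag in enumerate(pose.aromatic_flags):
                rw.GetAtomWithIdx(i).SetIsAromatic(bool(flag))
            for b in rw.GetBonds():
                if pose.aromatic_flags[b.GetBeginAtomIdx()] and pose.aromatic_flags[b.GetEndAtomIdx()] \
                        and b.GetBondType() == Chem.BondType.AROMATIC:
                    b.SetIsAromatic(True)
            mol = rw.GetMol()
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(pose.coords):
                conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
            mol.AddConformer(conf)
            mol.SetProp("_Name", pose.ligand_name)
            mol.SetProp(frame_key, pose.frame_id)
            mol.SetProp(rank_key, str(pose.rank))
            mol.SetProp(score_key, f"{pose.score:.4f}")
            writer.write(mol)
    finally:
        writer.close()


def check_pose_frame_links(poses: Sequence[LigandPose],
                           frames: Sequence[ReceptorFrame]) -> None:
    """Referential integrity: every pose's frame_id must resolve to a frame."""
    known = {f.frame_id for f in frames}
    orphans = [p.pose_id for p in poses if p.frame_id not in known]
    if orphans:
        raise StructureError(
            f"{len(orphans)} poses reference unknown frames: {orphans[:10]}"
            + (" ..." if len(orphans) > 10 else "")
        )


# ---------------------------------------------------------------------------
# Moiety schemes
# ---------------------------------------------------------------------------

def load_moiety_scheme(path: str | Path, pose: LigandPose) -> MoietyScheme:
    """Load and validate a moiety scheme from a YAML config.

    Schema::

        ligand: <name>
        moieties:
          - label: sugar
            indices: [0, 1, 2, ...]    # 0-based heavy-atom indices
          - label: sulfate
            indices: [...]

    Indices are over heavy atoms only, in pose atom order. Overlapping or
    uncovered indices are hard errors.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "moieties" not in cfg:
        raise StructureError(f"{path}: moiety config must define a 'moieties' list")
    ligand_name = str(cfg.get("ligand", pose.ligand_name))
    if ligand_name != pose.ligand_name:
        raise StructureError(
            f"{path}: config is for ligand {ligand_name!r}, pose is {pose.ligand_name!r}"
        )
    labels: list[str] = []
    assignment: dict[int, str] = {}
    for entry in cfg["moieties"]:
        label = str(entry["label"])
        if label in labels:
            raise StructureError(f"{path}: duplicate moiety label {label!r}")
        labels.append(label)
        for i in entry["indices"]:
            i = int(i)
            if i in assignment:
                raise StructureError(
                    f"{path}: heavy atom {i} assigned to both "
                    f"{assignment[i]!r} and {label!r}"
                )
            assignment[i] = label
    scheme = MoietyScheme(ligand_name=ligand_name, labels=labels, assignment=assignment)
    scheme.validate(pose)
    return scheme


def save_moiety_scheme(scheme: MoietyScheme, path: str | Path) -> None:
    by_label: dict[str, list[int]] = {lab: [] for lab in scheme.labels}
    for i in sorted(scheme.assignment):
        by_label[scheme.assignment[i]].append(i)
    cfg = {
        "ligand": scheme.ligand_name,
        "moieties": [{"label": lab, "indices": by_label[lab]} for lab in scheme.labels],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
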