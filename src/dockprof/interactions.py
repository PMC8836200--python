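"""Geometric detection and typing of protein-ligand contacts.

Nine contact classes are profiled between each docked pose and its
receptor frame: hydrogen bonds, halogen bonds, salt bridges (ionic),
Pi-cation, Pi-Pi, hydrophobic, water-mediated hydrogen bonds, aromatic
hydrogen bonds and metal contacts. All criteria are heavy-atom
distance/angle rules (docking outputs typically carry no hydrogens), with
defaults following widely used open profiling conventions; every cutoff is
overridable and echoed into output metadata.

Records are deduplicated per ``(pose, residue, moiety, itype)``: the
downstream per-cluster frequency counts *poses* exhibiting a contact, so
several geometric instances in one pose must not inflate it.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_structures import METAL_ELEMENTS, LigandPose, MoietyScheme, ReceptorFrame, ResidueId
from .templates import RESIDUE_CHEMISTRY

__all__ = [
    "InteractionParams",
    "InteractionRecord",
    "LigandChemistry",
    "FrameChemistry",
    "ITYPES",
    "perceive_ligand",
    "perceive_frame",
    "perceive_chemistry",
    "detect_interactions",
    "interaction_report",
    "records_to_frame",
]

ITYPES = (
    "hbond", "halogen_bond", "ionic", "pi_cation", "pi_pi",
    "hydrophobic", "water_hbond", "aromatic_hbond", "metal",
)


@dataclass(frozen=True)
class InteractionParams:
    """Geometric cutoffs (Å / degrees) for the nine contact classes."""

    hbond_dist: float = 3.5
    ionic_dist: float = 4.0
    pipi_dist: float = 5.5
    pipi_parallel_angle: float = 30.0
    pipi_tshape_angle_lo: float = 60.0
    pipi_offset: float = 2.0
    pication_dist: float = 6.0
    pication_angle: float = 30.0
    hydrophobic_dist: float = 4.0
    halogen_dist: float = 3.5
    halogen_angle: float = 140.0
    water_hbond_dist: float = 3.5
    aromatic_hbond_dist: float = 4.0
    metal_dist: float = 2.8

    def override(self, **kwargs) -> "InteractionParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InteractionRecord:
    pose_id: str
    frame_id: str
    residue: ResidueId
    ligand_atom: int  # heavy-atom index (0-based)
    moiety: str
    itype: str
    distance: float
    detail: str = ""

    def triple(self) -> tuple:
        """(residue identity, moiety, itype) — the profiling unit."""
        return ((self.residue.chain, self.residue.resnum, self.residue.icode,
                 self.residue.resname), self.moiety, self.itype)


# ---------------------------------------------------------------------------
# Chemistry perception
# ---------------------------------------------------------------------------

_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5}
_HALOGENS = {"Cl", "Br", "I"}


@dataclass
class LigandChemistry:
    """Typed heavy-atom features of a ligand pose (indices are heavy-atom indices)."""

    donors: list[int] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    # charged groups as heavy-atom index tuples; centroids are computed per
    # pose at detection time (a chemistry object is reused across poses)
    cations: list[tuple[int, ...]] = field(default_factory=list)
    anions: list[tuple[int, ...]] = field(default_factory=list)
    rings: list[tuple[int, ...]] = field(default_factory=list)
    hydrophobic: list[int] = field(default_factory=list)
    halogens: list[tuple[int, int]] = field(default_factory=list)  # (X, attached C)

    @property
    def polar(self) -> list[int]:
        return sorted(set(self.donors) | set(self.acceptors))


def perceive_ligand(pose: LigandPose) -> LigandChemistry:
    """Classify ligand heavy atoms from elements, bonds, charges and
    aromatic flags.

    Donor/acceptor assignment is valence-based (implicit hydrogens are
    inferred from default valences and formal charge); charged centres are
    group centroids — a charge carried by a terminal O/S is pooled with its
    equivalent terminal siblings on the same central atom, so e.g. a
    sulfate counts as one anionic centre at the centroid of its terminal
    oxygens.
    """
    heavy = pose.heavy_indices()
    full_to_heavy = {a: i for i, a in enumerate(heavy)}
    coords = pose.coords

    nbrs: dict[int, list[tuple[int, float]]] = {i: [] for i in range(pose.n_atoms)}
    for i, j, order in pose.bonds:
        nbrs[i].append((j, order))
        nbrs[j].append((i, order))

    def heavy_neighbors(a: int) -> list[int]:
        return [b for b, _ in nbrs[a] if pose.elements[b] != "H"]

    def implicit_h(a: int) -> int:
        el = pose.elements[a]
        used = sum(o for _, o in nbrs[a])
        explicit_h = sum(1 for b, _ in nbrs[a] if pose.elements[b] == "H")
        allowed = _DEFAULT_VALENCE.get(el, 4) + pose.formal_charges[a]
        return max(int(round(allowed - used)), 0) + explicit_h

    chem = LigandChemistry()
    for a in heavy:
        el = pose.elements[a]
        hn = heavy_neighbors(a)
        if el in _HALOGENS:
            carbons = [b for b in hn if pose.elements[b] == "C"]
            if carbons:
                chem.halogens.append((full_to_heavy[a], full_to_heavy[carbons[0]]))
            continue
        if el == "C":
            if all(pose.elements[b] in ("C", "S", "H") for b in hn):
                chem.hydrophobic.append(full_to_heavy[a])
            continue
        if el == "O":
            if pose.formal_charges[a] <= 0:
                chem.acceptors.append(full_to_heavy[a])
            if implicit_h(a) >= 1:
                chem.donors.append(full_to_heavy[a])
        elif el == "N":
            q = pose.formal_charges[a]
            has_h = implicit_h(a) >= 1
            if has_h or q > 0:
                chem.donors.append(full_to_heavy[a])
            if q <= 0 and not (pose.aromatic_flags[a] and has_h):
                # pyrrole-type aromatic NH has no available lone pair
                chem.acceptors.append(full_to_heavy[a])

    # charged group centroids over equivalent terminal siblings
    seen_groups: set[tuple[int, ...]] = set()
    for a in heavy:
        q = pose.formal_charges[a]
        if q == 0:
            continue
        el = pose.elements[a]
        hn = heavy_neighbors(a)
        if len(hn) == 1 and el in ("O", "S"):
            center = hn[0]
            group = tuple(sorted(
                b for b in heavy_neighbors(center)
                if pose.elements[b] == el and len(heavy_neighbors(b)) == 1
            ))
        else:
            group = (a,)
        if group in seen_groups:
            continue
        seen_groups.add(group)
        hgroup = tuple(full_to_heavy[g] for g in group)
        if q > 0:
            chem.cations.append(hgroup)
        else:
            chem.anions.append(hgroup)

    # aromatic rings: cycles of the aromatic-bond subgraph
    g = nx.Graph()
    for i, j, order in pose.bonds:
        if pose.elements[i] == "H" or pose.elements[j] == "H":
            continue
        if pose.aromatic_flags[i] and pose.aromatic_flags[j] and order == 1.5:
            g.add_edge(i, j)
    for cycle in nx.cycle_basis(g):
        if 5 <= len(cycle) <= 6:
            chem.rings.append(tuple(sorted(full_to_heavy[a] for a in cycle)))
    chem.rings.sort()
    return chem


@dataclass
class FrameChemistry:
    """Typed residue features of a receptor frame; atom ids index frame.atoms."""

    donors: list[tuple[int, int]] = field(default_factory=list)  # (residue_ref, atom)
    acceptors: list[tuple[int, int]] = field(default_factory=list)
    cations: list[tuple[int, np.ndarray]] = field(default_factory=list)
    anions: list[tuple[int, np.ndarray]] = field(default_factory=list)
    rings: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    hydrophobic: list[tuple[int, int]] = field(default_factory=list)
    metals: list[tuple[int, int]] = field(default_factory=list)
    skipped_residues: list[str] = field(default_factory=list)

    @property
    def polar(self) -> list[tuple[int, int]]:
        return sorted(set(self.donors) | set(self.acceptors))


def perceive_frame(frame: ReceptorFrame) -> FrameChemistry:
    """Classify receptor atoms from residue-template tables.

    Residues outside the 20 standard amino acids are skipped with a
    warning (collected in ``skipped_residues``), except single metal ions
    which are registered as metal centres.
    """
    chem = FrameChemistry()
    by_res = frame.residue_atoms()
    for ridx, rid in enumerate(frame.residues):
        atom_ids = by_res[ridx]
        atoms = {frame.atoms[i].name: i for i in atom_ids}
        metal_atoms = [i for i in atom_ids if frame.atoms[i].element in METAL_ELEMENTS]
        if metal_atoms and rid.resname not in RESIDUE_CHEMISTRY:
            for i in metal_atoms:
                chem.metals.append((ridx, i))
            continue
        tmpl = RESIDUE_CHEMISTRY.get(rid.resname)
        if tmpl is None:
            chem.skipped_residues.append(rid.label())
            continue
        for name in tmpl.donors:
            if name in atoms:
                chem.donors.append((ridx, atoms[name]))
        for name in tmpl.acceptors:
            if name in atoms:
                chem.acceptors.append((ridx, atoms[name]))
        for group in tmpl.cation_groups:
            ids = [atoms[n] for n in group if n in atoms]
            if ids:
                centroid = np.mean([frame.atoms[i].coords for i in ids], axis=0)
                chem.cations.append((ridx, centroid))
        for group in tmpl.anion_groups:
            ids = [atoms[n] for n in group if n in atoms]
            if ids:
                centroid = np.mean([frame.atoms[i].coords for i in ids], axis=0)
                chem.anions.append((ridx, centroid))
        for ring in tmpl.rings:
            ids = tuple(atoms[n] for n in ring if n in atoms)
            if len(ids) >= 5:
                chem.rings.append((ridx, ids))
        for name in tmpl.hydrophobic:
            if name in atoms:
                chem.hydrophobic.append((ridx, atoms[name]))
    if chem.skipped_residues:
        warnings.warn(
            f"frame {frame.frame_id}: skipped residues without chemistry templates: "
            f"{chem.skipped_residues}",
            stacklevel=2,
        )
    return chem


def perceive_chemistry(pose: LigandPose, frame: ReceptorFrame) -> tuple[LigandChemistry, FrameChemistry]:
    return perceive_ligand(pose), perceive_frame(frame)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit normal) of a ring from its atom coordinates."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _axis_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between a direction and an (unsigned) axis, in [0, 90]."""
    a = _angle_deg(v1, v2)
    return min(a, 180.0 - a)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _ring_moiety(ring: tuple[int, ...], scheme: MoietyScheme) -> str:
    """Majority moiety of the ring atoms; ties broken by lowest atom index."""
    counts: dict[str, int] = {}
    for a in ring:
        m = scheme.assignment[a]
        counts[m] = counts.get(m, 0) + 1
    best = max(counts.values())
    tied = [m for m, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    for a in sorted(ring):
        if scheme.assignment[a] in tied:
            return scheme.assignment[a]
    return tied[0]  # pragma: no cover


def detect_interactions(pose: LigandPose, frame: ReceptorFrame, scheme: MoietyScheme,
                        params: InteractionParams | None = None,
                        ligand_chem: LigandChemistry | None = None,
                        frame_chem: FrameChemistry | None = None) -> list[InteractionRecord]:
    """All typed contacts between one pose and its receptor frame.

    Returns one record per ``(residue, moiety, itype)`` triple (the
    closest geometric instance is kept). ``ligand_chem``/``frame_chem``
    can be passed to reuse perception across the poses of an ensemble.
    """
    if pose.frame_id != frame.frame_id:
        raise ValueError(
            f"pose {pose.pose_id} was docked into frame {pose.frame_id!r}, "
            f"not {frame.frame_id!r}"
        )
    params = params or InteractionParams()
    lig = ligand_chem if ligand_chem is not None else perceive_ligand(pose)
    prot = frame_chem if frame_chem is not None else perceive_frame(frame)
    scheme.validate(pose)

    L = pose.heavy_coords()
    moiety = scheme.assignment
    raw: list[InteractionRecord] = []

    def emit(ridx: int, atom: int, itype: str, dist: float, detail: str = "",
             moiety_label: str | None = None) -> None:
        raw.append(InteractionRecord(
            pose_id=pose.pose_id,
            frame_id=frame.frame_id,
            residue=frame.residues[ridx],
            ligand_atom=atom,
            moiety=moiety_label if moiety_label is not None else moiety[atom],
            itype=itype,
            distance=float(dist),
            detail=detail,
        ))

    def pcoord(atom_id: int) -> np.ndarray:
        return frame.atoms[atom_id].coords

    # --- hydrogen bonds (donor-acceptor heavy-atom pairs, distance-only) ---
    for la in lig.donors:
        for ridx, pa in prot.acceptors:
            d = np.linalg.norm(L[la] - pcoord(pa))
            if d <= params.hbond_dist:
                emit(ridx, la, "hbond", d, f"lig donor -> {frame.atoms[pa].name}")
    for la in lig.acceptors:
        for ridx, pa in prot.donors:
            d = np.linalg.norm(L[la] - pcoord(pa))
            if d <= params.hbond_dist:
                emit(ridx, la, "hbond", d, f"{frame.atoms[pa].name} -> lig acceptor")

    # --- ionic (salt bridges): opposite charged-group centroids ---
    for lgroup in lig.anions:
        lcen = L[list(lgroup)].mean(axis=0)
        for ridx, pcen in prot.cations:
            d = np.linalg.norm(lcen - pcen)
            if d <= params.ionic_dist:
                emit(ridx, min(lgroup), "ionic", d, "lig anion / res cation",
                     moiety_label=moiety[min(lgroup)])
    for lgroup in lig.cations:
        lcen = L[list(lgroup)].mean(axis=0)
        for ridx, pcen in prot.anions:
            d = np.linalg.norm(lcen - pcen)
            if d <= params.ionic_dist:
                emit(ridx, min(lgroup), "ionic", d, "lig cation / res anion",
                     moiety_label=moiety[min(lgroup)])

    # --- Pi-Pi stacking ---
    for lring in lig.rings:
        lcen, lnorm = _ring_plane(L[list(lring)])
        lmoiety = _ring_moiety(lring, scheme)
        for ridx, pring in prot.rings:
            pc = np.array([pcoord(i) for i in pring])
            pcen, pnorm = _ring_plane(pc)
            d = np.linalg.norm(lcen - pcen)
            if d > params.pipi_dist:
                continue
            angle = _axis_angle_deg(lnorm, pnorm)
            sep = pcen - lcen
            offset = np.linalg.norm(sep - np.dot(sep, lnorm) * lnorm)
            if angle <= params.pipi_parallel_angle and offset <= params.pipi_offset:
                emit(ridx, min(lring), "pi_pi", d,
                     f"parallel angle={angle:.0f} offset={offset:.1f}", lmoiety)
            elif angle >= params.pipi_tshape_angle_lo:
                emit(ridx, min(lring), "pi_pi", d, f"t-shaped angle={angle:.0f}", lmoiety)

    # --- Pi-cation (both directions) ---
    for lring in lig.rings:
        lcen, lnorm = _ring_plane(L[list(lring)])
        lmoiety = _ring_moiety(lring, scheme)
        for ridx, pcen in prot.cations:
            d = np.linalg.norm(pcen - lcen)
            if d <= params.pication_dist:
                angle = _axis_angle_deg(pcen - lcen, lnorm)
                if angle <= params.pication_angle:
                    emit(ridx, min(lring), "pi_cation", d, f"angle={angle:.0f}", lmoiety)
    for lgroup in lig.cations:
        lcen = L[list(lgroup)].mean(axis=0)
        for ridx, pring in prot.rings:
            pc = np.array([pcoord(i) for i in pring])
            pcen, pnorm = _ring_plane(pc)
            d = np.linalg.norm(lcen - pcen)
            if d <= params.pication_dist:
                angle = _axis_angle_deg(lcen - pcen, pnorm)
                if angle <= params.pication_angle:
                    emit(ridx, min(lgroup), "pi_cation", d, f"angle={angle:.0f}",
                         moiety[min(lgroup)])

    # --- hydrophobic (closest carbon pair per residue) ---
    if lig.hydrophobic and prot.hydrophobic:
        best: dict[int, tuple[float, int]] = {}
        for la in lig.hydrophobic:
            for ridx, pa in prot.hydrophobic:
                d = np.linalg.norm(L[la] - pcoord(pa))
                if d <= params.hydrophobic_dist:
                    if ridx not in best or d < best[ridx][0]:
                        best[ridx] = (d, la)
        for ridx, (d, la) in best.items():
            emit(ridx, la, "hydrophobic", d)

    # --- halogen bonds: C-X...A with angle at X ---
    for xa, ca in lig.halogens:
        for ridx, pa in prot.acceptors:
            d = np.linalg.norm(L[xa] - pcoord(pa))
            if d <= params.halogen_dist:
                # angle C-X...A at the halogen; sigma-hole points opposite C
                cx_angle = _angle_deg(L[ca] - L[xa], pcoord(pa) - L[xa])
                if cx_angle >= params.halogen_angle:
                    emit(ridx, xa, "halogen_bond", d, f"C-X..A={cx_angle:.0f}")

    # --- water-mediated hydrogen bonds ---
    if len(frame.waters):
        lig_polar = lig.polar
        for wi, w in enumerate(frame.waters):
            lhits = [(la, np.linalg.norm(L[la] - w)) for la in lig_polar]
            lhits = [(la, d) for la, d in lhits if d <= params.water_hbond_dist]
            if not lhits:
                continue
            for ridx, pa in prot.polar:
                dp = np.linalg.norm(pcoord(pa) - w)
                if dp <= params.water_hbond_dist:
                    la, dl = min(lhits, key=lambda t: t[1])
                    emit(ridx, la, "water_hbond", dl,
                         f"via water {wi} (res-water {dp:.2f} A)")

    # --- aromatic hydrogen bonds (weak CH...O / pi contacts) ---
    for la in lig.polar:
        for ridx, pring in prot.rings:
            for pa in pring:
                d = np.linalg.norm(L[la] - pcoord(pa))
                if d <= params.aromatic_hbond_dist:
                    emit(ridx, la, "aromatic_hbond", d,
                         f"lig polar vs ring C {frame.atoms[pa].name}")
    lig_ring_atoms = sorted({a for ring in lig.rings for a in ring})
    for la in lig_ring_atoms:
        for ridx, pa in prot.polar:
            d = np.linalg.norm(L[la] - pcoord(pa))
            if d <= params.aromatic_hbond_dist:
                emit(ridx, la, "aromatic_hbond", d,
                     f"res polar {frame.atoms[pa].name} vs lig ring atom")

    # --- metal contacts ---
    lig_nos = [i for i, a in enumerate(pose.heavy_indices())
               if pose.elements[a] in ("N", "O", "S")]
    for ridx, ma in prot.metals:
        for la in lig_nos:
            d = np.linalg.norm(L[la] - pcoord(ma))
            if d <= params.metal_dist:
                emit(ridx, la, "metal", d, f"ion {frame.atoms[ma].element}")

    # --- deduplicate: keep closest instance per (residue, moiety, itype) ---
    best_rec: dict[tuple, InteractionRecord] = {}
    for rec in raw:
        key = rec.triple()
        if key not in best_rec or rec.distance < best_rec[key].distance:
            best_rec[key] = rec
    deduped = sorted(
        best_rec.values(),
        key=lambda r: (r.residue.chain, r.residue.resnum, r.residue.icode,
                       r.itype, r.moiety),
    )
    return deduped


def interaction_report(records: Sequence[InteractionRecord],
                       by: str = "residue") -> pd.Series:
    """Aggregate record counts by residue, moiety or type (stable order)."""
    if by not in ("residue", "moiety", "type"):
        raise ValueError(f"unknown grouping {by!r}")
    if not records:
        return pd.Series(dtype=int)
    if by == "residue":
        keys = [r.residue.label() for r in records]
        order_key = {r.residue.label(): (r.residue.chain, r.residue.resnum, r.residue.icode)
                     for r in records}
        counts = pd.Series(keys).value_counts()
        return counts.reindex(sorted(counts.index, key=lambda k: order_key[k]))
    if by == "moiety":
        keys = [r.moiety for r in records]
    else:
        keys = [r.itype for r in records]
    counts = pd.Series(keys).value_counts()
    return counts.reindex(sorted(counts.index))


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Flat table of records (CSV-ready)."""
    rows = [
        {
            "pose_id": r.pose_id,
            "frame_id": r.frame_id,
            "chain": r.residue.chain,
            "resnum": r.residue.resnum,
            "icode": r.residue.icode,
            "resname": r.residue.resname,
            "ligand_atom": r.ligand_atom,
            "moiety": r.moiety,
            "itype": r.itype,
            "distance": round(r.distance, 4),
            "detail": r.detail,
        }
        for r in records
    ]
    cols = ["pose_id", "frame_id", "chain", "resnum", "icode", "resname",
            "ligand_atom", "moiety", "itype", "distance", "detail"]
    return pd.DataFrame(rows, columns=cols)
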