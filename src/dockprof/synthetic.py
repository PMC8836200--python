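"""Deterministic synthetic scenarios: toy pockets, pose ensembles and planted contacts.

The generator emulates what an ensemble-docking campaign hands to the
post-processing pipeline — a directory of receptor-frame PDB files, one
SDF of docked poses tagged with frame ids and ranks, and a moiety config —
while knowing the ground truth: which poses belong to which conformational
cluster and which residue contacts were planted.

Pose sets are drawn from ``k`` cluster centres with isotropic Gaussian
noise on every heavy atom. Centres are built from one toy-ligand
conformation by (a) twisting an internal torsion (so centres differ in
*shape*, which the superposition metric sees) and (b) rigidly rotating the
molecule about an anchor atom (so centres differ in *placement*). The
anchor atom stays put across centres, which lets a "hub" residue contact
every cluster — the planted top molecular determinant.

Pocket residues are placed so each planted contact satisfies its geometric
criterion with a safety margin, and each matched decoy (same residue type
and geometry) violates it by at least the decoy margin. Everything is
reproducible from the scenario seed (NumPy PCG64 generator).

No physical realism is attempted: no sterics, no force field — geometry-only
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import ClusterModel
from .geometry import inplace_rmsd, kabsch_superpose
from .interactions import InteractionParams, detect_interactions
from .io_structures import (
    Atom,
    LigandPose,
    MoietyScheme,
    ReceptorFrame,
    ResidueId,
    save_moiety_scheme,
    write_poses,
    write_receptor_frame,
)
from .profiling import InteractionProfile
from .templates import RESIDUE_COORDS

__all__ = [
    "PlantedContact",
    "ScenarioSpec",
    "ScenarioData",
    "generate_scenario",
    "standard_scenario_spec",
    "two_cluster_spec",
    "score_recovery",
    "TOY_LIGANDS",
]


# ---------------------------------------------------------------------------
# Toy ligands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyLigand:
    """A hand-built ligand conformation with named probe points.

    ``anchor`` is the atom held fixed across cluster centres;
    ``flex`` lists (pivot atom, moved atom indices) groups: per-cluster
    conformers swing each group about its pivot around differing axes,
    which differentiates centre *shapes* (what the superposition metric
    sees) while bond lengths to the pivot are preserved. Two
    counter-swinging groups defeat the rigid-body compensation an optimal
    superposition would otherwise apply.
    """

    name: str
    elements: tuple[str, ...]
    coords: np.ndarray
    charges: tuple[int, ...]
    aromatic: tuple[bool, ...]
    bonds: tuple[tuple[int, int, float], ...]
    moieties: dict[str, tuple[int, ...]]
    anchor: int
    flex: tuple[tuple[int, tuple[int, ...]], ...]
    probes: dict[str, dict]

    def n_atoms(self) -> int:
        return len(self.elements)

    def moiety_scheme(self) -> MoietyScheme:
        assignment = {i: lab for lab, idx in self.moieties.items() for i in idx}
        return MoietyScheme(ligand_name=self.name, labels=list(self.moieties),
                            assignment=assignment)


def _toy_glucosinolate() -> ToyLigand:
    # 20 heavy atoms: a polyol "sugar" arm, an -O-SO3(-) sulfate, and a
    # chlorinated aromatic side chain, echoing the glucosinolate moiety split.
    atoms = [
        # (element, charge, aromatic, xyz)
        ("C", 0, False, (0.0, 0.0, 0.0)),      # 0  sugar C1
        ("O", 0, False, (-0.7, 1.2, 0.2)),     # 1  OH  (anchor / hub target)
        ("C", 0, False, (1.5, 0.1, 0.1)),      # 2
        ("O", 0, False, (2.1, 1.3, -0.3)),     # 3  OH  (hbond target)
        ("C", 0, False, (2.2, -1.2, 0.5)),     # 4
        ("O", 0, False, (1.7, -2.4, -0.1)),    # 5  OH  (water-bridge target)
        ("C", 0, False, (3.7, -1.1, 0.4)),     # 6  core carbon
        ("O", 0, False, (4.3, 0.1, 0.8)),      # 7  bridging O
        ("S", 0, False, (5.8, 0.3, 1.0)),      # 8
        ("O", -1, False, (6.4, 0.6, 2.3)),     # 9  charged sulfate O
        ("O", 0, False, (6.5, -0.8, 0.4)),     # 10 (metal target)
        ("O", 0, False, (6.1, 1.5, 0.2)),      # 11
        ("C", 0, False, (4.5, -2.3, 0.0)),     # 12 side-chain linker
        ("Cl", 0, False, (4.3, -8.22, -0.3)),  # 13 ring chlorine
        ("C", 0, True, (4.3, -3.70, -0.3)),    # 14 ring (attached to 12)
        ("C", 0, True, (5.504, -4.395, -0.3)),  # 15
        ("C", 0, True, (5.504, -5.785, -0.3)),  # 16
        ("C", 0, True, (4.3, -6.48, -0.3)),     # 17 (carries Cl)
        ("C", 0, True, (3.096, -5.785, -0.3)),  # 18
        ("C", 0, True, (3.096, -4.395, -0.3)),  # 19
    ]
    bonds = [
        (0, 1, 1.0), (0, 2, 1.0), (2, 3, 1.0), (2, 4, 1.0), (4, 5, 1.0),
        (4, 6, 1.0), (6, 7, 1.0), (7, 8, 1.0), (8, 9, 1.0), (8, 10, 2.0),
        (8, 11, 2.0), (6, 12, 1.0), (12, 14, 1.0), (13, 17, 1.0),
        (14, 15, 1.5), (15, 16, 1.5), (16, 17, 1.5), (17, 18, 1.5),
        (18, 19, 1.5), (19, 14, 1.5),
    ]
    probes = {
        "hub_O": {"kind": "atom", "atom": 1},
        "hbond_O": {"kind": "atom", "atom": 3},
        "water_O": {"kind": "atom", "atom": 5},
        "metal_O": {"kind": "atom", "atom": 10},
        "arom_hb_O": {"kind": "atom", "atom": 3, "away_from": 1},
        "anion": {"kind": "group_centroid", "atoms": (9, 10, 11)},
        "ring": {"kind": "ring", "atoms": (14, 15, 16, 17, 18, 19)},
        "ring_edge": {"kind": "ring_edge", "atoms": (14, 15, 16, 17, 18, 19),
                      "edge_atom": 19},
        "halogen": {"kind": "halogen", "x": 13, "c": 17},
    }
    return ToyLigand(
        name="toy_glucosinolate",
        elements=tuple(a[0] for a in atoms),
        coords=np.array([a[3] for a in atoms], dtype=float),
        charges=tuple(a[1] for a in atoms),
        aromatic=tuple(a[2] for a in atoms),
        bonds=tuple(bonds),
        moieties={
            "sugar": tuple(range(0, 7)),
            "sulfate": tuple(range(7, 12)),
            "sidechain": (12, 13, 14, 15, 16, 17, 18, 19),
        },
        anchor=1,
        flex=((6, (7, 8, 9, 10, 11)), (6, (12, 13, 14, 15, 16, 17, 18, 19))),
        probes=probes,
    )


def _toy_dipeptide() -> ToyLigand:
    # 11 heavy atoms: a phosphonate head and a small peptide-like core,
    # echoing the two-moiety (phosphate/core) split of alafosfalin.
    atoms = [
        ("P", 0, False, (0.0, 0.0, 0.0)),       # 0
        ("O", -1, False, (0.3, 1.4, 0.5)),      # 1
        ("O", 0, False, (-1.4, -0.3, 0.3)),     # 2
        ("O", 0, False, (0.4, -1.1, 1.0)),      # 3
        ("C", 0, False, (0.9, -0.3, -1.5)),     # 4
        ("C", 0, False, (2.4, -0.2, -1.4)),     # 5
        ("N", 0, False, (3.0, 1.0, -1.8)),      # 6
        ("C", 0, False, (4.4, 1.1, -1.7)),      # 7
        ("O", 0, False, (5.1, 0.1, -1.4)),      # 8
        ("C", 0, False, (5.0, 2.4, -2.0)),      # 9
        ("C", 0, False, (6.5, 2.4, -1.9)),      # 10
    ]
    bonds = [
        (0, 1, 1.0), (0, 2, 2.0), (0, 3, 2.0), (0, 4, 1.0), (4, 5, 1.0),
        (5, 6, 1.0), (6, 7, 1.0), (7, 8, 2.0), (7, 9, 1.0), (9, 10, 1.0),
    ]
    probes = {
        "hub_O": {"kind": "atom", "atom": 3},
        "hbond_O": {"kind": "atom", "atom": 8},
        "water_O": {"kind": "atom", "atom": 2},
        "metal_O": {"kind": "atom", "atom": 2},
        "anion": {"kind": "group_centroid", "atoms": (1, 2, 3)},
        "hydrophobic_C": {"kind": "atom", "atom": 10},
    }
    return ToyLigand(
        name="toy_dipeptide",
        elements=tuple(a[0] for a in atoms),
        coords=np.array([a[3] for a in atoms], dtype=float),
        charges=tuple(a[1] for a in atoms),
        aromatic=tuple(a[2] for a in atoms),
        bonds=tuple(bonds),
        moieties={"phosphate": (0, 1, 2, 3), "core": (4, 5, 6, 7, 8, 9, 10)},
        anchor=3,
        flex=((5, (6, 7, 8, 9, 10)),),
        probes=probes,
    )


TOY_LIGANDS = {
    "toy_glucosinolate": _toy_glucosinolate,
    "toy_dipeptide": _toy_dipeptide,
}


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    """One contact to engineer into the pocket.

    ``targets`` lists 0-based true-cluster indices, or ``"all"`` for a hub
    contact engineered against the anchor (present in every cluster).
    ``probe`` names a probe point of the ligand template.
    """

    residue: str
    itype: str
    moiety: str
    probe: str
    targets: tuple[int, ...] | str = (0,)
    hub: bool = False


def standard_planted_contacts() -> tuple[PlantedContact, ...]:
    """One planted contact per supported type, plus the hub residue."""
    return (
        PlantedContact("SER", "hbond", "sugar", "hbond_O", (0,)),
        PlantedContact("LYS", "ionic", "sulfate", "anion", (1,)),
        PlantedContact("PHE", "pi_pi", "sidechain", "ring", (0,)),
        PlantedContact("LYS", "pi_cation", "sidechain", "ring", (1,)),
        PlantedContact("LEU", "hydrophobic", "sidechain", "ring_edge", (0,)),
        PlantedContact("ASN", "halogen_bond", "sidechain", "halogen", (1,)),
        PlantedContact("THR", "water_hbond", "sugar", "water_O", (0,)),
        PlantedContact("PHE", "aromatic_hbond", "sugar", "arom_hb_O", (1,)),
        PlantedContact("ZN", "metal", "sulfate", "metal_O", (0,)),
        PlantedContact("ARG", "hbond", "sugar", "hub_O", "all", hub=True),
    )


@dataclass
class ScenarioSpec:
    seed: int
    n_frames: int
    k_clusters: int
    populations: tuple[int, ...]
    cluster_sep: float  # Å, minimal in-place RMSD between centres
    noise_sd: float  # Å, isotropic per heavy atom
    planted_contacts: tuple[PlantedContact, ...] = field(
        default_factory=standard_planted_contacts)
    ligand_template: str = "toy_glucosinolate"
    plant_margin: float = 1.0  # Å inside the cutoff for planted contacts
    decoy_margin: float = 0.5  # Å outside the cutoff for decoys

    def validate(self) -> None:
        if len(self.populations) != self.k_clusters:
            raise ValueError("populations length must equal k_clusters")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cluster_sep <= 0:
            raise ValueError("cluster_sep must be > 0")
        if sum(self.populations) > 10 * self.n_frames:
            raise ValueError(
                "total population exceeds 10 poses per frame; increase n_frames"
            )
        for pc in self.planted_contacts:
            if pc.targets != "all" and any(t >= self.k_clusters for t in pc.targets):
                raise ValueError(f"planted contact targets unknown cluster: {pc}")


def standard_scenario_spec(seed: int = 7) -> ScenarioSpec:
    """The benchmark scenario: 3 clusters (200/150/20 poses), 0.3 Å noise,
    8 Å centre separation, one planted contact per type plus a hub."""
    return ScenarioSpec(
        seed=seed, n_frames=40, k_clusters=3, populations=(200, 150, 20),
        cluster_sep=8.0, noise_sd=0.3,
    )


def two_cluster_spec(seed: int = 11) -> ScenarioSpec:
    """Small well-separated two-cluster scenario (30/5 poses)."""
    return ScenarioSpec(
        seed=seed, n_frames=4, k_clusters=2, populations=(30, 5),
        cluster_sep=6.0, noise_sd=0.2,
        planted_contacts=(
            PlantedContact("SER", "hbond", "sugar", "hbond_O", (0,)),
            PlantedContact("ARG", "hbond", "sugar", "hub_O", "all", hub=True),
        ),
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotate_about_line(coords: np.ndarray, point: np.ndarray, axis: np.ndarray,
                       angle: float) -> np.ndarray:
    R = _rotation_about_axis(axis, angle)
    return (coords - point) @ R.T + point


def _rotation_mapping(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_about_axis(perp, np.pi)
    K = np.array([
        [0, -v[2], v[1]],
        [v[2], 0, -v[0]],
        [-v[1], v[0], 0],
    ])
    return np.eye(3) + K + K @ K / (1.0 + c)


# Per-conformer recipe: a swing (axis, angle in radians) for each of the
# (up to two) flexible groups, plus a placement rotation about the anchor.
# The sequence was chosen so that successive conformers are far apart both
# in placement (in-place RMSD, what cluster_sep constrains) and in shape
# (superposed RMSD, so the two metrics both see distinct clusters).
_CONF_RECIPES = [
    (((0, 0, 1), 0.0), ((0, 0, 1), 0.0), ((0, 0, 1), 0.0)),
    (((0, 0, 1), -0.9), ((0, 0, 1), 0.9), ((0, 0, 1), np.pi)),
    (((1, 0, 0), 0.9), ((1, 0, 0), -1.4), ((0, 0, 1), np.pi / 2)),
    (((0, 0, 1), 1.4), ((0, 0, 1), 1.4), ((0.707, 0.707, 0), np.pi / 2)),
    (((0, 0, 1), -1.4), ((0, 0, 1), -1.4), ((0, 1, 0), np.pi)),
    (((1, 0, 0), -0.9), ((1, 0, 0), 1.4), ((0, 1, 0), np.pi / 2)),
]


def _build_centers(lig: ToyLigand, spec: ScenarioSpec) -> list[np.ndarray]:
    """k centre conformations: internal group swings + rigid placement spin."""
    k = spec.k_clusters
    if k > len(_CONF_RECIPES):
        raise ValueError(f"at most {len(_CONF_RECIPES)} clusters supported")
    base = lig.coords.copy()
    anchor = base[lig.anchor]
    centers = []
    for j in range(k):
        c = base.copy()
        *swings, (place_axis, place_angle) = _CONF_RECIPES[j]
        for g, (pivot_atom, moved) in enumerate(lig.flex):
            axis, swing = swings[min(g, 1)]
            if swing != 0.0:
                c[list(moved)] = _rotate_about_line(
                    c[list(moved)], c[pivot_atom], np.asarray(axis, float), swing)
        if place_angle != 0.0:
            c = _rotate_about_line(c, anchor, np.asarray(place_axis, float), place_angle)
        centers.append(c)
    # separation checks: placement (in-place) and shape (superposed)
    for i in range(k):
        for j in range(i + 1, k):
            sep = inplace_rmsd(centers[i], centers[j])
            if sep < spec.cluster_sep:
                raise ValueError(
                    f"infeasible geometry: centres {i},{j} separated by "
                    f"{sep:.2f} Å < cluster_sep {spec.cluster_sep:.2f} Å"
                )
            _, shape_sep = kabsch_superpose(centers[i], centers[j])
            min_shape = 4.0 * spec.noise_sd
            if shape_sep < min_shape:
                raise ValueError(
                    f"infeasible geometry: centres {i},{j} have shape "
                    f"separation {shape_sep:.2f} Å < {min_shape:.2f} Å; the "
                    f"superposed metric could not distinguish the clusters"
                )
    return centers


# ---------------------------------------------------------------------------
# Pocket construction
# ---------------------------------------------------------------------------

_CUTOFFS = InteractionParams()

#: criterion distance per contact type (the quantity the margins apply to)
_TYPE_CUTOFF = {
    "hbond": _CUTOFFS.hbond_dist,
    "ionic": _CUTOFFS.ionic_dist,
    "pi_pi": 3.6,  # stacking distance planted; cutoff check handled separately
    "pi_cation": _CUTOFFS.pication_dist,
    "hydrophobic": _CUTOFFS.hydrophobic_dist,
    "halogen_bond": _CUTOFFS.halogen_dist,
    "water_hbond": _CUTOFFS.water_hbond_dist,
    "aromatic_hbond": _CUTOFFS.aromatic_hbond_dist,
    "metal": _CUTOFFS.metal_dist,
}


@dataclass
class _Placement:
    resname: str
    resnum: int
    atoms: list[tuple[str, str, np.ndarray]]  # (name, element, coords)
    is_water: bool = False


def _place_residue(resname: str, resnum: int, position: np.ndarray,
                   direction: np.ndarray, orient: str = "x") -> _Placement:
    """Instantiate an idealized residue with its probe atom at ``position``
    and its body extending along ``direction`` (away from the ligand).

    ``orient="x"`` maps the template +x axis onto ``direction``;
    ``orient="y"`` maps +y (used to point a ring edge at the ligand).
    """
    template = RESIDUE_COORDS[resname]
    axis = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0])}[orient]
    R = _rotation_mapping(axis, direction)
    atoms = [(name, el, R @ np.asarray(xyz) + position) for name, el, xyz in template]
    return _Placement(resname=resname, resnum=resnum, atoms=atoms,
                      is_water=resname == "HOH")


def _probe_geometry(lig: ToyLigand, center: np.ndarray, probe_name: str) -> dict:
    """World-space geometry of a named probe for one centre conformation."""
    probe = lig.probes[probe_name]
    centroid = center.mean(axis=0)
    kind = probe["kind"]
    if kind == "atom":
        p = center[probe["atom"]]
        ref = center[probe["away_from"]] if "away_from" in probe else centroid
        return {"point": p, "out": _unit(p - ref)}
    if kind == "group_centroid":
        p = center[list(probe["atoms"])].mean(axis=0)
        return {"point": p, "out": _unit(p - centroid)}
    if kind in ("ring", "ring_edge"):
        ring = center[list(probe["atoms"])]
        rc = ring.mean(axis=0)
        _, _, vt = np.linalg.svd(ring - rc)
        normal = vt[2]
        if np.dot(normal, rc - centroid) < 0:
            normal = -normal
        out = {"point": rc, "normal": _unit(normal), "out": _unit(rc - centroid)}
        if kind == "ring_edge":
            edge = center[probe["edge_atom"]]
            out["point"] = edge
            out["out"] = _unit(edge - rc)
        return out
    if kind == "halogen":
        x = center[probe["x"]]
        c = center[probe["c"]]
        return {"point": x, "out": _unit(x - c)}
    raise ValueError(f"unknown probe kind {kind!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _plant_one(lig: ToyLigand, center: np.ndarray, pc: PlantedContact,
               resnum: int, distance_shift: float) -> list[_Placement]:
    """Residue placement(s) realising (or, shifted outward, spoiling) a contact.

    ``distance_shift`` = -plant_margin for real contacts, +decoy_margin for
    decoys; it moves the probe atom along the placement direction relative
    to the type's criterion distance.
    """
    geo = _probe_geometry(lig, center, pc.probe)
    itype = pc.itype
    placements: list[_Placement] = []
    if itype in ("hbond", "ionic", "metal", "hydrophobic"):
        d = _TYPE_CUTOFF[itype] + distance_shift
        pos = geo["point"] + d * geo["out"]
        placements.append(_place_residue(pc.residue, resnum, pos, geo["out"]))
    elif itype == "pi_pi":
        # parallel stack along the ring normal; decoys pushed past the
        # centroid-distance cutoff
        d = 3.6 if distance_shift < 0 else _CUTOFFS.pipi_dist + distance_shift
        pos = geo["point"] + d * geo["normal"]
        placements.append(_place_residue("PHE", resnum, pos, geo["normal"], orient="x"))
    elif itype == "pi_cation":
        d = _CUTOFFS.pication_dist - 1.5 if distance_shift < 0 \
            else _CUTOFFS.pication_dist + distance_shift
        pos = geo["point"] - d * geo["normal"]
        placements.append(_place_residue(pc.residue, resnum, pos, -geo["normal"]))
    elif itype == "halogen_bond":
        d = _TYPE_CUTOFF[itype] + distance_shift
        pos = geo["point"] + d * geo["out"]
        placements.append(_place_residue(pc.residue, resnum, pos, geo["out"]))
    elif itype == "water_hbond":
        d = _TYPE_CUTOFF[itype] + distance_shift
        wpos = geo["point"] + d * geo["out"]
        placements.append(_place_residue("HOH", resnum + 500, wpos, geo["out"]))
        respos = wpos + (_TYPE_CUTOFF[itype] - 0.7) * geo["out"]
        placements.append(_place_residue(pc.residue, resnum, respos, geo["out"]))
    elif itype == "aromatic_hbond":
        # nearest ring atom of a PHE at the criterion distance from the
        # ligand polar atom; ring plane contains the approach direction
        if distance_shift < 0:
            d = _TYPE_CUTOFF[itype] - 0.3 + distance_shift
        else:
            d = _TYPE_CUTOFF[itype] + distance_shift
        pos = geo["point"] + (d + 1.39) * geo["out"]
        placements.append(_place_residue("PHE", resnum, pos, geo["out"], orient="y"))
    else:
        raise ValueError(f"cannot plant contact type {itype!r}")
    return placements


def _pocket_frame(frame_id: str, placements: list[_Placement]) -> ReceptorFrame:
    frame = ReceptorFrame(frame_id=frame_id)
    waters = []
    for pl in placements:
        if pl.is_water:
            waters.append(pl.atoms[0][2])
            continue
        rid = ResidueId(chain="A", resnum=pl.resnum, icode="", resname=pl.resname)
        frame.residues.append(rid)
        ridx = len(frame.residues) - 1
        for name, el, xyz in pl.atoms:
            frame.atoms.append(Atom(name=name, element=el, coords=np.asarray(xyz, float),
                                    residue_ref=ridx))
    frame.waters = np.array(waters) if waters else np.zeros((0, 3))
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioData:
    """In-memory scenario plus the paths of the files written."""

    spec: ScenarioSpec
    frames: list[ReceptorFrame]
    poses: list[LigandPose]
    scheme: MoietyScheme
    truth: dict
    frames_dir: Path | None = None
    poses_file: Path | None = None
    scheme_file: Path | None = None
    truth_file: Path | None = None


def _residue_key(resnum: int, resname: str) -> list:
    return ["A", resnum, "", resname]


def generate_scenario(spec: ScenarioSpec, out_dir: str | Path | None = None) -> ScenarioData:
    """Build a scenario; optionally write PDB/SDF/YAML/JSON files under ``out_dir``.

    Raises on infeasible geometry — insufficient centre separation, or a
    planted/decoy contact that the detector (run on the noiseless centre
    poses, with the safety margins applied to the cutoffs) does not
    confirm.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lig = TOY_LIGANDS[spec.ligand_template]()
    centers = _build_centers(lig, spec)
    scheme = lig.moiety_scheme()

    # --- place planted residues, decoys, hub --------------------------------
    placements: list[_Placement] = []
    truth_planted: list[dict] = []
    truth_decoys: list[dict] = []
    hub_residue: list | None = None
    resnum_plant, resnum_decoy = 101, 301
    for pc in spec.planted_contacts:
        if pc.hub or pc.targets == "all":
            pls = _plant_one(lig, centers[0], pc, 201, -spec.plant_margin)
            placements.extend(pls)
            hub_residue = _residue_key(201, pc.residue)
            truth_planted.append({
                "residue": _residue_key(201, pc.residue),
                "moiety": pc.moiety, "itype": pc.itype,
                "targets": list(range(spec.k_clusters)),
            })
            continue
        for t in pc.targets:
            pls = _plant_one(lig, centers[t], pc, resnum_plant, -spec.plant_margin)
            placements.extend(pls)
            truth_planted.append({
                "residue": _residue_key(resnum_plant, pc.residue),
                "moiety": pc.moiety, "itype": pc.itype, "targets": [t],
            })
            dls = _plant_one(lig, centers[t], pc, resnum_decoy, +spec.decoy_margin)
            placements.extend(dls)
            truth_decoys.append({
                "residue": _residue_key(resnum_decoy, pc.residue),
                "moiety": pc.moiety, "itype": pc.itype, "targets": [t],
            })
            resnum_plant += 1
            resnum_decoy += 1

    pocket = _pocket_frame("frame_000", placements)

    # --- verify ground truth against the detector on the centre poses -------
    margin = 0.25
    tight = _shift_params(-margin)
    loose = _shift_params(+margin)
    for j, center in enumerate(centers):
        cpose = _make_pose(lig, center, pose_id=f"center{j}", frame_id="frame_000",
                           rank=1, score=0.0)
        found_tight = {_rec_key(r) for r in detect_interactions(cpose, pocket, scheme, tight)}
        found_loose = {_rec_key(r) for r in detect_interactions(cpose, pocket, scheme, loose)}
        for tp in truth_planted:
            if j in tp["targets"]:
                key = (tuple(tp["residue"]), tp["moiety"], tp["itype"])
                if key not in found_tight:
                    raise ValueError(
                        f"infeasible geometry: planted contact {key} not detected "
                        f"in cluster {j} even before noise"
                    )
        for td in truth_decoys:
            if j in td["targets"]:
                key = (tuple(td["residue"]), td["moiety"], td["itype"])
                if key in found_loose:
                    raise ValueError(
                        f"infeasible geometry: decoy contact {key} detected in "
                        f"cluster {j}"
                    )

    # --- frames (identical pocket, one PDB per frame) -----------------------
    frames = []
    for i in range(spec.n_frames):
        f = _pocket_frame(f"frame_{i:03d}", placements)
        frames.append(f)

    # --- poses: noisy copies of the centres, shuffled, spread over frames ---
    order = []
    for j, pop in enumerate(spec.populations):
        order.extend([j] * pop)
    order = np.array(order)
    rng.shuffle(order)
    per_frame_count = {f.frame_id: 0 for f in frames}
    poses: list[LigandPose] = []
    truth_clusters: dict[str, int] = {}
    fidx = 0
    for j in order:
        coords = centers[j] + rng.normal(0.0, spec.noise_sd, size=centers[j].shape)
        frame_id = frames[fidx % spec.n_frames].frame_id
        fidx += 1
        rank = per_frame_count[frame_id] + 1
        per_frame_count[frame_id] = rank
        score = -9.0 + 0.3 * j + rng.normal(0.0, 0.1)
        pose = _make_pose(lig, coords, pose_id="", frame_id=frame_id, rank=rank,
                          score=float(score))
        pose.pose_id = f"{lig.name}/{frame_id}/r{rank}"
        poses.append(pose)
        truth_clusters[pose.pose_id] = int(j)

    truth = {
        "ligand": lig.name,
        "k_clusters": spec.k_clusters,
        "populations": list(spec.populations),
        "pose_clusters": truth_clusters,
        "planted": truth_planted,
        "decoys": truth_decoys,
        "hub_residue": hub_residue,
        "seed": spec.seed,
    }

    data = ScenarioData(spec=spec, frames=frames, poses=poses, scheme=scheme, truth=truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        frames_dir = out_dir / "frames"
        frames_dir.mkdir(parents=True, exist_ok=True)
        for f in frames:
            write_receptor_frame(f, frames_dir / f"{f.frame_id}.pdb")
        poses_file = out_dir / "poses.sdf"
        write_poses(poses, poses_file)
        scheme_file = out_dir / "moieties.yaml"
        save_moiety_scheme(scheme, scheme_file)
        truth_file = out_dir / "truth.json"
        with open(truth_file, "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        data.frames_dir = frames_dir
        data.poses_file = poses_file
        data.scheme_file = scheme_file
        data.truth_file = truth_file
    return data


def _shift_params(delta: float) -> InteractionParams:
    """All distance cutoffs shifted by delta (margin verification)."""
    p = InteractionParams()
    return p.override(
        hbond_dist=p.hbond_dist + delta,
        ionic_dist=p.ionic_dist + delta,
        pipi_dist=p.pipi_dist + delta,
        pication_dist=p.pication_dist + delta,
        hydrophobic_dist=p.hydrophobic_dist + delta,
        halogen_dist=p.halogen_dist + delta,
        water_hbond_dist=p.water_hbond_dist + delta,
        aromatic_hbond_dist=p.aromatic_hbond_dist + delta,
        metal_dist=p.metal_dist + delta,
    )


def _rec_key(rec) -> tuple:
    return ((rec.residue.chain, rec.residue.resnum, rec.residue.icode,
             rec.residue.resname), rec.moiety, rec.itype)


def _make_pose(lig: ToyLigand, coords: np.ndarray, pose_id: str, frame_id: str,
               rank: int, score: float) -> LigandPose:
    return LigandPose(
        pose_id=pose_id or f"{lig.name}/{frame_id}/r{rank}",
        ligand_name=lig.name,
        frame_id=frame_id,
        rank=rank,
        score=score,
        elements=list(lig.elements),
        coords=np.asarray(coords, dtype=float),
        formal_charges=list(lig.charges),
        aromatic_flags=list(lig.aromatic),
        bonds=[tuple(b) for b in lig.bonds],
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(truth: dict, model: ClusterModel, profile: InteractionProfile,
                   frequency_floor: float = 0.5) -> dict:
    """Compare pipeline output against scenario ground truth.

    * ``partition_ari`` — adjusted Rand index between true and recovered
      pose partitions;
    * ``contact_recall`` / ``contact_precision`` — over the planted
      contacts and their matched decoys: a contact counts as detected when
      its per-cluster frequency (FIPC) reaches ``frequency_floor`` in the
      recovered cluster corresponding to its target (majority mapping);
    * ``hub_rank`` — 1-based rank of the planted hub residue in the
      summed-FI table (None if no hub was planted).
    """
    from sklearn.metrics import adjusted_rand_score

    from .profiling import residue_totals

    truth_assign = truth["pose_clusters"]
    missing = [p for p in truth_assign if p not in model.assignment]
    if missing:
        raise ValueError(f"cluster model is missing {len(missing)} poses: {missing[:5]}")
    pose_ids = sorted(truth_assign)
    t_labels = [truth_assign[p] for p in pose_ids]
    m_labels = [model.assignment[p] for p in pose_ids]
    ari = float(adjusted_rand_score(t_labels, m_labels))

    # majority mapping: true cluster index -> recovered label
    mapping: dict[int, int] = {}
    for tc in sorted(set(t_labels)):
        members = [model.assignment[p] for p in pose_ids if truth_assign[p] == tc]
        counts: dict[int, int] = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        mapping[tc] = max(counts, key=lambda c: (counts[c], -c))

    fipc_by = {}
    for row in profile.rows:
        fipc_by[(row.cluster, row.residue, row.moiety, row.itype)] = float(row.fipc)

    def detected(entry: dict) -> bool:
        res = tuple(entry["residue"])
        for t in entry["targets"]:
            label = mapping[t]
            f = fipc_by.get((label, res, entry["moiety"], entry["itype"]), 0.0)
            if f < frequency_floor:
                return False
        return True

    planted = truth["planted"]
    decoys = truth["decoys"]
    tp = sum(1 for e in planted if detected(e))
    fp = sum(1 for e in decoys if detected(e))
    recall = tp / len(planted) if planted else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0

    hub_rank = None
    if truth.get("hub_residue"):
        totals = residue_totals(profile)
        hub = tuple(truth["hub_residue"])
        label = f"{hub[0]}:{hub[3]}{hub[1]}{hub[2]}"
        pos = totals.index[totals["residue"] == label].tolist()
        hub_rank = int(pos[0]) + 1 if pos else None

    return {
        "partition_ari": ari,
        "contact_recall": recall,
        "contact_precision": precision,
        "n_planted": len(planted),
        "n_decoys": len(decoys),
        "hub_rank": hub_rank,
        "cluster_mapping": mapping,
    }
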