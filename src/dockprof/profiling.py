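"""Cluster-weighted interaction-frequency profiling.

For every significant cluster ``c`` and contact triple
``t = (residue, moiety, itype)``:

* FIPC(c, t) — frequency of the interaction per cluster: the fraction of
  poses in ``c`` exhibiting ``t``;
* FI(c, t) = FIPC(c, t) * SCP(c) / TPSC — the frequency weighted by the
  cluster's share of the total significant population.

Summing FI per residue ranks candidate molecular-determinant residues:
a residue contacted in every pose of every significant cluster totals
exactly 1 per contact type. Only significant clusters contribute; all
frequencies are kept as exact rationals internally and rounded to 4
decimals on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .clustering import ClusterModel
from .interactions import InteractionRecord

__all__ = [
    "ProfileRow",
    "InteractionProfile",
    "cluster_weights",
    "compute_fipc",
    "compute_fi",
    "residue_totals",
    "moiety_breakdown",
    "build_profile",
    "plot_residue_totals",
]

ResidueKey = tuple[str, int, str, str]  # chain, resnum, icode, resname


def residue_label(res: ResidueKey) -> str:
    chain, resnum, icode, resname = res
    return f"{chain}:{resname}{resnum}{icode.strip()}"


@dataclass
class ProfileRow:
    cluster: int
    residue: ResidueKey
    moiety: str
    itype: str
    n_poses: int  # poses in the cluster exhibiting the triple
    fipc: Fraction
    fi: Fraction | None = None


@dataclass
class InteractionProfile:
    rows: list[ProfileRow]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = [
            {
                "cluster": r.cluster,
                "residue": residue_label(r.residue),
                "chain": r.residue[0],
                "resnum": r.residue[1],
                "resname": r.residue[3],
                "moiety": r.moiety,
                "itype": r.itype,
                "n_poses": r.n_poses,
                "fipc": round(float(r.fipc), 4),
                "fi": round(float(r.fi), 4) if r.fi is not None else None,
            }
            for r in self.rows
        ]
        cols = ["cluster", "residue", "chain", "resnum", "resname", "moiety",
                "itype", "n_poses", "fipc", "fi"]
        return pd.DataFrame(data, columns=cols)


def cluster_weights(model: ClusterModel) -> dict[int, Fraction]:
    """Exact population share SCP/TPSC per significant cluster (sums to 1)."""
    if model.tpsc == 0:
        raise ValueError("no significant clusters (TPSC is 0)")
    return {c: Fraction(scp, model.tpsc) for c, scp in model.scp.items()}


def compute_fipc(records: Sequence[InteractionRecord], model: ClusterModel) -> InteractionProfile:
    """FIPC rows for every (significant cluster, triple) observed.

    ``records`` must already be deduplicated per (pose, residue, moiety,
    itype) — :func:`dockprof.interactions.detect_interactions` guarantees
    this per pose. Triples absent from a cluster produce no row (zero
    frequencies are suppressed). A record whose pose is not in the model
    is a hard error.
    """
    sig = model.significant
    counts: dict[tuple[int, tuple], int] = {}
    seen: set[tuple] = set()
    for rec in records:
        cluster = model.assignment.get(rec.pose_id)
        if cluster is None:
            raise ValueError(f"record pose {rec.pose_id!r} is absent from the cluster model")
        dedup_key = (rec.pose_id, rec.triple())
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        if cluster not in sig:
            continue
        key = (cluster, rec.triple())
        counts[key] = counts.get(key, 0) + 1
    rows = [
        ProfileRow(
            cluster=cluster,
            residue=triple[0],
            moiety=triple[1],
            itype=triple[2],
            n_poses=n,
            fipc=Fraction(n, model.scp[cluster]),
        )
        for (cluster, triple), n in counts.items()
    ]
    rows.sort(key=lambda r: (r.cluster, r.residue[0], r.residue[1], r.residue[2],
                             r.itype, r.moiety))
    return InteractionProfile(rows=rows, metadata=dict(model.metadata))


def compute_fi(profile: InteractionProfile, model: ClusterModel) -> InteractionProfile:
    """Fill FI = FIPC * SCP / TPSC on every row (in place; also returned)."""
    weights = cluster_weights(model)
    for row in profile.rows:
        row.fi = row.fipc * weights[row.cluster]
    return profile


def residue_totals(profile: InteractionProfile) -> pd.DataFrame:
    """Summed FI per residue, descending (ties broken by residue number).

    The resulting ranking is the candidate molecular-determinant list: it
    weighs how many interactions a residue makes with the conformers of
    the significant clusters.
    """
    totals: dict[ResidueKey, Fraction] = {}
    for row in profile.rows:
        if row.fi is None:
            raise ValueError("FI not filled; run compute_fi first")
        totals[row.residue] = totals.get(row.residue, Fraction(0)) + row.fi
    items = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0], kv[0][2]))
    return pd.DataFrame(
        [
            {
                "residue": residue_label(res),
                "chain": res[0],
                "resnum": res[1],
                "resname": res[3],
                "total_fi": round(float(fi), 4),
            }
            for res, fi in items
        ],
        columns=["residue", "chain", "resnum", "resname", "total_fi"],
    )


def moiety_breakdown(profile: InteractionProfile) -> pd.DataFrame:
    """FI summed over clusters, pivoted as (moiety, itype) x residue.

    This is the moiety-resolved interaction fingerprint: which portion of
    the ligand establishes which kind of contact with which residue.
    """
    acc: dict[tuple[str, str, ResidueKey], Fraction] = {}
    for row in profile.rows:
        if row.fi is None:
            raise ValueError("FI not filled; run compute_fi first")
        key = (row.moiety, row.itype, row.residue)
        acc[key] = acc.get(key, Fraction(0)) + row.fi
    if not acc:
        return pd.DataFrame()
    long = pd.DataFrame(
        [
            {"moiety": m, "itype": t, "residue": residue_label(res),
             "resnum": res[1], "fi": float(fi)}
            for (m, t, res), fi in acc.items()
        ]
    )
    order = long.sort_values("resnum")["residue"].unique()
    table = long.pivot_table(index=["moiety", "itype"], columns="residue",
                             values="fi", aggfunc="sum", fill_value=0.0)
    table = table.reindex(columns=order).round(4)
    return table


def build_profile(records: Sequence[InteractionRecord], model: ClusterModel,
                  metadata: dict | None = None) -> InteractionProfile:
    """FIPC + FI in one step."""
    profile = compute_fipc(records, model)
    compute_fi(profile, model)
    if metadata:
        profile.metadata.update(metadata)
    return profile


def plot_residue_totals(totals: pd.DataFrame, path, top: int = 20) -> None:
    """Bar chart of the top residues by summed FI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = totals.head(top)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(df)), 4))
    ax.bar(df["residue"], df["total_fi"], color="#46689b")
    ax.set_ylabel("summed FI")
    ax.set_xlabel("residue")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
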