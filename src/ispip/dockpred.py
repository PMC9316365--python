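"""Docking-based interface likelihood (DockPred-style scoring).

Non-cognate protein ligands tend to bind the same "sticky" patches as the
cognate partner, so the frequency with which a residue appears at the
interface of many docked poses — against partners that are deliberately
unrelated to the query — is itself an interface predictor.  The canonical
setup docks the query against 13 diverse non-cognate partners, keeping 2000
poses per partner; a residue is at a pose's interface when any of its heavy
atoms is within 4.0 Å of the docked partner.

The score of residue ``r`` is the per-partner interface fraction averaged
over partners:

    score(r) = (1/P) * Σ_p  (# poses of partner p with r interfacial) / (# poses of partner p)

Pose input comes either as full coordinate files (one PDB per pose) or as
precomputed per-pose interface residue sets; the computation defined here is
the aggregation, not the docking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure import ResidueKey, StructureModel, annotate_interface, parse_structure

__all__ = [
    "PoseSet",
    "DockScoreVector",
    "pose_interface_set",
    "dockpred_scores",
    "read_pose_table",
    "read_pose_directory",
]

DEFAULT_PARTNERS = 13
DEFAULT_POSES_PER_PARTNER = 2000


@dataclass
class PoseSet:
    """All docked poses for one non-cognate partner, reduced to their
    per-pose interface residue sets."""

    partner_id: str
    interface_sets: list[frozenset[ResidueKey]]

    def __post_init__(self) -> None:
        if len(self.interface_sets) == 0:
            raise ValueError(f"partner {self.partner_id!r} has zero poses")

    @property
    def n_poses(self) -> int:
        return len(self.interface_sets)


@dataclass
class DockScoreVector:
    scores: dict[ResidueKey, float]
    partner_count: int
    pose_counts: dict[str, int]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name="dockpred")


def pose_interface_set(
    pose: StructureModel,
    query_chain: str,
    partner_chain: str,
    cutoff: float = 4.0,
) -> frozenset[ResidueKey]:
    """Query residues with any heavy atom within ``cutoff`` of the docked partner."""
    ann = annotate_interface(pose, query_chain, {partner_chain}, cutoff)
    return frozenset(ann.positives())


def dockpred_scores(
    pose_sets: Sequence[PoseSet],
    query_residues: Sequence[ResidueKey],
    *,
    pooled: bool = False,
) -> DockScoreVector:
    """Aggregate per-pose interface sets into per-residue likelihoods.

    Partners are weighted equally (mean of per-partner fractions) by default;
    ``pooled=True`` instead pools all poses into one denominator.  The two
    coincide when every partner contributes the same number of poses.
    """
    if not pose_sets:
        raise ValueError("at least one PoseSet required")
    query = list(query_residues)
    query_set = set(query)
    if len(query_set) != len(query):
        raise ValueError("duplicate residue keys in query residue list")
    for ps in pose_sets:
        for s in ps.interface_sets:
            stray = s - query_set
            if stray:
                raise ValueError(
                    f"pose of partner {ps.partner_id!r} references residues "
                    f"outside the query: {sorted(stray)[:3]}"
                )

    index = {key: i for i, key in enumerate(query)}
    P = len(pose_sets)
    if pooled:
        counts = np.zeros(len(query))
        total = 0
        for ps in pose_sets:
            total += ps.n_poses
            for s in ps.interface_sets:
                for key in s:
                    counts[index[key]] += 1
        values = counts / total
    else:
        # exact rational accumulation: scores are invariant to partner and
        # pose ordering, and a single partner yields the exact pose fraction
        from fractions import Fraction

        acc = [Fraction(0)] * len(query)
        for ps in pose_sets:
            counts = [0] * len(query)
            for s in ps.interface_sets:
                for key in s:
                    counts[index[key]] += 1
            for i, c in enumerate(counts):
                acc[i] += Fraction(c, ps.n_poses)
        values = np.array([float(a / P) for a in acc])
    return DockScoreVector(
        scores={key: float(values[i]) for key, i in index.items()},
        partner_count=P,
        pose_counts={ps.partner_id: ps.n_poses for ps in pose_sets},
    )


def read_pose_table(path_or_buffer, sep: str = "\t") -> list[PoseSet]:
    """Read precomputed pose interfaces from a delimited file with columns
    (partner_id, pose_id, chain, resnum, icode).  A row per interfacial
    residue per pose; poses with no interfacial residue still need one row
    with empty chain/resnum to register the pose — or appear implicitly when
    ``pose_id`` gaps are dense.  Empty-interface poses may alternatively list
    resnum as blank.
    """
    df = pd.read_csv(
        path_or_buffer, sep=sep, dtype={"partner_id": str, "chain": str, "icode": str}
    )
    required = {"partner_id", "pose_id", "chain", "resnum", "icode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    df["icode"] = df["icode"].fillna("")
    sets: list[PoseSet] = []
    for partner_id, part in df.groupby("partner_id", sort=False):
        poses: dict[object, set[ResidueKey]] = {}
        for row in part.itertuples(index=False):
            pose = poses.setdefault(row.pose_id, set())
            if pd.notna(row.resnum) and str(row.chain) not in ("", "nan"):
                pose.add(ResidueKey(str(row.chain), int(row.resnum), str(row.icode)))
        sets.append(
            PoseSet(str(partner_id), [frozenset(poses[k]) for k in poses])
        )
    return sets


def read_pose_directory(
    root: str | Path,
    query_chain: str,
    partner_chain: str,
    cutoff: float = 4.0,
) -> list[PoseSet]:
    """Read poses laid out as ``<root>/<partner_id>/pose_*.pdb`` and reduce
    each coordinate file to its interface set."""
    root = Path(root)
    sets: list[PoseSet] = []
    for partner_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        interfaces = []
        for pose_file in sorted(partner_dir.glob("pose_*.pdb")):
            pose = parse_structure(pose_file.read_text())
            interfaces.append(pose_interface_set(pose, query_chain, partner_chain, cutoff))
        if interfaces:
            sets.append(PoseSet(partner_dir.name, interfaces))
    if not sets:
        raise ValueError(f"no poses found under {root}")
    return sets
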