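"""Binder-histone contact detection and steric-clash screening.

Contacts are heavy-atom pairs (one atom on the binder chain, one on a
histone chain) within a distance cutoff (default 5 Å), deduplicated to
residue pairs with the minimum atom-atom distance retained.  DNA chains
take part in clash detection but never contribute SF contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import HISTONE_ROLES, PredictedModel, ConfidenceBundle

__all__ = [
    "AtomContact",
    "ContactPair",
    "ContactSet",
    "ClashReport",
    "find_atom_contacts",
    "dedupe_to_residue_pairs",
    "detect_clashes",
    "histone_combination",
    "all_histone_combinations",
    "contacts_to_frame",
]


class AtomContact(NamedTuple):
    binder_res: tuple[str, int]
    binder_atom: str
    histone_res: tuple[str, int]
    histone_atom: str
    histone_type: str
    distance: float


@dataclass(frozen=True)
class ContactPair:
    binder_res: tuple[str, int]
    histone_res: tuple[str, int]
    histone_type: str
    min_dist: float


@dataclass
class ContactSet:
    model_id: str
    pairs: list[ContactPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def residue_pairs(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        return {(p.binder_res, p.histone_res) for p in self.pairs}


@dataclass
class ClashReport:
    has_confidence_clash: bool
    n_histone_clash_atom_pairs: int
    excluded: bool


def _chain_atom_table(chains) -> tuple[np.ndarray, list[tuple[str, int, str, str]]]:
    """Flatten heavy atoms of the given chains into coordinates plus
    (chain_id, seq_id, atom_name, role) bookkeeping rows."""
    coords: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str]] = []
    for chain in chains:
        for res in chain.residues:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                meta.append((chain.chain_id, res.seq_id, atom.name, chain.role))
    if not coords:
        return np.empty((0, 3)), meta
    return np.asarray(coords), meta


def find_atom_contacts(
    model: PredictedModel, cutoff: float = 5.0
) -> list[AtomContact]:
    """All heavy-atom pairs (binder atom, histone atom) within ``cutoff`` Å.

    Uses a KD-tree; the result is identical to a brute-force all-pairs
    scan (distances compared with <=).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    binder = model.binder_chain
    histones = model.histone_chains
    if not histones:
        raise ValueError(f"model {model.model_id} has no histone chains")

    b_xyz, b_meta = _chain_atom_table([binder])
    h_xyz, h_meta = _chain_atom_table(histones)
    out: list[AtomContact] = []
    if len(b_xyz) == 0 or len(h_xyz) == 0:
        return out
    tree = cKDTree(h_xyz)
    for bi, neighbors in enumerate(tree.query_ball_point(b_xyz, r=cutoff)):
        b_chain, b_seq, b_atom, _ = b_meta[bi]
        for hi in sorted(neighbors):
            h_chain, h_seq, h_atom, h_role = h_meta[hi]
            dist = float(np.linalg.norm(b_xyz[bi] - h_xyz[hi]))
            out.append(
                AtomContact(
                    binder_res=(b_chain, b_seq),
                    binder_atom=b_atom,
                    histone_res=(h_chain, h_seq),
                    histone_atom=h_atom,
                    histone_type=h_role,
                    distance=dist,
                )
            )
    return out


def dedupe_to_residue_pairs(
    atom_contacts: Iterable[AtomContact], model_id: str = ""
) -> ContactSet:
    """Collapse atom contacts to unique (binder residue, histone residue)
    pairs, keeping the minimum atom-atom distance per pair."""
    best: dict[tuple[tuple[str, int], tuple[str, int]], AtomContact] = {}
    order: list[tuple[tuple[str, int], tuple[str, int]]] = []
    for ac in atom_contacts:
        key = (ac.binder_res, ac.histone_res)
        if key not in best:
            best[key] = ac
            order.append(key)
        elif ac.distance < best[key].distance:
            best[key] = ac
    pairs = [
        ContactPair(
            binder_res=key[0],
            histone_res=key[1],
            histone_type=best[key].histone_type,
            min_dist=best[key].distance,
        )
        for key in order
    ]
    return ContactSet(model_id=model_id, pairs=pairs)


def detect_clashes(
    model: PredictedModel,
    confidence: ConfidenceBundle | None = None,
    clash_dist: float = 1.2,
    tolerance: int = 0,
) -> ClashReport:
    """Count binder vs histone/DNA heavy-atom pairs closer than
    ``clash_dist`` Å (strict) and combine with the AlphaFold clash flag.

    A model is excluded when the confidence file flags a clash or the
    geometric clash count exceeds ``tolerance``.
    """
    binder = model.binder_chain
    partners = [c for c in model.chains if c.role in HISTONE_ROLES or c.role == "DNA"]
    b_xyz, _ = _chain_atom_table([binder])
    p_xyz, _ = _chain_atom_table(partners)
    n_clash = 0
    if len(b_xyz) and len(p_xyz):
        tree = cKDTree(p_xyz)
        for bi, neighbors in enumerate(tree.query_ball_point(b_xyz, r=clash_dist)):
            for hi in neighbors:
                if np.linalg.norm(b_xyz[bi] - p_xyz[hi]) < clash_dist:
                    n_clash += 1
    flagged = bool(confidence.has_clash) if confidence is not None else False
    return ClashReport(
        has_confidence_clash=flagged,
        n_histone_clash_atom_pairs=n_clash,
        excluded=flagged or n_clash > tolerance,
    )


def histone_combination(contacts: ContactSet) -> frozenset[str]:
    """The set of histone types contacted; the empty set means "no histone
    contact" and falls outside the 15 non-empty combination categories."""
    return frozenset(p.histone_type for p in contacts.pairs)


def all_histone_combinations() -> list[frozenset[str]]:
    """Enumerate the 15 non-empty subsets of {H2A, H2B, H3, H4}."""
    combos: list[frozenset[str]] = []
    for mask in range(1, 1 << len(HISTONE_ROLES)):
        combos.append(
            frozenset(
                role for i, role in enumerate(HISTONE_ROLES) if mask & (1 << i)
            )
        )
    return combos


def contacts_to_frame(contact_set: ContactSet) -> pd.DataFrame:
    """Tabular export of a ContactSet (one row per residue pair)."""
    rows = [
        {
            "model_id": contact_set.model_id,
            "binder_chain": p.binder_res[0],
            "binder_res": p.binder_res[1],
            "histone_chain": p.histone_res[0],
            "histone_res": p.histone_res[1],
            "histone_type": p.histone_type,
            "min_dist": p.min_dist,
        }
        for p in contact_set.pairs
    ]
    columns = [
        "model_id", "binder_chain", "binder_res",
        "histone_chain", "histone_res", "histone_type", "min_dist",
    ]
    return pd.DataFrame(rows, columns=columns)
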