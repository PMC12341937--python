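"""Acidic-patch analyses.

The nucleosome acidic patch is the negatively charged cluster formed on
each face of the histone octamer by H2A residues E57, E62, E65, D91, E92
and E93 (human H2A type 2-C numbering).  Its two sub-pockets are
AP1 = {E62, D91, E93} and AP2 = {E62, D91, E65}; canonical binders insert
an arginine or lysine anchor into these pockets.

This module locates the patch on each H2A copy of a model (by alignment
to the reference sequence, so truncated constructs and arbitrary author
numbering are handled), extracts binder residues near the patch centroid,
scores inter-model prediction consistency (mode of the 10 pairwise
binder-residue RMSDs across a protein's five models, normalized against
the cohort maximum), builds 21-residue motif windows centred on the
anchor Arg/Lys, and calls benchmark hits against experimentally solved
reference complexes by Jaccard overlap of acidic-patch contact pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .contacts import ContactSet
from .structio import (
    HISTONE_REFERENCES,
    ChainRecord,
    PredictedModel,
    align_to_reference,
)

__all__ = [
    "AcidicPatchDefinition",
    "PatchContactSet",
    "ConsistencyResult",
    "MotifWindow",
    "BenchmarkCall",
    "locate_patch_faces",
    "patch_centroid",
    "binder_patch_residues",
    "select_representative_segment",
    "superpose_on_histones",
    "kabsch",
    "patch_rmsd_matrix",
    "mode_rmsd",
    "consistency_score",
    "motif_windows",
    "patch_pair_set",
    "benchmark_hit",
]

#: Seed used for random tie-breaking between equal-length binding segments.
DEFAULT_TIEBREAK_SEED = 985866441


@dataclass(frozen=True)
class AcidicPatchDefinition:
    """Acidic-patch residue positions in reference H2A numbering."""

    ap_residues: frozenset[int] = frozenset({57, 62, 65, 91, 92, 93})
    ap1: frozenset[int] = frozenset({62, 91, 93})
    ap2: frozenset[int] = frozenset({62, 91, 65})
    reference_sequence: str = HISTONE_REFERENCES["H2A"]

    def __post_init__(self) -> None:
        if not (self.ap1 <= self.ap_residues and self.ap2 <= self.ap_residues):
            raise ValueError("AP1 and AP2 must be subsets of the patch residues")

    @property
    def pocket_residues(self) -> frozenset[int]:
        return self.ap1 | self.ap2


@dataclass
class PatchContactSet:
    model_id: str
    face: str  # chain_id of the H2A copy carrying the occupied patch
    binder_residues: list[int]
    segments: list[list[int]]


@dataclass
class ConsistencyResult:
    protein_id: str
    rmsd_pairs: list[float] = field(default_factory=list)
    omitted_pairs: list[tuple[int, int]] = field(default_factory=list)
    mode_rmsd: float = float("nan")
    score: float = float("nan")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mode_rmsd)


@dataclass(frozen=True)
class MotifWindow:
    center: int
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != 21:
            raise ValueError(f"motif window must have length 21, got {len(self.window)}")
        if self.window[10] not in "RK":
            raise ValueError(f"window centre must be R or K, got {self.window[10]!r}")


@dataclass
class BenchmarkCall:
    protein_id: str
    jaccard: float
    positive: bool
    defined: bool = True


# ---------------------------------------------------------------------------
# Patch location and centroid
# ---------------------------------------------------------------------------

def locate_patch_faces(
    model: PredictedModel, defn: AcidicPatchDefinition | None = None
) -> list[tuple[str, dict[int, int]]]:
    """For each H2A chain, map reference patch positions to author seq_ids.

    Returns a list of (chain_id, {ref_pos: seq_id}) in model chain order;
    positions missing from a truncated chain are absent from its map.
    """
    defn = defn or AcidicPatchDefinition()
    faces = []
    for chain in model.chains_with_role("H2A"):
        ref_to_query_idx = align_to_reference(chain.sequence, defn.reference_sequence)
        mapping: dict[int, int] = {}
        for ref_pos in sorted(defn.ap_residues):
            q_idx = ref_to_query_idx.get(ref_pos)
            if q_idx is not None:
                mapping[ref_pos] = chain.residues[q_idx - 1].seq_id
        faces.append((chain.chain_id, mapping))
    return faces


def patch_centroid(
    model: PredictedModel,
    defn: AcidicPatchDefinition | None = None,
    face: str | None = None,
) -> np.ndarray:
    """Unweighted mean of the heavy-atom coordinates of the AP1 ∪ AP2
    residues on one H2A face (the first H2A chain when ``face`` is None)."""
    defn = defn or AcidicPatchDefinition()
    faces = dict(locate_patch_faces(model, defn))
    if face is None:
        h2a = model.chains_with_role("H2A")
        if not h2a:
            raise ValueError(f"model {model.model_id} has no H2A chain")
        face = h2a[0].chain_id
    if face not in faces:
        raise ValueError(f"chain {face} is not an H2A chain of model {model.model_id}")
    mapping = faces[face]
    missing = sorted(defn.pocket_residues - set(mapping))
    if missing:
        raise ValueError(
            f"model {model.model_id} chain {face}: acidic-patch residues "
            f"missing from the structure: {missing}"
        )
    chain = model.get_chain(face)
    coords = []
    for ref_pos in sorted(defn.pocket_residues):
        res = chain.get_residue(mapping[ref_pos])
        coords.extend(a.coords for a in res.heavy_atoms())
    if not coords:
        raise ValueError(f"no heavy atoms found for the acidic patch on chain {face}")
    return np.mean(np.asarray(coords), axis=0)


def _segments_of(seq_ids: Sequence[int]) -> list[list[int]]:
    segments: list[list[int]] = []
    for sid in sorted(seq_ids):
        if segments and sid == segments[-1][-1] + 1:
            segments[-1].append(sid)
        else:
            segments.append([sid])
    return segments


def binder_patch_residues(
    model: PredictedModel,
    defn: AcidicPatchDefinition | None = None,
    cutoff: float = 5.0,
) -> PatchContactSet:
    """Binder residues with a heavy atom within ``cutoff`` Å of the patch
    centroid.  Both nucleosome faces are evaluated; the face with more
    qualifying residues is reported (ties go to the first H2A chain)."""
    defn = defn or AcidicPatchDefinition()
    binder = model.binder_chain
    best: PatchContactSet | None = None
    for chain_id, mapping in locate_patch_faces(model, defn):
        if not defn.pocket_residues <= set(mapping):
            continue
        centroid = patch_centroid(model, defn, face=chain_id)
        near = []
        for res in binder.residues:
            dists = [np.linalg.norm(a.coords - centroid) for a in res.heavy_atoms()]
            if dists and min(dists) <= cutoff:
                near.append(res.seq_id)
        candidate = PatchContactSet(
            model_id=model.model_id,
            face=chain_id,
            binder_residues=sorted(near),
            segments=_segments_of(near),
        )
        if best is None or len(candidate.binder_residues) > len(best.binder_residues):
            best = candidate
    if best is None:
        raise ValueError(
            f"model {model.model_id}: no H2A chain carries a complete acidic patch"
        )
    return best


def select_representative_segment(
    pcs: PatchContactSet, seed: int = DEFAULT_TIEBREAK_SEED
) -> list[int]:
    """The longest patch-binding segment; equal-length ties are resolved
    by a seeded uniform draw so re-runs are reproducible."""
    if not pcs.segments:
        raise ValueError(f"model {pcs.model_id}: no patch-binding segments")
    max_len = max(len(s) for s in pcs.segments)
    longest = [s for s in pcs.segments if len(s) == max_len]
    if len(longest) == 1:
        return longest[0]
    rng = np.random.default_rng(seed)
    return longest[int(rng.integers(len(longest)))]


# ---------------------------------------------------------------------------
# Superposition and consistency
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R @ moving_i + t ≈ fixed_i."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return R, t


def _histone_ca_map(model: PredictedModel) -> dict[tuple[str, int, int], np.ndarray]:
    """Histone Cα coordinates keyed by (role, copy index within role,
    seq_id) — chain-id independent so models from different jobs match."""
    out: dict[tuple[str, int, int], np.ndarray] = {}
    copy_count: dict[str, int] = {}
    for chain in model.chains:
        if chain.role not in ("H2A", "H2B", "H3", "H4"):
            continue
        idx = copy_count.get(chain.role, 0)
        copy_count[chain.role] = idx + 1
        for res in chain.residues:
            ca = res.get_atom("CA")
            if ca is not None:
                out[(chain.role, idx, res.seq_id)] = ca.coords
    return out


def superpose_on_histones(
    model_a: PredictedModel, model_b: PredictedModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch-superpose ``model_b`` onto ``model_a`` over shared histone
    Cα atoms; returns (R, t, core_rmsd)."""
    ca_a = _histone_ca_map(model_a)
    ca_b = _histone_ca_map(model_b)
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError(
            f"models {model_a.model_id} and {model_b.model_id} share only "
            f"{len(shared)} histone CA atoms; >= 3 required"
        )
    fixed = np.array([ca_a[k] for k in shared])
    moving = np.array([ca_b[k] for k in shared])
    R, t = kabsch(moving, fixed)
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return R, t, rmsd


def _binder_ca(model: PredictedModel, seq_ids: Iterable[int]) -> np.ndarray | None:
    chain = model.binder_chain
    coords = []
    for sid in seq_ids:
        res = chain.get_residue(sid)
        ca = res.get_atom("CA") if res is not None else None
        if ca is None:
            return None
        coords.append(ca.coords)
    return np.asarray(coords)


def patch_rmsd_matrix(
    models: Sequence[PredictedModel],
    patch_sets: Sequence[PatchContactSet],
    protein_id: str = "",
    bin_width: float = 0.1,
) -> ConsistencyResult:
    """Pairwise patch-region RMSDs across a protein's models.

    For every model pair, model b is superposed onto model a over shared
    histone Cα atoms and the RMSD is taken over the Cα atoms of the
    intersection of the two models' patch-contacting binder residues.
    Pairs with an empty intersection are omitted and flagged.  The mode
    of the collected RMSDs (0.1 Å histogram) summarizes consistency; the
    cohort-normalized score is filled in later by the caller.
    """
    if len(models) != len(patch_sets):
        raise ValueError("need one PatchContactSet per model")
    result = ConsistencyResult(protein_id=protein_id)
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            common = sorted(
                set(patch_sets[i].binder_residues)
                & set(patch_sets[j].binder_residues)
            )
            ca_i = _binder_ca(models[i], common) if common else None
            ca_j = _binder_ca(models[j], common) if common else None
            if not common or ca_i is None or ca_j is None:
                result.omitted_pairs.append((i, j))
                continue
            R, t, _ = superpose_on_histones(models[i], models[j])
            ca_j_moved = ca_j @ R.T + t
            rmsd = float(np.sqrt(np.mean(np.sum((ca_j_moved - ca_i) ** 2, axis=1))))
            if rmsd < 1e-8:  # Kabsch round-off on identical conformations
                rmsd = 0.0
            result.rmsd_pairs.append(rmsd)
    if result.rmsd_pairs:
        result.mode_rmsd = mode_rmsd(result.rmsd_pairs, bin_width=bin_width)
    return result


def mode_rmsd(values: Sequence[float], bin_width: float = 0.1) -> float:
    """Mode of continuous RMSD values estimated by histogram binning:
    centre of the most populated ``bin_width`` bin, ties to the lowest bin.

    A degenerate winning bin (all its values identical, e.g. the all-zero
    RMSDs of five identical models) returns that exact value, so perfectly
    reproducible predictions score a consistency of exactly 1.
    """
    if len(values) == 0:
        raise ValueError("mode_rmsd requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    bins = [int(v // bin_width) for v in values]
    counts: dict[int, int] = {}
    for b in bins:
        counts[b] = counts.get(b, 0) + 1
    best_bin = min(counts, key=lambda b: (-counts[b], b))
    in_bin = [v for v, b in zip(values, bins) if b == best_bin]
    if max(in_bin) == min(in_bin):
        return float(in_bin[0])
    return (best_bin + 0.5) * bin_width


def consistency_score(mode: float, cohort_max: float) -> float:
    """1 − mode/cohort_max, clipped to [0, 1]."""
    if not cohort_max > 0:
        raise ValueError(f"cohort_max must be > 0, got {cohort_max}")
    return float(np.clip(1.0 - mode / cohort_max, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Motif windows and benchmarking
# ---------------------------------------------------------------------------

def motif_windows(
    model: PredictedModel,
    contacts: ContactSet,
    defn: AcidicPatchDefinition | None = None,
) -> list[MotifWindow]:
    """One 21-residue window (centre ± 10, '-'-padded at the termini) per
    binder Arg/Lys contacting an AP1 or AP2 pocket residue."""
    defn = defn or AcidicPatchDefinition()
    binder = model.binder_chain
    pocket_ids: set[tuple[str, int]] = set()
    for chain_id, mapping in locate_patch_faces(model, defn):
        for ref_pos in defn.pocket_residues:
            if ref_pos in mapping:
                pocket_ids.add((chain_id, mapping[ref_pos]))
    centers = []
    for pair in contacts.pairs:
        if pair.histone_res in pocket_ids:
            res = binder.get_residue(pair.binder_res[1])
            if res is not None and res.aa_code in "RK":
                centers.append(res.seq_id)
    seq = binder.sequence
    index_of = {res.seq_id: i for i, res in enumerate(binder.residues)}
    windows = []
    for center in sorted(set(centers)):
        i = index_of[center]
        lo, hi = i - 10, i + 10
        chars = [
            seq[k] if 0 <= k < len(seq) else "-" for k in range(lo, hi + 1)
        ]
        windows.append(MotifWindow(center=center, window="".join(chars)))
    return windows


def patch_pair_set(
    model: PredictedModel,
    contacts: ContactSet,
    defn: AcidicPatchDefinition | None = None,
) -> set[tuple[int, int]]:
    """Contact pairs restricted to the acidic patch, expressed in the
    model-independent frame (binder seq_id, H2A reference position)."""
    defn = defn or AcidicPatchDefinition()
    seqid_to_ref: dict[tuple[str, int], int] = {}
    for chain_id, mapping in locate_patch_faces(model, defn):
        for ref_pos, sid in mapping.items():
            seqid_to_ref[(chain_id, sid)] = ref_pos
    pairs = set()
    for pair in contacts.pairs:
        ref_pos = seqid_to_ref.get(pair.histone_res)
        if ref_pos is not None:
            pairs.add((pair.binder_res[1], ref_pos))
    return pairs


def benchmark_hit(
    predicted: set[tuple[int, int]],
    reference: set[tuple[int, int]],
    threshold: float = 0.3,
    protein_id: str = "",
) -> BenchmarkCall:
    """Jaccard overlap of acidic-patch contact pairs between a predicted
    and an experimentally solved complex; positive when >= ``threshold``.
    Two empty sets give an undefined (flagged) negative call."""
    union = predicted | reference
    if not union:
        return BenchmarkCall(
            protein_id=protein_id, jaccard=0.0, positive=False, defined=False
        )
    jaccard = len(predicted & reference) / len(union)
    return BenchmarkCall(
        protein_id=protein_id, jaccard=jaccard, positive=jaccard >= threshold
    )
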