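"""Synthetic mini-nucleosome fixtures.

Generates fully self-contained test inputs: a miniature nucleosome (eight
short histone chains embedding exact substrings of the reference histone
sequences, two short DNA strands) plus a binder chain positioned so that
every planted quantity — binder-histone contact distances, steric
clashes, binder residues near the acidic-patch centroid, PAE and pLDDT
values — is realized exactly and is recoverable by the corresponding
analysis operation.

Geometry is deliberately non-physical: chains are ideal Cα traces
(3.8 Å spacing) laid out on widely separated lines, and the acidic-patch
residues of each H2A copy are clustered at an off-chain pocket site so a
patch centroid exists away from everything else.  The screening method
depends only on distances and confidences, so nothing more is needed.

Everything is a pure function of the spec (seed included): re-running
produces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import (
    HISTONE_REFERENCES,
    AtomRecord,
    ChainRecord,
    ConfidenceBundle,
    PredictedModel,
    ResidueRecord,
)

__all__ = [
    "FixtureSpec",
    "make_mini_nucleosome",
    "place_binder",
    "synth_confidence",
    "build_fixture",
    "write_model_cif",
    "write_confidence_json",
    "write_fixture_files",
]

# chain roster: two copies of each histone, two DNA strands, one binder
CHAIN_ROSTER: tuple[tuple[str, str], ...] = (
    ("A", "H2A"), ("B", "H2A"),
    ("C", "H2B"), ("D", "H2B"),
    ("E", "H3"), ("F", "H3"),
    ("G", "H4"), ("H", "H4"),
    ("I", "DNA"), ("J", "DNA"),
    ("K", "BINDER"),
)

#: First author seq_id of each histone chain; H2A starts at 50 so the
#: default 51-residue chain spans 50-100 and carries the complete patch.
_HISTONE_START = {"H2A": 50, "H2B": 32, "H3": 39, "H4": 21}

_AP_SEQ_IDS = (57, 62, 65, 91, 92, 93)  # author == reference numbering here

_CA_SPACING = 3.8
_CHAIN_SPACING = 60.0
_POCKET_OFFSET = 10.0  # patch cluster sits this far off the chain line
_DEFAULT_PAE = 31.75
_DEFAULT_PLDDT = 50.0
_MARGIN = 1.0  # unplanned pairs stay above cutoff + margin

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_NT1TO3 = {"a": "DA", "c": "DC", "g": "DG", "t": "DT", "u": "DU"}


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic model.

    ``planted_contacts`` / ``clash_pairs`` are ((binder_chain, seq),
    (histone_chain, seq), distance) triples realized as exact minimum
    inter-residue heavy-atom distances.  ``planted_patch_residues`` are
    (binder seq_id, distance-from-patch-centroid) pairs placed at the
    first H2A face's pocket.  ``planted_pae`` entries are directional
    ((chain, seq), (chain, seq), value); everything else defaults to the
    maximally uninformative 31.75 / 50 confidence background.
    """

    seed: int = 0
    n_histone_res_per_chain: int = 51
    binder_length: int = 25
    n_dna_res_per_chain: int = 20
    binder_sequence: str | None = None
    planted_contacts: list[tuple[tuple[str, int], tuple[str, int], float]] = field(
        default_factory=list
    )
    clash_pairs: list[tuple[tuple[str, int], tuple[str, int], float]] = field(
        default_factory=list
    )
    planted_patch_residues: list[tuple[int, float]] = field(default_factory=list)
    planted_pae: list[tuple[tuple[str, int], tuple[str, int], float]] = field(
        default_factory=list
    )
    planted_plddt: list[tuple[tuple[str, int], float]] = field(default_factory=list)
    has_clash: bool = False
    contact_cutoff: float = 5.0

    def __post_init__(self) -> None:
        for (_, _, d) in self.planted_contacts:
            if d < 1.5:
                raise ValueError(
                    f"planted contact distance {d} < 1.5 Å; use clash_pairs "
                    "for deliberate clashes"
                )
        for (_, v) in self.planted_plddt:
            if not 0 <= v <= 100:
                raise ValueError(f"planted pLDDT {v} outside [0, 100]")
        for (_, _, v) in self.planted_pae:
            if v < 0:
                raise ValueError(f"planted PAE {v} < 0")


def _residue(chain_id: str, seq_id: int, code: str, ca: np.ndarray,
             bfactor: float) -> ResidueRecord:
    ca = np.asarray(ca, float)
    if code in _NT1TO3:
        atoms = [
            AtomRecord("P", "P", ca + np.array([-1.0, 0.8, 0.0]), 1.0, bfactor),
            AtomRecord("C", "C1'", ca, 1.0, bfactor),
        ]
    else:
        atoms = [
            AtomRecord("N", "N", ca + np.array([-1.2, 0.6, 0.0]), 1.0, bfactor),
            AtomRecord("C", "CA", ca, 1.0, bfactor),
            AtomRecord("C", "C", ca + np.array([1.2, 0.6, 0.0]), 1.0, bfactor),
        ]
    return ResidueRecord(chain_id=chain_id, seq_id=seq_id, aa_code=code, atoms=atoms)


def _binder_sequence(spec: FixtureSpec) -> str:
    if spec.binder_sequence is not None:
        if len(spec.binder_sequence) != spec.binder_length:
            raise ValueError("binder_sequence length must equal binder_length")
        return spec.binder_sequence.upper()
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    return "".join(rng.choice(alphabet, size=spec.binder_length))


def make_mini_nucleosome(spec: FixtureSpec) -> PredictedModel:
    """Build the un-placed fixture model (binder far from the nucleosome)."""
    model = PredictedModel(model_id=f"fixture_seed{spec.seed}")
    for k, (chain_id, role) in enumerate(CHAIN_ROSTER):
        chain = ChainRecord(chain_id=chain_id, role=role)
        y = _CHAIN_SPACING * k
        if role == "DNA":
            seq = ("acgt" * ((spec.n_dna_res_per_chain // 4) + 1))[: spec.n_dna_res_per_chain]
            for i, code in enumerate(seq):
                ca = np.array([_CA_SPACING * i, y, 0.0])
                chain.residues.append(
                    _residue(chain_id, i + 1, code, ca, _DEFAULT_PLDDT)
                )
        elif role == "BINDER":
            for i, code in enumerate(_binder_sequence(spec)):
                ca = np.array([_CA_SPACING * i, y, 0.0])
                chain.residues.append(
                    _residue(chain_id, i + 1, code, ca, _DEFAULT_PLDDT)
                )
        else:
            start = _HISTONE_START[role]
            ref = HISTONE_REFERENCES[role]
            end = min(start + spec.n_histone_res_per_chain - 1, len(ref))
            for i, seq_id in enumerate(range(start, end + 1)):
                ca = np.array([_CA_SPACING * i, y, 0.0])
                chain.residues.append(
                    _residue(chain_id, seq_id, ref[seq_id - 1], ca, _DEFAULT_PLDDT)
                )
        model.chains.append(chain)

    # cluster the acidic-patch residues of each H2A copy at an off-chain
    # pocket site so the patch has a meaningful centroid
    for chain in model.chains_with_role("H2A"):
        present = [s for s in _AP_SEQ_IDS if chain.get_residue(s) is not None]
        if len(present) != len(_AP_SEQ_IDS):
            continue  # truncated fixture: no complete patch
        mid_x = float(
            np.mean([_ca_of(chain.get_residue(s))[0] for s in present])
        )
        pocket_y = chain.get_residue(present[0]).atoms[0].coords[1]
        for idx, seq_id in enumerate(present):
            res = chain.get_residue(seq_id)
            target = np.array(
                [mid_x + (idx - (len(present) - 1) / 2) * 1.5,
                 pocket_y + _POCKET_OFFSET, 0.0]
            )
            _move_residue(res, target)
    return model


def _ca_of(res: ResidueRecord) -> np.ndarray:
    rep = res.representative_atom()
    if rep is None:
        rep = res.atoms[0]
    return rep.coords


def _move_residue(res: ResidueRecord, new_ca: np.ndarray) -> None:
    shift = np.asarray(new_ca, float) - _ca_of(res)
    for atom in res.atoms:
        atom.coords = atom.coords + shift


def _min_residue_dist(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    xa = np.array([a.coords for a in res_a.heavy_atoms()])
    xb = np.array([a.coords for a in res_b.heavy_atoms()])
    diff = xa[:, None, :] - xb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def place_binder(model: PredictedModel, spec: FixtureSpec) -> PredictedModel:
    """Realize every planted contact, clash and patch placement exactly.

    Each planted (binder_res, histone_res, d) lifts the histone residue
    off its chain line and parks the binder residue directly above it at
    height d, which makes d the exact minimum heavy-atom distance; the
    lift height is chosen so chain neighbours stay outside
    cutoff + 1 Å.  Placements are then verified by a brute-force distance
    scan; any violation raises (infeasible geometry).
    """
    binder = model.binder_chain
    used_binder: set[int] = set()
    planted_keys: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}

    for (b_res, h_res, dist) in list(spec.planted_contacts) + list(spec.clash_pairs):
        if b_res[0] != binder.chain_id:
            raise ValueError(f"planted binder residue {b_res} not on the binder chain")
        if b_res[1] in used_binder:
            raise ValueError(
                f"binder residue {b_res[1]} used in more than one planting"
            )
        used_binder.add(b_res[1])
        h_chain = model.get_chain(h_res[0])
        if h_chain is None or h_chain.role not in ("H2A", "H2B", "H3", "H4", "DNA"):
            raise ValueError(f"planted partner chain {h_res[0]} is not histone/DNA")
        target = h_chain.get_residue(h_res[1])
        b = binder.get_residue(b_res[1])
        if target is None or b is None:
            raise ValueError(f"planted residue missing: {b_res} / {h_res}")
        # binder ends at height lift + dist >= 6 Å above the chain line, so
        # chain neighbours (effective in-line atom spacing >= 1.4 Å) stay
        # beyond cutoff + margin
        lift = max(2.0, 6.0 - dist)
        _move_residue(target, _ca_of(target) + np.array([0.0, 0.0, lift]))
        _move_residue(b, _ca_of(target) + np.array([0.0, 0.0, dist]))
        planted_keys[(b_res, h_res)] = dist

    patch_exempt: set[tuple[int, tuple[str, int]]] = set()
    if spec.planted_patch_residues:
        from .patch import AcidicPatchDefinition, patch_centroid

        face = model.chains_with_role("H2A")[0]
        centroid = patch_centroid(model, AcidicPatchDefinition(), face=face.chain_id)
        for (b_seq, dist) in spec.planted_patch_residues:
            if b_seq in used_binder:
                raise ValueError(
                    f"binder residue {b_seq} used in more than one planting"
                )
            used_binder.add(b_seq)
            res = binder.get_residue(b_seq)
            if res is None:
                raise ValueError(f"planted patch residue {b_seq} not on binder")
            _move_residue(res, centroid + np.array([0.0, 0.0, dist]))
            for ap_seq in _AP_SEQ_IDS:
                patch_exempt.add((b_seq, (face.chain_id, ap_seq)))

    _verify_geometry(model, spec, planted_keys, patch_exempt)
    return model


def _verify_geometry(
    model: PredictedModel,
    spec: FixtureSpec,
    planted: dict[tuple[tuple[str, int], tuple[str, int]], float],
    patch_exempt: set[tuple[int, tuple[str, int]]],
) -> None:
    binder = model.binder_chain
    margin = spec.contact_cutoff + _MARGIN
    patch_targets = {}
    if spec.planted_patch_residues:
        from .patch import AcidicPatchDefinition, patch_centroid

        face = model.chains_with_role("H2A")[0]
        centroid = patch_centroid(model, AcidicPatchDefinition(), face=face.chain_id)
        for (b_seq, dist) in spec.planted_patch_residues:
            patch_targets[b_seq] = (centroid, dist)

    for partner in model.chains:
        if partner.role not in ("H2A", "H2B", "H3", "H4", "DNA"):
            continue
        for h_res in partner.residues:
            for b_res in binder.residues:
                key = ((binder.chain_id, b_res.seq_id), (partner.chain_id, h_res.seq_id))
                d = _min_residue_dist(b_res, h_res)
                if key in planted:
                    if abs(d - planted[key]) > 1e-3:
                        raise ValueError(
                            f"infeasible geometry: planted distance {planted[key]} "
                            f"for {key} realized as {d:.4f}"
                        )
                elif (b_res.seq_id, key[1]) in patch_exempt:
                    continue
                elif d <= margin:
                    raise ValueError(
                        f"infeasible geometry: unplanned pair {key} at "
                        f"{d:.3f} Å (< cutoff + margin = {margin} Å)"
                    )
    for b_seq, (centroid, dist) in patch_targets.items():
        res = binder.get_residue(b_seq)
        realized = min(
            float(np.linalg.norm(a.coords - centroid)) for a in res.heavy_atoms()
        )
        if abs(realized - dist) > 1e-3:
            raise ValueError(
                f"infeasible geometry: patch distance {dist} for binder "
                f"residue {b_seq} realized as {realized:.4f}"
            )


def synth_confidence(model: PredictedModel, spec: FixtureSpec) -> ConfidenceBundle:
    """Confidence bundle with a flat 31.75 PAE / 50 pLDDT background and
    the spec's planted entries; also stamps pLDDT into atom B-factors."""
    residues = model.polymer_residues()
    token_map = {(r.chain_id, r.seq_id): i for i, r in enumerate(residues)}
    n = len(residues)
    pae = np.full((n, n), _DEFAULT_PAE)
    plddt = np.full(n, _DEFAULT_PLDDT)
    for (res_a, res_b, value) in spec.planted_pae:
        for key in (res_a, res_b):
            if key not in token_map:
                raise ValueError(f"planted PAE references unknown residue {key}")
        pae[token_map[res_a], token_map[res_b]] = value
    for (res, value) in spec.planted_plddt:
        if res not in token_map:
            raise ValueError(f"planted pLDDT references unknown residue {res}")
        plddt[token_map[res]] = value
    for res in residues:
        value = plddt[token_map[(res.chain_id, res.seq_id)]]
        res.plddt = float(value)
        for atom in res.atoms:
            atom.bfactor = float(value)
    return ConfidenceBundle(
        pae=pae, token_map=token_map, has_clash=spec.has_clash,
        plddt_by_token=plddt,
    )


def build_fixture(spec: FixtureSpec) -> tuple[PredictedModel, ConfidenceBundle]:
    """Generate the complete in-memory fixture (model + confidence)."""
    model = make_mini_nucleosome(spec)
    place_binder(model, spec)
    confidence = synth_confidence(model, spec)
    return model, confidence


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_model_cif(model: PredictedModel, path: str | Path) -> Path:
    """Write a model as mmCIF (via biotite), B-factors carrying pLDDT."""
    import biotite.structure as struc
    from biotite.structure.io.pdbx import CIFFile, set_structure

    n_atoms = sum(
        len(r.atoms) for c in model.chains for r in c.residues
    )
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("b_factor", float)
    arr.add_annotation("occupancy", float)
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            res_name = (
                _NT1TO3.get(res.aa_code)
                or _AA1TO3.get(res.aa_code, "UNK")
            )
            for atom in res.atoms:
                arr.chain_id[i] = chain.chain_id
                arr.res_id[i] = res.seq_id
                arr.res_name[i] = res_name
                arr.atom_name[i] = atom.name
                arr.element[i] = atom.element
                arr.hetero[i] = False
                arr.coord[i] = atom.coords
                arr.b_factor[i] = atom.bfactor
                arr.occupancy[i] = atom.occupancy
                i += 1
    cif = CIFFile()
    set_structure(cif, arr)
    path = Path(path)
    cif.write(str(path))
    return path


def write_confidence_json(
    model: PredictedModel, confidence: ConfidenceBundle, path: str | Path
) -> Path:
    """Write the flat confidence dialect (pae + has_clash + explicit
    token arrays + per-token plddt)."""
    order = sorted(confidence.token_map, key=confidence.token_map.get)
    payload = {
        "pae": np.round(confidence.pae, 6).tolist(),
        "has_clash": bool(confidence.has_clash),
        "token_chain_ids": [c for c, _ in order],
        "token_res_ids": [int(r) for _, r in order],
        "plddt": np.round(confidence.plddt_by_token, 6).tolist(),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def write_fixture_files(
    spec: FixtureSpec, outdir: str | Path, name: str = "fixture"
) -> dict[str, Path]:
    """Write model mmCIF, confidence JSON and a manifest TSV of all
    planted truths; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, confidence = build_fixture(spec)
    model_path = write_model_cif(model, outdir / f"{name}.cif")
    conf_path = write_confidence_json(model, confidence, outdir / f"{name}_confidence.json")
    rows = []
    for (b, h, d) in spec.planted_contacts:
        rows.append({"kind": "contact", "a": f"{b[0]}:{b[1]}", "b": f"{h[0]}:{h[1]}", "value": d})
    for (b, h, d) in spec.clash_pairs:
        rows.append({"kind": "clash", "a": f"{b[0]}:{b[1]}", "b": f"{h[0]}:{h[1]}", "value": d})
    for (b_seq, d) in spec.planted_patch_residues:
        rows.append({"kind": "patch", "a": f"K:{b_seq}", "b": "centroid", "value": d})
    for (ra, rb, v) in spec.planted_pae:
        rows.append({"kind": "pae", "a": f"{ra[0]}:{ra[1]}", "b": f"{rb[0]}:{rb[1]}", "value": v})
    for (r, v) in spec.planted_plddt:
        rows.append({"kind": "plddt", "a": f"{r[0]}:{r[1]}", "b": "", "value": v})
    manifest = pd.DataFrame(rows, columns=["kind", "a", "b", "value"])
    manifest_path = outdir / f"{name}_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return {"model": model_path, "confidence": conf_path, "manifest": manifest_path}
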