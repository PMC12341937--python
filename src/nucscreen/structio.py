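"""Structure and confidence input layer.

Reads predicted binder-nucleosome complexes (PDB / mmCIF) into a uniform
in-memory representation, reads the matching AlphaFold-style confidence
files (PAE matrix, pLDDT, clash flag), and assigns biological roles to
chains (H2A / H2B / H3 / H4 / DNA / BINDER) by sequence identity against
shipped human histone references.

Conventions
-----------
* Author residue numbering (1-based) is used everywhere; mmCIF label_seq
  is ignored.
* Amino-acid residues carry upper-case one-letter codes, nucleotides
  lower-case one-letter codes.
* Per-residue pLDDT is taken from the B-factor of the CA atom (C1' for
  nucleotides), falling back to the mean atom B-factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainRecord",
    "PredictedModel",
    "ConfidenceBundle",
    "HISTONE_REFERENCES",
    "HISTONE_ROLES",
    "read_structure",
    "read_confidence",
    "classify_chains",
    "sequence_identity",
    "align_to_reference",
]

HISTONE_ROLES = ("H2A", "H2B", "H3", "H4")

# Canonical human histone sequences (initiator Met = residue 1).  The H2A
# entry follows the type 2-C numbering in which the acidic patch is formed
# by E57, E62, E65, D91, E92 and E93.
_H2A_FULL = (
    "MSGRGKQGGKARAKAKSRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLT"
    "AEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKK"
    "TESHHKAKGK"
)
_H2B_FULL = (
    "MPEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAM"
    "GIMNSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVT"
    "KYTSSK"
)
_H3_FULL = (
    "MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTE"
    "LLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEASEAYLVGLFEDTNLCAIHAKRVTI"
    "MPKDIQLARRIRGERA"
)
_H4_FULL = (
    "MSGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLK"
    "VFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
)

#: Full-length reference sequences keyed by histone role.
HISTONE_REFERENCES: dict[str, str] = {
    "H2A": _H2A_FULL,
    "H2B": _H2B_FULL,
    "H3": _H3_FULL,
    "H4": _H4_FULL,
}

#: Tailless construct ranges (author numbering, inclusive) used for the
#: nucleosome prediction template.
HISTONE_CONSTRUCT_RANGES: dict[str, tuple[int, int]] = {
    "H2A": (12, 119),
    "H2B": (32, 125),
    "H3": (39, 134),
    "H4": (21, 103),
}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}
_NT3TO1 = {
    "DA": "a", "DC": "c", "DG": "g", "DT": "t", "DU": "u",
    "A": "a", "C": "c", "G": "g", "U": "u", "T": "t",
}
_NT_CODES = frozenset("acgtu")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """A single heavy atom; ``bfactor`` carries pLDDT in predicted models."""

    element: str
    name: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.bfactor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_id: int
    aa_code: str
    atoms: list[AtomRecord] = field(default_factory=list)
    plddt: float = 0.0

    @property
    def is_nucleotide(self) -> bool:
        return self.aa_code in _NT_CODES

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def representative_atom(self) -> AtomRecord | None:
        """CA for amino acids, C1' for nucleotides, else None."""
        return self.get_atom("C1'" if self.is_nucleotide else "CA")


@dataclass
class ChainRecord:
    chain_id: str
    role: str = "UNKNOWN"
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)

    @property
    def is_nucleic(self) -> bool:
        res = self.residues
        if not res:
            return False
        n_nt = sum(r.is_nucleotide for r in res)
        return n_nt / len(res) >= 0.8

    def get_residue(self, seq_id: int) -> ResidueRecord | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None


@dataclass
class PredictedModel:
    """One structural model (one of the five AF3 modes for a protein)."""

    model_id: str
    chains: list[ChainRecord] = field(default_factory=list)
    source_path: str | None = None

    def get_chain(self, chain_id: str) -> ChainRecord | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def chains_with_role(self, role: str) -> list[ChainRecord]:
        return [c for c in self.chains if c.role == role]

    @property
    def binder_chain(self) -> ChainRecord:
        binders = self.chains_with_role("BINDER")
        if len(binders) != 1:
            roles = {c.chain_id: c.role for c in self.chains}
            raise ValueError(
                f"model {self.model_id}: expected exactly one BINDER chain, "
                f"got {len(binders)} (roles: {roles})"
            )
        return binders[0]

    @property
    def histone_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.role in HISTONE_ROLES]

    def polymer_residues(self) -> list[ResidueRecord]:
        """All residues in chain order — the confidence token order."""
        return [r for c in self.chains for r in c.residues]


@dataclass
class ConfidenceBundle:
    """Token-level PAE matrix, clash flag and per-token pLDDT for one model."""

    pae: np.ndarray
    token_map: dict[tuple[str, int], int]
    has_clash: bool
    plddt_by_token: np.ndarray

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ValueError(f"PAE matrix must be square, got {self.pae.shape}")
        if len(self.token_map) != self.pae.shape[0]:
            raise ValueError(
                f"token_map has {len(self.token_map)} entries but PAE is "
                f"{self.pae.shape[0]}x{self.pae.shape[1]}"
            )
        if np.any(self.pae < 0):
            raise ValueError("PAE entries must be >= 0")

    def token_of(self, chain_id: str, seq_id: int) -> int:
        try:
            return self.token_map[(chain_id, seq_id)]
        except KeyError:
            raise KeyError(
                f"residue {chain_id}:{seq_id} not present in confidence token map"
            ) from None

    def pae_between(self, res_a: tuple[str, int], res_b: tuple[str, int]) -> float:
        return float(self.pae[self.token_of(*res_a), self.token_of(*res_b)])

    def plddt_of(self, chain_id: str, seq_id: int) -> float:
        return float(self.plddt_by_token[self.token_of(chain_id, seq_id)])


# ---------------------------------------------------------------------------
# Structure reading
# ---------------------------------------------------------------------------

def _one_letter(res_name: str) -> str:
    res_name = res_name.strip().upper()
    if res_name in _AA3TO1:
        return _AA3TO1[res_name]
    if res_name in _NT3TO1:
        return _NT3TO1[res_name]
    return "X"


def read_structure(path: str | Path, format: str = "auto") -> PredictedModel:
    """Read a PDB or mmCIF file into a :class:`PredictedModel`.

    All heavy atoms are loaded; hydrogens are dropped.  Per-residue pLDDT
    is populated from the B-factor of the representative atom (CA, or C1'
    for nucleotides), falling back to the mean atom B-factor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "auto":
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"

    try:
        if format == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_structure

            cif = CIFFile.read(str(path))
            atoms = get_structure(
                cif, model=1, extra_fields=["b_factor", "occupancy"]
            )
        elif format == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(
                model=1, extra_fields=["b_factor", "occupancy"]
            )
        else:
            raise ValueError(f"unknown structure format: {format!r}")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        if isinstance(exc, ValueError) and "unknown structure format" in str(exc):
            raise
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc

    if atoms.array_length() == 0:
        raise ValueError(f"{path}: structure contains no atoms")

    model = PredictedModel(model_id=path.stem, source_path=str(path))
    chain: ChainRecord | None = None
    residue: ResidueRecord | None = None
    for i in range(atoms.array_length()):
        element = str(atoms.element[i])
        if element.upper() in ("H", "D"):
            continue
        cid = str(atoms.chain_id[i])
        rid = int(atoms.res_id[i])
        if chain is None or chain.chain_id != cid:
            chain = ChainRecord(chain_id=cid)
            model.chains.append(chain)
            residue = None
        if residue is None or residue.seq_id != rid:
            residue = ResidueRecord(
                chain_id=cid, seq_id=rid, aa_code=_one_letter(str(atoms.res_name[i]))
            )
            chain.residues.append(residue)
        residue.atoms.append(
            AtomRecord(
                element=element,
                name=str(atoms.atom_name[i]),
                coords=np.array(atoms.coord[i], dtype=float),
                occupancy=float(atoms.occupancy[i]),
                bfactor=float(atoms.b_factor[i]),
            )
        )

    for ch in model.chains:
        seq_ids = [r.seq_id for r in ch.residues]
        if any(b <= a for a, b in zip(seq_ids, seq_ids[1:])):
            raise ValueError(
                f"{path}: chain {ch.chain_id} residue numbering is not "
                "strictly increasing"
            )
        for res in ch.residues:
            rep = res.representative_atom()
            if rep is not None:
                res.plddt = rep.bfactor
            elif res.atoms:
                res.plddt = float(np.mean([a.bfactor for a in res.atoms]))
    return model


# ---------------------------------------------------------------------------
# Confidence reading
# ---------------------------------------------------------------------------

def read_confidence(path: str | Path, model: PredictedModel) -> ConfidenceBundle:
    """Read an AF3-server style confidence JSON for ``model``.

    Two dialects are accepted:

    * server style — an object with a square ``"pae"`` array and a boolean
      ``"has_clash"``; tokens are taken in model residue order (one token
      per standard residue / nucleotide).
    * flat fixture dialect — additionally carries explicit
      ``"token_chain_ids"`` / ``"token_res_ids"`` arrays and a per-token
      ``"plddt"`` vector.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if "pae" not in data:
        raise ValueError(f"{path}: confidence file lacks a 'pae' array")
    pae = np.asarray(data["pae"], dtype=float)
    has_clash = bool(data.get("has_clash", False))

    residues = model.polymer_residues()
    n_tokens = pae.shape[0] if pae.ndim == 2 else 0
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError(f"{path}: PAE array is not square ({pae.shape})")
    if n_tokens != len(residues):
        raise ValueError(
            f"{path}: PAE has {n_tokens} tokens but the model has "
            f"{len(residues)} polymer residues"
        )

    if "token_chain_ids" in data and "token_res_ids" in data:
        keys = list(zip(data["token_chain_ids"], data["token_res_ids"]))
        token_map = {(str(c), int(r)): i for i, (c, r) in enumerate(keys)}
    else:
        token_map = {(r.chain_id, r.seq_id): i for i, r in enumerate(residues)}
    if len(token_map) != n_tokens:
        raise ValueError(f"{path}: token map is not a bijection onto tokens")

    if "plddt" in data:
        plddt = np.asarray(data["plddt"], dtype=float)
        if plddt.shape != (n_tokens,):
            raise ValueError(
                f"{path}: plddt vector length {plddt.shape} != {n_tokens} tokens"
            )
    else:
        plddt = np.empty(n_tokens)
        for res in residues:
            plddt[token_map[(res.chain_id, res.seq_id)]] = res.plddt
    return ConfidenceBundle(
        pae=pae, token_map=token_map, has_clash=has_clash, plddt_by_token=plddt
    )


# ---------------------------------------------------------------------------
# Chain classification
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(query: str, reference: str) -> float:
    """Fraction of identical aligned positions, normalized by the shorter
    sequence length (so an exact substring scores 1.0)."""
    if not query or not reference:
        return 0.0
    aligner = _make_aligner()
    aln = aligner.align(query.upper(), reference.upper())[0]
    identical = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        identical += sum(
            q == r for q, r in zip(query.upper()[qs:qe], reference.upper()[rs:re_])
        )
    return identical / min(len(query), len(reference))


def align_to_reference(query: str, reference: str) -> dict[int, int]:
    """Map 1-based reference positions to 1-based query positions via a
    pairwise local alignment (gaps excluded)."""
    aligner = _make_aligner()
    aln = aligner.align(query.upper(), reference.upper())[0]
    mapping: dict[int, int] = {}
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for offset in range(qe - qs):
            mapping[rs + offset + 1] = qs + offset + 1
    return mapping


def classify_chains(
    model: PredictedModel,
    references: Mapping[str, str] | None = None,
    identity_threshold: float = 0.8,
) -> PredictedModel:
    """Assign a role to every chain of ``model`` in place (and return it).

    Nucleotide chains become DNA.  A protein chain matching one of the
    histone references at >= ``identity_threshold`` identity over the
    aligned region takes that histone's role (highest identity wins);
    anything below the threshold is the candidate BINDER.  Exactly one
    BINDER chain must remain, otherwise a ``ValueError`` is raised.
    """
    refs = dict(references) if references is not None else dict(HISTONE_REFERENCES)
    for chain in model.chains:
        if chain.is_nucleic:
            chain.role = "DNA"
            continue
        best_role, best_ident = "BINDER", 0.0
        for role, ref_seq in refs.items():
            ident = sequence_identity(chain.sequence, ref_seq)
            if ident > best_ident:
                best_role, best_ident = role, ident
        chain.role = best_role if best_ident >= identity_threshold else "BINDER"
    binders = model.chains_with_role("BINDER")
    if len(binders) != 1:
        roles = {c.chain_id: c.role for c in model.chains}
        raise ValueError(
            f"model {model.model_id}: classification produced {len(binders)} "
            f"BINDER chains, expected exactly 1 (roles: {roles})"
        )
    return model
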