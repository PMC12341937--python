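import numpy as np
import pytest

from nucscreen.fixtures import FixtureSpec, build_fixture
from nucscreen.structio import AtomRecord, ChainRecord, PredictedModel, ResidueRecord


def make_spec_with_contacts(seed: int, n_contacts: int = 4) -> FixtureSpec:
    """A fixture spec with `n_contacts` planted binder-histone contacts at
    seeded random distances, on histone residues spaced widely apart."""
    rng = np.random.default_rng(seed)
    histone_chains = ["A", "B", "C", "D", "E", "F", "G", "H"]
    starts = {"A": 50, "B": 50, "C": 32, "D": 32, "E": 39, "F": 39, "G": 21, "H": 21}
    contacts, pae, plddt = [], [], []
    chains = rng.choice(histone_chains, size=n_contacts, replace=False)
    for k, chain in enumerate(chains):
        h_seq = int(starts[chain] + 5 + 8 * rng.integers(0, 5))
        b_seq = k + 1
        dist = float(np.round(rng.uniform(2.0, 4.9), 3))
        contacts.append(((("K"), b_seq), ((chain), h_seq), dist))
        pae.append(((("K"), b_seq), ((chain), h_seq), float(rng.uniform(0, 31.75))))
        pae.append(((chain, h_seq), ("K", b_seq), float(rng.uniform(0, 31.75))))
        plddt.append((("K", b_seq), float(rng.uniform(30, 100))))
        plddt.append(((chain, h_seq), float(rng.uniform(30, 100))))
    return FixtureSpec(
        seed=seed,
        planted_contacts=contacts,
        planted_pae=pae,
        planted_plddt=plddt,
    )


@pytest.fixture(scope="session")
def default_fixture():
    spec = make_spec_with_contacts(seed=11, n_contacts=4)
    model, confidence = build_fixture(spec)
    return spec, model, confidence


def tiny_two_chain_model(distance: float) -> PredictedModel:
    """A minimal classified model: one binder atom and one H2A atom at the
    given separation."""
    h2a = ChainRecord(
        chain_id="A",
        role="H2A",
        residues=[
            ResidueRecord(
                "A", 61, "E",
                atoms=[AtomRecord("C", "CA", np.zeros(3), 1.0, 50.0)],
            )
        ],
    )
    binder = ChainRecord(
        chain_id="K",
        role="BINDER",
        residues=[
            ResidueRecord(
                "K", 1, "R",
                atoms=[AtomRecord("C", "CA", np.array([distance, 0.0, 0.0]), 1.0, 50.0)],
            )
        ],
    )
    return PredictedModel(model_id="tiny", chains=[h2a, binder])


def brute_force_contacts(model, cutoff):
    """Independent O(n^2) all-pairs contact oracle."""
    binder = model.binder_chain
    pairs = []
    for chain in model.chains:
        if chain.role not in ("H2A", "H2B", "H3", "H4"):
            continue
        for h_res in chain.residues:
            for h_atom in h_res.heavy_atoms():
                for b_res in binder.residues:
                    for b_atom in b_res.heavy_atoms():
                        d = float(np.linalg.norm(b_atom.coords - h_atom.coords))
                        if d <= cutoff:
                            pairs.append(
                                (
                                    (binder.chain_id, b_res.seq_id, b_atom.name),
                                    (chain.chain_id, h_res.seq_id, h_atom.name),
                                    round(d, 9),
                                )
                            )
    return sorted(pairs)


def rigid_transform_model(model, seed=0):
    """Apply a seeded random rotation + translation to every atom (copy)."""
    import copy

    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    moved = copy.deepcopy(model)
    for chain in moved.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = R @ atom.coords + t
    return moved
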