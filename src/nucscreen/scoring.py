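"""Strength-factor (SF) scoring, ranking and knee detection.

The SF of a predicted binder-nucleosome model is the sum, over deduplicated
binder-histone residue contact pairs, of a confidence weight built from the
AlphaFold error estimates: the PAE between the two residues is flipped into
an agreement index p_a = 31.75 - rawPAE (31.75 being the maximum raw PAE
the server emits) and multiplied with the local-confidence index
p_l = rawpLDDT; the directional products are averaged over both residue
orderings.  The raw SF is divided by B, the raw SF of a designated
reference complex (the BARD1-nucleosome complex in the original screen),
giving a score of 1.0 for the reference itself.

Proteins are ranked by the best SF over their five predicted models, and
the elbow of the ranked score curve is located with the Kneedle algorithm
(min-max normalization, maximum distance to the chord joining the curve
endpoints, sensitivity 1, no smoothing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .contacts import ContactPair, ContactSet
from .structio import ConfidenceBundle

__all__ = [
    "ScoringParams",
    "ContactWeight",
    "SFResult",
    "NormalizationReference",
    "RankEntry",
    "pair_weight",
    "sf_raw",
    "normalize",
    "score_model",
    "best_of_models",
    "rank_proteins",
    "kneedle_top",
]

logger = logging.getLogger("nucscreen")

#: Maximum raw PAE in AF3 server output; anchors the PAE->agreement flip.
DEFAULT_PAE_MAX = 31.75


@dataclass(frozen=True)
class ScoringParams:
    contact_cutoff: float = 5.0
    pae_max: float = DEFAULT_PAE_MAX
    clamp_negative: bool = True
    plddt_scale: float = 100.0
    weight_mode: str = "directional_mean"  # or "component_mean"
    clash_dist: float = 1.2
    clash_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        if self.pae_max <= 0:
            raise ValueError("pae_max must be > 0")
        if self.weight_mode not in ("directional_mean", "component_mean"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass(frozen=True)
class ContactWeight:
    pair: ContactPair
    p_a: float
    p_l: float
    weight: float


@dataclass
class SFResult:
    model_id: str
    weights: list[ContactWeight] = field(default_factory=list)
    sf_raw: float = 0.0
    sf: float = float("nan")
    excluded_by_clash: bool = False

    @property
    def n_contacts(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class NormalizationReference:
    B: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"normalization constant B must be > 0, got {self.B}")


@dataclass
class RankEntry:
    protein_id: str
    sf_best: float
    model_of_best: str
    rank: int = 0


def _transform_pae(raw_pae: float, params: ScoringParams) -> float:
    value = params.pae_max - raw_pae
    if params.clamp_negative:
        value = max(0.0, value)
    return value


def pair_weight(
    pair: ContactPair, confidence: ConfidenceBundle, params: ScoringParams
) -> ContactWeight:
    """Confidence weight of one contact pair.

    ``directional_mean`` (default) averages the two directional products
    (pae_max - pae(a,b)) * plddt(a) over the orderings (i,j) and (j,i);
    ``component_mean`` averages the PAE transform and the pLDDT first and
    multiplies the averages.  p_a and p_l are always recorded as the
    direction-averaged components.
    """
    i, j = pair.binder_res, pair.histone_res
    pae_ij = confidence.pae_between(i, j)
    pae_ji = confidence.pae_between(j, i)
    plddt_i = confidence.plddt_of(*i)
    plddt_j = confidence.plddt_of(*j)
    t_ij = _transform_pae(pae_ij, params)
    t_ji = _transform_pae(pae_ji, params)
    p_a = 0.5 * (t_ij + t_ji)
    p_l = 0.5 * (plddt_i + plddt_j)
    if params.weight_mode == "directional_mean":
        weight = 0.5 * (t_ij * plddt_i + t_ji * plddt_j)
    else:
        weight = p_a * p_l
    return ContactWeight(pair=pair, p_a=p_a, p_l=p_l, weight=weight)


def sf_raw(
    contacts: ContactSet, confidence: ConfidenceBundle, params: ScoringParams
) -> SFResult:
    """Sum of contact-pair weights — the unnormalized strength factor."""
    weights = [pair_weight(p, confidence, params) for p in contacts.pairs]
    total = float(sum(w.weight for w in weights))
    return SFResult(model_id=contacts.model_id, weights=weights, sf_raw=total)


def normalize(result: SFResult, ref: NormalizationReference) -> SFResult:
    """Divide the raw SF by the reference constant B."""
    result.sf = result.sf_raw / ref.B
    return result


def score_model(
    model,
    confidence: ConfidenceBundle,
    params: ScoringParams | None = None,
    ref: NormalizationReference | None = None,
) -> SFResult:
    """Clash-filter, contact-detect and score one model end to end.

    Models excluded by the clash screen carry sf_raw = 0 (sf = 0 after
    normalization) and the exclusion flag.
    """
    from .contacts import detect_clashes, dedupe_to_residue_pairs, find_atom_contacts

    params = params or ScoringParams()
    clash = detect_clashes(
        model, confidence, clash_dist=params.clash_dist,
        tolerance=params.clash_tolerance,
    )
    if clash.excluded:
        result = SFResult(model_id=model.model_id, excluded_by_clash=True)
    else:
        atom_contacts = find_atom_contacts(model, cutoff=params.contact_cutoff)
        contacts = dedupe_to_residue_pairs(atom_contacts, model_id=model.model_id)
        result = sf_raw(contacts, confidence, params)
    if ref is not None:
        normalize(result, ref)
    logger.info(
        "model %s: n_contacts=%d sf_raw=%.4f sf=%s excluded=%s",
        model.model_id, result.n_contacts, result.sf_raw,
        f"{result.sf:.6f}" if result.sf == result.sf else "NA",
        result.excluded_by_clash,
    )
    return result


def _effective_sf(res: SFResult) -> float:
    if res.excluded_by_clash:
        return 0.0
    return res.sf_raw if np.isnan(res.sf) else res.sf


def best_of_models(results: Sequence[SFResult], protein_id: str = "") -> RankEntry:
    """Best (maximum) SF over a protein's models; excluded models count
    as 0; ties keep the first model in input order."""
    if not results:
        raise ValueError("best_of_models requires at least one model result")
    best, best_sf = results[0], _effective_sf(results[0])
    for res in results[1:]:
        sf = _effective_sf(res)
        if sf > best_sf:
            best, best_sf = res, sf
    return RankEntry(
        protein_id=protein_id, sf_best=float(best_sf), model_of_best=best.model_id
    )


def rank_proteins(entries: Iterable[RankEntry]) -> list[RankEntry]:
    """Stable descending sort by sf_best; ties keep input order; ranks
    are assigned 1..N."""
    ranked = sorted(entries, key=lambda e: -e.sf_best)
    return [
        RankEntry(e.protein_id, e.sf_best, e.model_of_best, rank=i + 1)
        for i, e in enumerate(ranked)
    ]


def screen_bookkeeping(
    n_nuclear: int = 7655,
    n_over_hard_limit: int = 2,
    n_split: int = 25,
    n_segments_per_split: int = 2,
    n_models: int = 5,
) -> dict[str, int]:
    """Prediction-count arithmetic of the proteome-scale screen.

    Of the nuclear proteins, those above the hard length limit are dropped,
    the over-long remainder are split into segments, and every prediction
    job yields ``n_models`` structural modes.
    """
    n_processed = n_nuclear - n_over_hard_limit
    n_unsplit = n_processed - n_split
    split_predictions = n_split * n_segments_per_split * n_models
    unsplit_predictions = n_unsplit * n_models
    return {
        "proteins_processed": n_processed,
        "proteins_unsplit": n_unsplit,
        "split_predictions": split_predictions,
        "unsplit_predictions": unsplit_predictions,
        "total_predictions": split_predictions + unsplit_predictions,
    }


def kneedle_top(
    sorted_scores: Sequence[float], tol: float = 1e-9
) -> int | None:
    """Knee index of a non-increasing score curve (classic Kneedle).

    Both axes are min-max normalized and the index with maximal
    perpendicular distance from the chord joining the curve endpoints is
    returned.  Returns ``None`` when the curve has no knee (constant or
    linear within ``tol``).
    """
    y = np.asarray(sorted_scores, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("kneedle_top requires at least 3 scores")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("scores must be non-increasing")
    y_range = y.max() - y.min()
    if y_range <= tol:
        return None
    x_norm = np.arange(n) / (n - 1)
    y_norm = (y - y.min()) / y_range
    # chord joins (0, 1) and (1, 0): x + y - 1 = 0
    dist = np.abs(x_norm + y_norm - 1.0) / np.sqrt(2.0)
    knee = int(np.argmax(dist))
    if dist[knee] <= tol:
        return None
    return knee
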