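# Methods

## Scope and model of the data

`nucscreen` operates downstream of a structure predictor. Its unit of input
is one predicted complex — a binder chain folded together with a tailless
nucleosome (two copies each of H2A, H2B, H3, H4 and two DNA strands) — plus
the predictor's confidence output: a token-level PAE matrix, per-residue
pLDDT (carried in the B-factor column of the model) and a boolean clash
flag. One confidence token corresponds to one standard amino acid or
nucleotide; ligands and modified residues are unsupported. Author residue
numbering (1-based) is the coordinate convention throughout; mmCIF
`label_seq` is ignored.

Chain roles are not trusted from the file. Protein chains are assigned a
histone role when a local alignment against the shipped human reference
sequence reaches ≥ 80 % identity (identical aligned positions normalized by
the shorter sequence length, so exact substrings of a reference score 1.0);
the highest-identity reference wins, nucleotide chains become DNA, and the
single remaining protein chain is the binder. The identity normalization is
deliberately coverage-aware: a local alignment alone would let a short
accidental match masquerade as a histone. Classification is idempotent and
fails loudly if zero or several binder chains remain.

## Strength factor

Contacts are heavy-atom pairs (binder atom, histone-chain atom) within the
contact cutoff (default 5 Å, compared with ≤). DNA chains never contribute
contacts, but do participate in clash detection. Atom pairs are
deduplicated to residue pairs because PAE and pLDDT are residue-level
quantities; the minimum atom distance per pair is retained for reporting.
A KD-tree accelerates the search, with the contract that results equal the
brute-force all-pairs scan exactly (tested against an independent O(n²)
oracle).

Each contact pair (i, j) is weighted from the two confidence indices:

```
w(i,j) = ½ [ max(0, 31.75 − PAE(i,j)) · pLDDT(i)
           + max(0, 31.75 − PAE(j,i)) · pLDDT(j) ]
```

31.75 is the maximum raw PAE emitted by the AF3 server, so the transform
maps "worst possible" to 0 and aligns the trend with pLDDT. The raw SF is
the sum of weights; the normalized SF divides by B, the raw SF of a
user-designated reference complex scored with identical parameters (never a
hard-coded constant, since B is data-dependent). Parameters worth knowing:

| parameter | default | meaning |
|---|---|---|
| `contact_cutoff` | 5.0 Å | heavy-atom contact distance |
| `pae_max` | 31.75 | PAE→agreement anchor |
| `clamp_negative` | true | PAE above `pae_max` contributes 0, never negative |
| `weight_mode` | `directional_mean` | see below |
| `clash_dist` / `clash_tolerance` | 1.2 Å / 0 | geometric exclusion rule |

Two readings of "the product of the indices is averaged" are possible:
averaging the directional products (default, above) or averaging the two
PAE transforms and the two pLDDTs first and multiplying the averages
(`weight_mode="component_mean"`). They differ only in cross terms and obey
the same invariants; both are exposed so the choice is explicit rather than
silent.

Models are excluded before scoring when the predictor's clash flag is set
or when any binder↔histone/DNA heavy-atom pair is closer than 1.2 Å
(a hard-sphere violation threshold; the exclusion rule is configurable).
Excluded models carry SF 0 so they participate in per-protein maxima
without distorting them.

Per-protein scores take the maximum over the protein's (typically five)
models; ties keep input order, and the pipeline sorts protein IDs
lexicographically first so outputs are byte-reproducible. The top-hit cut
uses Kneedle with sensitivity 1 and no smoothing: both axes are min–max
normalized and the knee is the index with maximal perpendicular distance
from the chord joining the endpoints; a constant or linear curve (max
distance ≤ 1e-9) has no knee.

## Acidic-patch analyses

The patch definition lives in reference H2A coordinates (E57, E62, E65,
D91, E92, E93; AP1 = {62, 91, 93}, AP2 = {62, 91, 65}) and is mapped onto
each H2A copy by pairwise alignment, so truncated constructs and arbitrary
author numbering work. The pocket centroid is the unweighted mean of all
heavy atoms of the AP1 ∪ AP2 residues (the definition names residues, not
atoms, so no atom subset is privileged). Both nucleosome faces are
evaluated; the face with more binder residues within 5 Å of its centroid is
reported, ties going to the first H2A chain.

Prediction consistency across a protein's five models: each model pair is
rigidly superposed over shared histone Cα atoms (Kabsch; models from the
same job otherwise sit in arbitrary frames), then the RMSD is taken over
Cα atoms of the intersection of the two models' patch-contacting binder
residues. Pairs with an empty intersection are omitted and flagged; RMSDs
below 1e-8 Å are snapped to exactly 0 (Kabsch round-off on identical
conformations). The per-protein summary is the mode of the ≤ 10 pairwise
RMSDs, estimated as the centre of the most populated 0.1 Å histogram bin
(ties to the lowest bin), except that a degenerate winning bin — all its
values identical, e.g. the all-zero RMSDs of perfectly reproduced models —
returns the exact value. That exception is what makes the consistency
score, `1 − mode / cohort max` clipped to [0, 1], exactly 1 for five
identical models.

Motif windows: one 21-character window per binder Arg/Lys that contacts an
AP1/AP2 residue, centred on the anchor and '-'-padded at chain termini so
column registration is preserved for downstream logo building. Benchmark
calls compare predicted and experimental complexes as sets of
(binder residue, patch reference position) pairs — a numbering-independent
frame — by Jaccard overlap, positive at ≥ 0.3 by default ("well aligned" is
qualitative; the threshold is configurable and the call is symmetric in its
arguments). Two empty sets yield an undefined, flagged negative. When a
binder has several patch-binding segments, the representative is the
longest; exact length ties are broken by a seeded uniform draw (default
seed 985866441, recorded in output) so reruns are reproducible.

## Synthetic fixtures: what they do and do not establish

The generator emulates only what the method consumes: distances and
confidences. Chains are ideal Cα traces (3.8 Å spacing) on lines separated
by 60 Å; histone chains embed exact substrings of the reference sequences
(so classification exercises the real alignment path); each H2A copy's
patch residues are clustered at an off-chain pocket site so a centroid
exists away from everything else. A planted contact lifts its histone
residue off the chain line and parks the binder residue directly above at
the requested distance, making that distance the exact minimum inter-residue
heavy-atom separation; the lift height guarantees that chain neighbours
stay beyond cutoff + 1 Å. Every placement is verified by a brute-force
distance scan and infeasible requests (e.g. planted contacts on adjacent
histone residues) raise instead of silently degrading. Confidence files
default to the maximally uninformative background (PAE 31.75 everywhere,
pLDDT 50) so only planted entries carry weight.

Consequently a green test establishes that the pipeline recovers planted
geometric and confidence truth exactly — not that the SF discriminates real
binders, which depends on the predictor's error structure that these
fixtures deliberately do not model (no realistic PAE correlations, no DNA
geometry, no side chains).

Default fixture dimensions (51 residues per histone chain — enough for the
complete H2A patch span — 25-residue binder, 20-nt DNA strands) keep a full
model under 500 residues so brute-force oracles stay fast.

## Numerical choices and edge cases

* Contact test uses ≤ cutoff; clash test uses < threshold.
* Negative transformed PAE (raw PAE > 31.75) clamps to 0 by default so
  worse-than-max error cannot subtract signal.
* Weight/SF equality tests run at 1e-9 relative; coordinates round-trip
  through mmCIF at 1e-3 Å (file precision).
* `kneedle_top` rejects lists shorter than 3 and non-monotone input.
* Empty contact sets score 0; an all-excluded protein ranks with SF 0
  rather than being dropped; per-protein failures in batch runs are
  tabulated and never abort the cohort.
* Benchmark and consistency cohort maxima are computed over the run at
  hand, so scores are comparable only within one cohort.

## Known limitations

* Only single-binder assemblies are supported; multi-binder complexes and
  ligands are out of scope.
* Histone-role assignment assumes the shipped references cover the variants
  in use; exotic histone variants below 80 % identity would be misread as
  binder candidates (and then rejected for multiplicity).
* The consistency estimate may differ from one computed without
  histone-frame superposition if upstream models were already aligned.
* Fixture geometry is non-physical by design; it validates bookkeeping and
  arithmetic, not biological plausibility.
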