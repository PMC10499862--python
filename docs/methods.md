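# Methods

## The regression problem

A protein is an ordered list of Cα sites, chains concatenated in file
order.  The target is the per-residue B factor, predicted in one of two
modes: **normalized** (the default) regresses the per-protein Z-score
B̂ᵢ = (Bᵢ − μ_B)/σ_B, where μ_B and σ_B are the mean and *population*
standard deviation (divisor N) over the protein's own residues;
**unnormalized** regresses raw Å² values, internally divided by 80 (the
curation ceiling) purely to condition the optimization and rescaled on
output.  The evaluation metric — Pearson correlation per protein, averaged
unweighted over proteins — is invariant under positive affine maps, so the
two modes are directly comparable.  The same single architecture serves
both modes.

Coordinates entering the feature vector are Z-scored per protein and per
axis.  This scaling is anisotropic: it does not exactly preserve relative
distances unless the three axis SDs coincide, and nothing in the package
assumes that it does.  All Euclidean distances used by the analyses
(cutoff masking, n̂, contact counts) are computed on raw Å coordinates.

## Curation

Four filters, all evaluated on Cα B factors: any value > 80 Å² (extreme
values indicate experimental error), any value ≤ 0 (unphysical), all
values exactly identical (placeholder deposits; exact equality is the
right test because the PDB field is quantized to 2 decimals), and chain
length > 500 residues (keeps training cost bounded).  Every violated rule
is reported, not just the first.  Altlocs resolve to the first-listed
conformer, only MODEL 1 of multi-model files is read, HETATM records are
ignored, and insertion-coded or non-standard residues are kept (the
encoder's catch-all slot absorbs their identity).  These file-handling
choices are this package's own; they are deliberately conservative.

## Secondary structure

Three classes (helix, sheet, coil) assigned from Cα geometry alone via the
P-SEA distance/angle-window algorithm (biotite's implementation), applied
per chain; chains of ≤ 5 residues are coil.  A Cα-only assigner is used —
rather than a full-backbone method — because the model consumes only Cα
traces and the synthetic chains have no other atoms.  The assignment is
deterministic and invariant under rigid-body motion.

## Architecture and training

Encoder and decoder are fully connected ReLU stacks applied independently
at each position; between them an optional multi-layer bidirectional LSTM
carries information along the whole chain in both directions, so the
prediction at residue i may depend on every other residue.  The parameter
count is independent of sequence length.  The network, backpropagation
through time, and Adam are implemented in NumPy (float64): the package
needs exact control over determinism, masking, and gradient checks, and
the implementation is small.  Gate order is (input, forget, cell, output);
weights initialize uniform ±1/√fan-in from a seeded generator, so a
(config, seed) pair reproduces parameters bit for bit.

Variable-length batches are padded at the tail and padded positions are
excluded from loss and gradient; the reverse LSTM direction reverses each
sequence *within its own length*, so predictions are provably independent
of batch composition (tested).  The loss is the per-protein MSE averaged
over the batch's proteins — each protein counts equally, matching the
protein-weighted evaluation.  Early stopping monitors validation MSE with
a patience window; the returned weights are those of the epoch with the
lowest validation loss, earliest epoch on ties.  Defaults (Adam, lr 1e-3,
batch 32, patience 20, max 300 epochs) live in `TrainConfig`; the
reference architecture default (encoder 64→128, two bidirectional layers
of hidden 256, decoder 128→1) is a configuration value only — every
operation takes the architecture from `ModelConfig`, and the desk-scale
studies use a smaller one (below).

A multi-seed protocol (`seed_robustness`) retrains over a list of seeds
and reports the spread of held-out average PCC, the standard robustness
check for this family of models.

## Interpretability probes

**Window sweep.**  The prediction at residue i is recomputed from the
contiguous window of sequence span Ws centered on i (⌈Ws/2⌉ left, ⌊Ws/2⌋
right).  Near a terminus the window slides inward so it keeps min(Ws+1, N)
rows; consequently a span of N−1 or more reproduces the full-sequence
prediction exactly, and the sweep's plateau coincides with the unwindowed
PCC.  Chain flags are not recomputed for the crop — the crop is a probe of
the trained model, not a new encoding.  The critical span Wsc is the
smallest grid value whose PCC is within `plateau_tol` (default 0.02) of
the PCC at the largest span; the tolerance is this package's
operationalization of "the PCC stops improving".

**Cutoff masking.**  To ask what residues beyond Rcut contribute, all 28
feature slots of rows farther than Rcut from the probed site are zeroed
(a null token); rows are never deleted, so sequence separations are
preserved, and the probed row itself is never masked.  Zeroing (rather
than deletion) is a convention — deletion would corrupt the sequence
geometry the recurrent model relies on.  The pooled PCC over all residues
of the analysis set, divided by the unmasked pooled PCC, gives
PCC/PCC_all; consecutive differences divided by the growth in admitted
(i, j) neighbor pairs give ΔPCC/ΔAtoms, the per-atom marginal value of
context at that distance.  Zero-atom increments are skipped.  The
unmasked baseline is computed through the same batched code path as the
masked calls, so a cutoff covering every pair reproduces it bit for bit.

**n̂.**  For cutoff Rcut (optionally restricted to sequence separation
≤ Ws), nᵢ counts *other* Cα atoms within the cutoff; n̄ is the mean over
residues and n̂ = n̄/(N−1) ∈ [0, 1] (the self-exclusion is forced by the
N−1 normalization).  For each protein, PCC_n = Pearson(n̂(Ws; Rcut),
PCC(Ws)) over the window grid; the mean over proteins, PCC̄ₙ, scanned over
Rcut, peaks at the radius whose neighbor population best mirrors the
model's accuracy growth.  Proteins with a degenerate (constant) n̂ curve at
some cutoff are excluded at that cutoff and counted.

## Synthetic data: what it emulates, what it does not

The generator builds Cα chains from ideal segments — helix (rise
1.5 Å/residue, 100° twist), strand (rise 3.3 Å/residue, 190° twist, which
lands inside the P-SEA strand windows), coil (random 20–75° bends) — with
every virtual bond exactly 3.8 Å, excluded volume of 4 Å between
non-bonded sites, orientation continuity between segments, and optional
multiple chains anchored near the existing body.  Residue identities are
random with hydrophobic types enriched at high-contact (buried) sites,
echoing the real core-packing tendency that makes sequence alone partially
predictive of flexibility.

B factors follow a known caging law: the clean standardized profile is the
negated Z-score of the contact count within the generative radius
r\* (default 8 Å, a typical elastic-network interaction distance for Cα
models), plus Gaussian noise of SD `noise_sd` (default 0.3, i.e. a
noise-to-signal ratio of 0.3 on the unit-SD profile, implying a PCC
ceiling of ≈ 0.96); raw B is the fixed affine map 40 + 10·B̂ clipped to
[5, 75] Å², safely inside curation bounds.  Chains are 60–200 residues by
default, with roughly 35 % helix / 25 % sheet.

These chains are *not* physically realistic folds: no side chains, no
hydrogen-bond topology, no crystallographic noise model, and compactness
arises only from excluded-volume random growth rather than hydrophobic
collapse.  Passing the recovery tests therefore demonstrates that the
pipeline — encoding, training, evaluation, and the window/cutoff analyses
— correctly extracts a known generative radius and feature hierarchy from
data of this geometry; it does not certify accuracy on real deposited
structures, which requires training on a real corpus.

## Desk-scale study conditions

The end-to-end recovery study (tests and `scripts/acceptance.py`) uses 260
synthetic proteins (200 train / 30 validation / 30 test), architecture
encoder 32 → one bidirectional layer of hidden 32 → decoder 32→1 (≈ 19.7k
parameters), Adam at 2e-3, batch 16, up to 60 epochs with patience 12.
The n̂/PCC̄ₙ scan uses 23 analysis proteins, window grid 0–42 in steps of 3,
cutoff grid 2–20 Å in steps of 2; the ΔPCC/ΔAtoms study uses 5 proteins.
These sizes are the package's chosen desk-scale conditions: large enough
that the full model reliably clears a held-out average PCC of 0.6, that
the PS-only/no-LSTM ablation scores far lower, and that the PCC̄ₙ peak
lands within ±4 Å of r\* — while a complete run stays in the minutes
range on a single CPU.

## Numerical notes and limitations

* Everything is float64; training is single-threaded NumPy and
  deterministic for a fixed seed on a given machine.  Bit-level
  reproducibility across BLAS implementations is not guaranteed; the
  within-run consistency identities (masking at infinite cutoff, window
  covering the chain) are exact because they compare identical code paths.
* Pearson correlation requires ≥ 3 points and non-constant inputs; a
  constant prediction or target is reported as a failed protein and
  excluded from the dataset mean, never silently scored 0.
* The Wsc estimate is grid-resolution-limited and tolerance-dependent.
* The PCC̄ₙ curve is typically flat near its peak; with small analysis
  sets the argmax can wander a few Å within that plateau, which is why
  the recovery contract is stated as a ±4 Å window around r\*.
* Degenerate geometry (zero variance on a coordinate axis, all-equal B)
  raises explicit errors upstream of any silent NaN.
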