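# caflex

Sequence-based prediction of per-residue crystallographic B factors
(temperature factors), with the analysis machinery to ask *how far* — along
the chain and through space — one residue's neighborhood shapes another
residue's flexibility.

## Who this is for

Structural bioinformaticians and protein modellers who want (a) a
per-residue flexibility predictor that consumes only light-weight features
(no MSAs, no full-atom structure), and (b) quantitative, model-based
answers to "which neighbors set a residue's B factor?" — the question that
elastic-network cutoff radii answer from physics, here answered from a
learned regressor.

## The model

Each Cα site *i* of a protein is encoded as a 28-vector **I**ᵢ:

* slots 1–21 — one-hot amino-acid type (20 canonical residues + a
  catch-all for non-canonical ones),
* slots 22–24 — one-hot secondary structure (sheet, helix, coil), assigned
  from Cα geometry alone (P-SEA-style distance/angle windows),
* slots 25–27 — the Cα coordinates, Z-scored per protein and per axis:
  X̂ᵢ = (Xᵢ − μ_X)/σ_X (population SD),
* slot 28 — a chain start/end flag.

The regressor is

    Eᵢ = f_enc(Iᵢ)        (feedforward encoder, shared across positions)
    L  = f_lstm(E)        (bidirectional LSTM over the whole chain)
    B̂ᵢᵖ = f_dec(Lᵢ)       (feedforward decoder to a scalar)

trained with the per-protein mean-squared error
MSE = Σᵢ (B̂ᵢᵖ − B̂ᵢᵉ)²/N.  Targets are per-protein Z-scores
B̂ᵢ = (Bᵢ − μ_B)/σ_B (population SD), making proteins solved at different
resolutions comparable; a raw-Å² mode is also available.  Accuracy is the
Pearson correlation coefficient (PCC) between predicted and actual
profiles, averaged unweighted over proteins.  Setting `use_lstm=False`
collapses the model to a per-residue feedforward net — the ablation that
measures what chain context contributes — and the PS/SS/CoI/ChI feature
groups can be disabled independently.

Input curation mirrors standard practice: proteins are rejected if any Cα
B factor exceeds 80 Å², any is ≤ 0, all are identical, or the chain
exceeds 500 residues.

The interpretability toolkit probes a trained model with

* **window sweeps** — re-predict each residue from a sequence window of
  span Ws; PCC(Ws) rises and plateaus at a protein-specific critical span,
* **cutoff-radius masking** — blank all residues farther than Rcut (Å)
  from the probed site and track PCC/PCC_all and the per-atom marginal
  gain ΔPCC/ΔAtoms,
* **the n̂ statistic** — mean number of other Cα atoms within Rcut,
  normalized by N−1; correlating n̂(Ws) with PCC(Ws) over a grid of Rcut
  values locates the radius whose neighbor count best explains the
  model's accuracy profile.

Because no network access is assumed, the package ships a synthetic-chain
generator: helix/strand/coil Cα traces (3.8 Å virtual bonds, excluded
volume) whose B factors follow a known caging law — the negated Z-score of
the contact count within a generative radius r\* plus noise.  That makes
every analysis a parameter-recovery exercise with a known answer.

## Worked example

```python
from caflex import BFactorModel, ModelConfig, TrainConfig, SyntheticConfig
from caflex.synthetic_data import generate_dataset

records, truth = generate_dataset(SyntheticConfig(n_min=60, n_max=120), 60, seed=7)
model = BFactorModel(records,
                     config=ModelConfig(encoder_widths=(32,), lstm_hidden=32,
                                        lstm_layers=1, decoder_widths=(32, 1)))
result = model.fit(TrainConfig(seeds=(0,), max_epochs=30, batch_size=8,
                               learning_rate=2e-3, early_stop_patience=10),
                   fractions=(0.8, 0.1, 0.1), seed=0)
print(result.summary())
```

prints

```
B-factor regression results
=============================================
proteins (train/val/test): 48/6/6
feature mask:              {'use_ps': True, 'use_ss': True, 'use_coi': True, 'use_chi': True}
prediction mode:           normalized
architecture:              enc[32] biLSTM(h=32×1) dec[32, 1]
tunable parameters:        19,681
epochs run / best epoch:   30 / 29
best validation MSE:       0.3878
test average PCC:          0.8257 (6 proteins, 0 failed)
```

— a 19.7k-parameter model reaching a held-out average PCC of 0.83 on this
small synthetic corpus (the PCC ceiling implied by the generator's noise
level of 0.3 is ≈ 0.96).  The window sweep on one held-out protein:

```python
sweep = result.window_sweep(result.split.test[0], ws_grid=[0, 4, 8, 16, 32])
print(sweep.pcc_at_ws)       # [0.730, 0.868, 0.891, 0.894, 0.881]
print(sweep.wsc_estimate)    # 4
```

shows the characteristic sharp rise and plateau: for this chain, a
sequence window of span ≈ 4 already carries nearly all the information the
model uses.

A command-line interface covers the same workflows
(`caflex simulate | curate | encode | train | predict | evaluate |
analyze-window | analyze-rcut | summarize-groups`); run
`caflex <subcommand> --help` for the flags.

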