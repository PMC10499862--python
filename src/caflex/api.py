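"""High-level modelling interface: :class:`BFactorModel` / :class:`BFactorResults`.

Mirrors the model/results idiom of the statistical-modelling stack: a
model object is built from data (protein records) plus design choices
(feature mask, prediction mode, architecture), ``fit()`` trains it and
returns a results object carrying the fitted predictor, its training
history, held-out evaluation, a ``summary()`` table and the
interpretability sweeps.

    >>> records, _ = generate_dataset(SyntheticConfig(), 50, seed=0)
    >>> model = BFactorModel(records, mask=FeatureMask(), b_mode="normalized")
    >>> res = model.fit(TrainConfig(max_epochs=40), seed=0)
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation, interpret
from .features import FeatureMask, FeatureMatrix, encode_protein
from .model import (
    ModelConfig,
    TrainConfig,
    TrainingHistory,
    Predictor,
    count_parameters,
    save_checkpoint,
    train_model,
)
from .structures_io import (
    ProteinRecord,
    assign_secondary_structure,
    curate_protein,
    read_structure,
    split_dataset,
)

__all__ = ["BFactorModel", "BFactorResults"]


class BFactorModel:
    """A B-factor regression problem: curated records plus design choices.

    Parameters
    ----------
    records
        Protein records (synthetic or read from PDB files).  Records that
        fail curation are dropped (kept under ``rejected``).
    mask
        Which feature groups enter the encoding (PS/SS/CoI/ChI).
    b_mode
        ``"normalized"`` (per-protein Z-scored targets) or
        ``"unnormalized"`` (raw Å², scaled for conditioning).
    config
        Architecture of the regressor.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        mask: FeatureMask = FeatureMask(),
        b_mode: str = "normalized",
        config: ModelConfig | None = None,
        assign_ss: bool = False,
    ):
        self.mask = mask
        self.b_mode = b_mode
        self.config = config or ModelConfig()
        self.records: list[ProteinRecord] = []
        self.rejected: list[tuple[str, list[str]]] = []
        for rec in records:
            decision = curate_protein(rec)
            if not decision.accepted:
                self.rejected.append((rec.protein_id, decision.reasons))
                continue
            if assign_ss or (mask.use_ss and "unassigned" in rec.ss_labels):
                rec = assign_secondary_structure(rec)
            self.records.append(rec)
        if not self.records:
            raise ValueError("no record survived curation")
        self._encoded: dict[str, tuple[FeatureMatrix, np.ndarray]] = {
            rec.protein_id: encode_protein(rec, mask, b_mode) for rec in self.records
        }

    @classmethod
    def from_pdb_dir(cls, directory: str | Path, **kwargs) -> "BFactorModel":
        paths = sorted(Path(directory).glob("*.pdb"))
        if not paths:
            raise FileNotFoundError(f"no .pdb files under {directory}")
        return cls([read_structure(p) for p in paths], assign_ss=True, **kwargs)

    def encoded(self, ids: Sequence[str] | None = None):
        ids = ids if ids is not None else [r.protein_id for r in self.records]
        return [self._encoded[i] for i in ids]

    def record(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(protein_id)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        seed: int = 0,
        verbose: bool = False,
    ) -> "BFactorResults":
        tc = train_config or TrainConfig()
        split = split_dataset([r.protein_id for r in self.records], fractions, seed)
        predictor, history = train_model(
            self.config,
            tc,
            self.encoded(split.train),
            self.encoded(split.validation),
            seed=seed,
            verbose=verbose,
        )
        return BFactorResults(self, predictor, history, tc, split)


class BFactorResults:
    """A fitted regressor plus everything needed to judge and probe it."""

    def __init__(self, model: BFactorModel, predictor: Predictor,
                 history: TrainingHistory, train_config: TrainConfig, split):
        self.model = model
        self.predictor = predictor
        self.history = history
        self.train_config = train_config
        self.split = split

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.predictor)

    def predict(self, record: ProteinRecord) -> np.ndarray:
        feats, _ = encode_protein(record, self.model.mask, self.model.b_mode)
        return self.predictor.predict(feats.values)

    def evaluate(self, subset: str = "test") -> evaluation.EvalReport:
        ids = getattr(self.split, "validation" if subset == "val" else subset)
        return evaluation.evaluate_dataset(
            self.predictor, self.model.encoded(ids), self.model.b_mode
        )

    def summary(self) -> str:
        rep = self.evaluate("test")
        cfg = self.predictor.config
        lines = [
            "B-factor regression results",
            "=" * 45,
            f"proteins (train/val/test): "
            f"{len(self.split.train)}/{len(self.split.validation)}/{len(self.split.test)}",
            f"feature mask:              {self.model.mask.as_dict()}",
            f"prediction mode:           {self.model.b_mode}",
            f"architecture:              enc{list(cfg.encoder_widths)} "
            + (f"biLSTM(h={cfg.lstm_hidden}×{cfg.lstm_layers})" if cfg.use_lstm else "no-LSTM")
            + f" dec{list(cfg.decoder_widths)}",
            f"tunable parameters:        {self.n_parameters:,}",
            f"epochs run / best epoch:   {len(self.history.train_loss)} / {self.history.best_epoch}",
            f"best validation MSE:       {self.history.val_loss[self.history.best_epoch]:.4f}",
            f"test average PCC:          {rep.average_pcc:.4f} "
            f"({len(rep.per_protein)} proteins, {len(rep.failed)} failed)",
        ]
        return "\n".join(lines)

    # ---- interpretability, delegated to the interpret module -------------------

    def window_sweep(self, protein_id: str, ws_grid, plateau_tol: float = 0.02):
        rec = self.model.record(protein_id)
        feats, target = self.model._encoded[protein_id]
        return interpret.window_sweep(self.predictor, rec, feats, target, ws_grid, plateau_tol)

    def rcut_sweep(self, ids: Sequence[str], rcut_grid):
        items = [
            (self.model.record(i), *self.model._encoded[i]) for i in ids
        ]
        return interpret.rcut_sweep(self.predictor, items, rcut_grid)

    def pccn_vs_rcut(self, ids: Sequence[str], ws_grid, rcut_grid):
        curves = []
        for pid in ids:
            sweep = self.window_sweep(pid, ws_grid)
            curves.append((self.model.record(pid), sweep.ws_values, sweep.pcc_at_ws))
        return interpret.pccn_vs_rcut(curves, rcut_grid)

    def group_summary(self, ids: Sequence[str], group_by: str = "amino_acid"):
        records = [self.model.record(i) for i in ids]
        actual = [self.model._encoded[i][1] for i in ids]
        predicted = [self.predictor.predict(self.model._encoded[i][0].values) for i in ids]
        return interpret.group_summary(records, actual, predicted, group_by)

    # ---- persistence / plotting -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        save_checkpoint(self.predictor, directory, self.train_config)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(len(self.history.train_loss))
        ax.plot(epochs, self.history.train_loss, label="train MSE")
        ax.plot(epochs, self.history.val_loss, label="validation MSE")
        ax.axvline(self.history.best_epoch, ls=":", c="gray", label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("per-protein MSE")
        ax.legend()
        return ax

    def plot_profile(self, protein_id: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        feats, target = self.model._encoded[protein_id]
        pred = self.predictor.predict(feats.values)
        ax.plot(target, label="actual B̂")
        ax.plot(pred, label="predicted B̂")
        ax.set_xlabel("residue")
        ax.set_ylabel("normalized B factor")
        ax.set_title(protein_id)
        ax.legend()
        return ax
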