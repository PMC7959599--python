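"""High-level model/results interface.

:class:`PromoterClassifier` is constructed from labelled sequence records
(or a DataFrame of sequences and labels) plus an encoder/architecture
choice; ``fit()`` runs the full pipeline — stratified 81/9/10 split,
vocabulary fit on the training part, encoding, training — and returns a
:class:`PromoterResults` carrying the trained model, the held-out metrics,
the training history and a ``summary()`` table. Simulation helpers and
diagnostic plots hang off these two objects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import KmerVocabulary, encode_dataset
from .evaluation import (
    SplitIndices,
    _subset,
    run_random_negative_test,
    stratified_split,
    train_on_records,
)
from .io import SeqRecord
from .metrics import Metrics, compute_metrics, confusion, multiclass_metrics
from .models import TrainConfig, TrainedModel, predict

__all__ = ["PromoterClassifier", "PromoterResults"]


class PromoterClassifier:
    """Promoter sequence classification model.

    Parameters
    ----------
    records : sequence of SeqRecord
        Labelled sequences of one common length. Binary labels (0/1) give
        a promoter/non-promoter model; labels 0..C-1 with C > 2 give a
        multiclass (species-of-promoter) model.
    model : {"cnn", "lstm", "rf"}
        Classifier architecture.
    encoder : {"fbt", "onehot"}
        Frequency-based tokenization or one-hot k-mer encoding.
    k : int
        k-mer size (the study grid is 2, 4, 8; 1 is also supported).
    """

    def __init__(
        self,
        records: Sequence[SeqRecord],
        model: str = "cnn",
        encoder: str = "fbt",
        k: int = 2,
        spec=None,
    ):
        if not records:
            raise ValueError("no records")
        labels = {r.label for r in records}
        if None in labels:
            raise ValueError("every record needs a label")
        self.records = list(records)
        self.model_kind = model
        self.encoder = encoder
        self.k = k
        self.spec = spec
        self.n_classes = max(2, max(labels) + 1)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, bases_col="bases", label_col="label", **kwargs
    ) -> "PromoterClassifier":
        """Build from a DataFrame with sequence and label columns."""
        records = [
            SeqRecord(
                id=str(row.get("id", i)),
                bases=str(row[bases_col]).upper(),
                species=row.get("species"),
                label=int(row[label_col]),
            )
            for i, row in df.iterrows()
        ]
        return cls(records, **kwargs)

    def fit(self, config: TrainConfig | None = None, seed: int | None = None
            ) -> "PromoterResults":
        """Split, encode, train; score the held-out test part."""
        config = config or TrainConfig()
        if seed is not None:
            config = TrainConfig(
                epochs=config.epochs, batch_size=config.batch_size,
                learning_rate=config.learning_rate, patience=config.patience,
                seed=seed,
            )
        trained, data, vocab, split = train_on_records(
            self.records, self.model_kind, self.encoder, self.k,
            n_classes=self.n_classes, config=config, spec=self.spec,
        )
        test = _subset(data, split.test)
        _, y_hat = predict(trained, test)
        if self.n_classes == 2:
            m = compute_metrics(confusion(test.y, y_hat))
        else:
            m = multiclass_metrics(test.y, y_hat, self.n_classes)
        return PromoterResults(self, trained, data, vocab, split, m, config)


class PromoterResults:
    """Fit results: trained model, held-out metrics, history, diagnostics."""

    def __init__(
        self,
        model: PromoterClassifier,
        trained: TrainedModel,
        data,
        vocab: KmerVocabulary | None,
        split: SplitIndices,
        test_metrics: Metrics,
        config: TrainConfig,
    ):
        self.model = model
        self.trained = trained
        self.data = data
        self.vocab = vocab
        self.split = split
        self.test_metrics = test_metrics
        self.config = config

    @property
    def history(self):
        return self.trained.history

    def predict(self, records: Sequence[SeqRecord]) -> np.ndarray:
        """Hard labels for new sequences (encoded under the fitted vocabulary)."""
        data = encode_dataset(
            list(records), self.model.encoder, self.model.k, vocab=self.vocab
        )
        _, y_hat = predict(self.trained, data)
        return y_hat

    def predict_proba(self, records: Sequence[SeqRecord]) -> np.ndarray:
        data = encode_dataset(
            list(records), self.model.encoder, self.model.k, vocab=self.vocab
        )
        proba, _ = predict(self.trained, data)
        return proba

    def score_background(self, background: Sequence[SeqRecord]) -> Metrics:
        """Negative-control check: held-out promoters vs random background."""
        test_pos = [
            self.model.records[i]
            for i in self.split.test
            if self.model.records[i].label == 1
        ]
        return run_random_negative_test(
            self.trained, test_pos, list(background), vocab=self.vocab
        )

    def summary(self) -> str:
        """Human-readable fit summary (metrics printed to 2 decimals)."""
        m = self.test_metrics
        lines = [
            "Promoter classification results",
            "=" * 46,
            f"model:            {self.model.model_kind.upper()}",
            f"encoder:          {self.model.encoder} (k={self.model.k})",
            f"classes:          {self.trained.contract.n_classes}",
            f"sequence length:  {self.data.source_length} nt "
            f"({self.data.n_positions} k-mer positions)",
            f"train/val/test:   {len(self.split.train)}/"
            f"{len(self.split.validation)}/{len(self.split.test)}",
            f"seed:             {self.config.seed}",
            "-" * 46,
            f"test Acc:         {m.acc:.2f}",
            f"test Sn:          {m.sn:.2f}",
            f"test Sp:          {m.sp:.2f}",
            f"test MCC:         {m.mcc:.2f}",
        ]
        h = self.history
        if h is not None and h.n_epochs_run:
            stopped = (
                f" (early-stopped at epoch {h.stopped_epoch})"
                if h.stopped_epoch else ""
            )
            lines.append(
                f"epochs run:       {h.n_epochs_run}{stopped}; "
                f"final val loss {h.val_loss[-1]:.4f}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training / validation loss curves (neural models only)."""
        import matplotlib.pyplot as plt

        h = self.history
        if h is None or not h.n_epochs_run:
            raise ValueError("no training history to plot (random forest?)")
        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, h.n_epochs_run + 1)
        ax.plot(epochs, h.loss, marker="o", label="train loss")
        if h.val_loss:
            ax.plot(epochs, h.val_loss, marker="s", label="validation loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        ax.legend()
        return ax
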