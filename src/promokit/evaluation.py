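"""Data splitting and the four experiment designs.

Experiments: binary promoter vs shuffled-negative classification,
cross-species transfer (train on one species, score another),
negative-control testing against random genomic background, and
multiclass species-of-promoter classification. Each returns tidy result
rows (pandas) holding Acc, Sn, Sp and MCC plus the run's bookkeeping.

Splits are stratified: 10% of the data is held out for testing and 10% of
the remaining 90% (9% overall) for validation, leaving 81% for training.
Vocabularies are always fitted on the training split only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .encoding import EncodedDataset, fit_vocabulary, encode_dataset, KmerVocabulary
from .io import SeqRecord
from .metrics import Metrics, compute_metrics, confusion, multiclass_metrics
from .models import (
    CNNSpec,
    LSTMSpec,
    RFSpec,
    TrainConfig,
    TrainedModel,
    build_cnn,
    build_lstm,
    build_rf,
    predict,
    train,
)

__all__ = [
    "SplitIndices",
    "stratified_split",
    "train_on_records",
    "run_binary_experiment",
    "run_cross_species",
    "run_random_negative_test",
    "run_multiclass_experiment",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "experiment", "species_train", "species_test", "model", "encoder", "k",
    "seed", "Acc", "Sn", "Sp", "MCC", "n_train", "n_test", "wall_time_s",
]


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        n = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != n:
            raise ValueError("split parts overlap")


def stratified_split(
    labels: Sequence[int],
    test_frac: float = 0.10,
    val_frac_of_train: float = 0.10,
    seed: int = 0,
) -> SplitIndices:
    """Stratified train/validation/test indices (81/9/10 by default).

    The test part takes ``test_frac`` of all samples; the validation part
    takes ``val_frac_of_train`` of what remains. Both draws are stratified
    on the labels and deterministic under ``seed``.
    """
    y = np.asarray(labels)
    idx = np.arange(len(y))
    trainval, test = train_test_split(
        idx, test_size=test_frac, stratify=y, random_state=seed
    )
    train_idx, val = train_test_split(
        trainval,
        test_size=val_frac_of_train,
        stratify=y[trainval],
        random_state=seed + 1,
    )
    return SplitIndices(
        train=np.sort(train_idx), validation=np.sort(val), test=np.sort(test)
    )


def _build_model(model_kind, data: EncodedDataset, n_classes, seed, spec=None):
    if model_kind == "cnn":
        spec = spec or CNNSpec()
        return build_cnn(
            spec, data.vocab_size, data.n_positions, n_classes,
            encoder=data.encoder, seed=seed,
        ), spec
    if model_kind == "lstm":
        spec = spec or LSTMSpec()
        return build_lstm(
            spec, data.vocab_size, data.n_positions, n_classes,
            encoder=data.encoder, seed=seed,
        ), spec
    if model_kind == "rf":
        spec = spec or RFSpec()
        return build_rf(spec, seed=seed), spec
    raise ValueError(f"unknown model kind {model_kind!r}")


def train_on_records(
    records: Sequence[SeqRecord],
    model_kind: str,
    encoder: str = "fbt",
    k: int = 2,
    n_classes: int = 2,
    config: TrainConfig | None = None,
    spec=None,
) -> tuple[TrainedModel, EncodedDataset, KmerVocabulary | None, SplitIndices]:
    """Split, fit the vocabulary on the training part, encode and train.

    Returns the trained model, the encoded full dataset, the fitted
    vocabulary (None for one-hot) and the split indices, so callers can
    score the held-out test part or re-use the vocabulary on other corpora.
    """
    config = config or TrainConfig()
    labels = [r.label for r in records]
    split = stratified_split(labels, seed=config.seed)
    # leakage guard: the three parts must never share a sample
    assert (
        len(set(split.train) & set(split.test)) == 0
        and len(set(split.train) & set(split.validation)) == 0
        and len(set(split.validation) & set(split.test)) == 0
    )
    vocab = None
    if encoder == "fbt":
        vocab = fit_vocabulary((records[i].bases for i in split.train), k)
    data = encode_dataset(records, encoder, k, vocab=vocab)
    sub = _subset
    model, spec = _build_model(model_kind, data, n_classes, config.seed, spec)
    trained = train(
        model,
        sub(data, split.train),
        sub(data, split.validation),
        config,
        kind=model_kind,
        spec=spec,
        n_classes=n_classes,
    )
    return trained, data, vocab, split


def _subset(data: EncodedDataset, idx: np.ndarray) -> EncodedDataset:
    return EncodedDataset(
        X=data.X[idx],
        y=data.y[idx],
        encoder=data.encoder,
        k=data.k,
        source_length=data.source_length,
        vocab_checksum=data.vocab_checksum,
        vocab_size=data.vocab_size,
        ids=[data.ids[i] for i in idx],
    )


def _row(experiment, sp_train, sp_test, model_kind, encoder, k, seed,
         m: Metrics, n_train, n_test, wall) -> dict:
    return {
        "experiment": experiment, "species_train": sp_train,
        "species_test": sp_test, "model": model_kind, "encoder": encoder,
        "k": k, "seed": seed, "Acc": m.acc, "Sn": m.sn, "Sp": m.sp,
        "MCC": m.mcc, "n_train": n_train, "n_test": n_test,
        "wall_time_s": wall,
    }


def run_binary_experiment(
    records: Sequence[SeqRecord],
    model_kind: str,
    encoder: str = "fbt",
    k: int = 2,
    config: TrainConfig | None = None,
    species: str = "",
    spec=None,
) -> tuple[pd.DataFrame, TrainedModel, EncodedDataset, SplitIndices]:
    """Binary promoter / non-promoter classification on one species.

    Encodes, splits 81/9/10, trains and scores the held-out test part;
    returns a one-row result table plus the trained artefacts for re-use
    (cross-species scoring, random-negative testing).
    """
    config = config or TrainConfig()
    t0 = time.perf_counter()
    trained, data, vocab, split = train_on_records(
        records, model_kind, encoder, k, n_classes=2, config=config, spec=spec
    )
    test = _subset(data, split.test)
    _, y_hat = predict(trained, test)
    m = compute_metrics(confusion(test.y, y_hat))
    wall = time.perf_counter() - t0
    row = _row(
        "binary", species, species, model_kind, encoder, k, config.seed,
        m, len(split.train), len(split.test), wall,
    )
    return pd.DataFrame([row], columns=RESULT_COLUMNS), trained, data, split


def run_cross_species(
    datasets: Mapping[str, Sequence[SeqRecord]],
    model_kind: str,
    encoder: str = "fbt",
    k: int = 2,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train per species, score every *other* species' full dataset.

    The scoring corpus is encoded with the training species' vocabulary,
    so k-mers unseen in training map to the reserved index 0. Also emits
    the within-species (diagonal) test-split rows for reference.
    """
    if len(datasets) < 2:
        raise ValueError("cross-species evaluation needs at least 2 species")
    config = config or TrainConfig()
    lengths = {len(r.bases) for recs in datasets.values() for r in recs}
    if len(lengths) != 1:
        raise ValueError(f"species datasets have mixed lengths: {sorted(lengths)}")
    rows = []
    for sp_train, records in datasets.items():
        t0 = time.perf_counter()
        trained, data, vocab, split = train_on_records(
            records, model_kind, encoder, k, n_classes=2, config=config
        )
        test = _subset(data, split.test)
        _, y_hat = predict(trained, test)
        m = compute_metrics(confusion(test.y, y_hat))
        rows.append(_row(
            "cross_species", sp_train, sp_train, model_kind, encoder, k,
            config.seed, m, len(split.train), len(split.test),
            time.perf_counter() - t0,
        ))
        for sp_test, other in datasets.items():
            if sp_test == sp_train:
                continue
            t1 = time.perf_counter()
            other_data = encode_dataset(other, encoder, k, vocab=vocab)
            _, y_hat = predict(trained, other_data)
            m = compute_metrics(confusion(other_data.y, y_hat))
            rows.append(_row(
                "cross_species", sp_train, sp_test, model_kind, encoder, k,
                config.seed, m, len(split.train), len(other),
                time.perf_counter() - t1,
            ))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_random_negative_test(
    model: TrainedModel,
    test_promoters: Sequence[SeqRecord],
    random_background: Sequence[SeqRecord],
    vocab: KmerVocabulary | None = None,
) -> Metrics:
    """Score held-out promoters against never-trained-on random windows.

    Positives are the held-out promoters (label 1), negatives the random
    background windows (label 0); standard binary metrics.
    """
    if not random_background:
        raise ValueError("random background set is empty")
    if not test_promoters:
        raise ValueError("held-out promoter set is empty")
    recs = [
        SeqRecord(id=r.id, bases=r.bases, species=r.species, label=1)
        for r in test_promoters
    ] + [
        SeqRecord(id=r.id, bases=r.bases, species=r.species, label=0)
        for r in random_background
    ]
    data = encode_dataset(recs, model.contract.encoder, model.contract.k, vocab=vocab)
    _, y_hat = predict(model, data)
    return compute_metrics(confusion(data.y, y_hat))


def run_multiclass_experiment(
    promoter_corpora: Mapping[str, Sequence[SeqRecord]],
    model_kind: str,
    encoder: str = "fbt",
    k: int = 2,
    config: TrainConfig | None = None,
) -> tuple[pd.DataFrame, TrainedModel]:
    """Species-of-promoter classification over pooled promoter corpora.

    Labels are species indices in corpus-key order; no negative class.
    """
    if len(promoter_corpora) < 2:
        raise ValueError("multiclass experiment needs at least 2 corpora")
    config = config or TrainConfig()
    species_names = list(promoter_corpora)
    pooled: list[SeqRecord] = []
    for label, name in enumerate(species_names):
        for r in promoter_corpora[name]:
            pooled.append(
                SeqRecord(id=r.id, bases=r.bases, species=name, label=label)
            )
    n_classes = len(species_names)
    t0 = time.perf_counter()
    trained, data, vocab, split = train_on_records(
        pooled, model_kind, encoder, k, n_classes=n_classes, config=config
    )
    test = _subset(data, split.test)
    _, y_hat = predict(trained, test)
    m = multiclass_metrics(test.y, y_hat, n_classes)
    wall = time.perf_counter() - t0
    row = _row(
        "multiclass", "+".join(species_names), "+".join(species_names),
        model_kind, encoder, k, config.seed, m,
        len(split.train), len(split.test), wall,
    )
    return pd.DataFrame([row], columns=RESULT_COLUMNS), trained
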