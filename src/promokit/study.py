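"""One-call benchmark study on the synthetic pseudo-species fixture.

Runs the full experimental design on generated data: per-species binary
classification (promoters vs shuffled negatives), cross-species transfer
of every binary model to the other species' full datasets, a
negative-control test of one trained model against composition-matched
random background, and 3-way species-of-promoter classification with both
the CNN and the random forest. Everything is deterministic under the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    RESULT_COLUMNS,
    _row,
    _subset,
    run_multiclass_experiment,
    run_random_negative_test,
    train_on_records,
)
from .encoding import encode_dataset
from .metrics import Metrics, compute_metrics, confusion
from .models import TrainConfig, predict
from .simulate import generate_full_fixture

__all__ = ["FixtureStudy", "run_fixture_study"]


@dataclass
class FixtureStudy:
    """Result tables of the synthetic-fixture benchmark."""

    binary: pd.DataFrame        # within-species test-split rows (CNN)
    cross: pd.DataFrame         # off-diagonal transfer rows (CNN)
    random_negative: Metrics    # held-out promoters vs random background
    multiclass: pd.DataFrame    # 3-way rows for CNN and RF

    @property
    def within_mean_acc(self) -> float:
        return float(self.binary.Acc.mean())

    @property
    def cross_mean_acc(self) -> float:
        return float(self.cross.Acc.mean())


def run_fixture_study(
    n_per_class: int = 1000,
    length: int = 250,
    k: int = 2,
    seed: int = 0,
    encoder: str = "fbt",
    config: TrainConfig | None = None,
) -> FixtureStudy:
    """Run the four experiment designs on the default synthetic fixture.

    Trains one binary CNN per pseudo-species and reuses it for the
    cross-species matrix; the last species' model is additionally scored
    against its composition-matched random background pool. Multiclass
    runs both the CNN and the RF at the same seed.
    """
    config = config or TrainConfig(seed=seed)
    fixture = generate_full_fixture(n_per_class=n_per_class, length=length,
                                    seed=seed)
    binary_rows, cross_rows = [], []
    random_negative = None
    species = list(fixture)
    for sp in species:
        records = fixture[sp]["binary"]
        trained, data, vocab, split = train_on_records(
            records, "cnn", encoder, k, n_classes=2, config=config
        )
        test = _subset(data, split.test)
        _, y_hat = predict(trained, test)
        m = compute_metrics(confusion(test.y, y_hat))
        binary_rows.append(_row(
            "binary", sp, sp, "cnn", encoder, k, config.seed, m,
            len(split.train), len(split.test), np.nan,
        ))
        for other in species:
            if other == sp:
                continue
            other_data = encode_dataset(
                fixture[other]["binary"], encoder, k, vocab=vocab
            )
            _, y_hat = predict(trained, other_data)
            m = compute_metrics(confusion(other_data.y, y_hat))
            cross_rows.append(_row(
                "cross_species", sp, other, "cnn", encoder, k, config.seed,
                m, len(split.train), len(other_data.y), np.nan,
            ))
        # negative-control test for the last species' model
        if sp == species[-1]:
            test_pos = [records[i] for i in split.test if records[i].label == 1]
            random_negative = run_random_negative_test(
                trained, test_pos, fixture[sp]["background"], vocab=vocab
            )
    corpora = {sp: fixture[sp]["promoters"] for sp in species}
    mc_rows = []
    for kind in ("cnn", "rf"):
        table, _ = run_multiclass_experiment(corpora, kind, encoder, k, config)
        mc_rows.append(table)
    return FixtureStudy(
        binary=pd.DataFrame(binary_rows, columns=RESULT_COLUMNS),
        cross=pd.DataFrame(cross_rows, columns=RESULT_COLUMNS),
        random_negative=random_negative,
        multiclass=pd.concat(mc_rows, ignore_index=True),
    )
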