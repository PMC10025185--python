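"""Binary training-set construction and class-imbalance correction.

Only YES (coded 1) and NO (coded 0) substances enter training; for the
CMR endpoint Pending defaults to positive (a substance that *could* be
CMR is treated as CMR — the conservative reading).  NoInformation
substances are reserved for prediction.

Two imbalance strategies:

* :func:`oversample` — simple oversampling, literally doubling the less
  populated class by duplicating each minority record exactly once;
* :func:`partition_ensemble` — when positives far outnumber negatives,
  build several balanced subsets, each holding every negative plus an
  equally sized random sample of positives, such that every positive
  appears in at least one subset.  The subsets train an ensemble
  combined by majority voting downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from toxtriage.integration import YES, NO, PENDING, NO_INFORMATION

PENDING_AS_POSITIVE = "as_positive"
PENDING_EXCLUDE = "exclude"


class UnmodelableEndpointError(ValueError):
    """An endpoint with an empty class cannot train a classifier.

    Raised with a recommendation to fall back to read-across — the
    situation of an endpoint with (say) only three negatives.
    """


class PartitionUnnecessaryError(ValueError):
    """Positives do not outnumber negatives; use oversampling instead."""


@dataclass
class BinaryDataset:
    """Training records for one endpoint: columns cas, smiles, y."""

    records: pd.DataFrame
    endpoint: str
    note: str = ""

    @property
    def n_positive(self) -> int:
        return int((self.records["y"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.records["y"] == 0).sum())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EnsemblePartition:
    subsets: list
    seed: int


def extract_training_set(
    labels: pd.DataFrame,
    curation: pd.DataFrame,
    endpoint: str,
    pending_policy: Optional[str] = None,
) -> tuple[BinaryDataset, pd.DataFrame]:
    """Split labelled, curated substances into training and prediction sets.

    Returns ``(dataset, prediction_set)`` where the prediction set holds
    the modelable substances labelled NoInformation (columns cas,
    smiles).  Duplicate canonical structures across CAS are kept but
    flagged in the dataset note.
    """
    from toxtriage.curation import select_modelable

    if pending_policy is None:
        pending_policy = PENDING_AS_POSITIVE if endpoint == "CMR" else PENDING_EXCLUDE
    report = select_modelable(curation)
    kept = set(report.kept)
    smiles_by_cas = {
        row.cas: row.canonical_smiles
        for row in curation.itertuples(index=False)
        if row.cas in kept
    }
    ep = labels[(labels["endpoint"] == endpoint)
                & (labels["provenance"] == "integrated")]
    rows, pred_rows = [], []
    for row in ep.itertuples(index=False):
        if row.cas not in kept:
            continue
        smiles = smiles_by_cas[row.cas]
        if row.value == YES:
            rows.append({"cas": row.cas, "smiles": smiles, "y": 1})
        elif row.value == NO:
            rows.append({"cas": row.cas, "smiles": smiles, "y": 0})
        elif row.value == PENDING and pending_policy == PENDING_AS_POSITIVE:
            rows.append({"cas": row.cas, "smiles": smiles, "y": 1})
        elif row.value == NO_INFORMATION:
            pred_rows.append({"cas": row.cas, "smiles": smiles})
    records = pd.DataFrame(rows, columns=["cas", "smiles", "y"])
    note = f"pending_policy={pending_policy}"
    dupes = records["smiles"].duplicated().sum()
    if dupes:
        note += f"; {dupes} duplicate canonical structures across CAS"
    dataset = BinaryDataset(records=records, endpoint=endpoint, note=note)
    if dataset.n_positive == 0 or dataset.n_negative == 0:
        raise UnmodelableEndpointError(
            f"{endpoint}: {dataset.n_positive} positives / "
            f"{dataset.n_negative} negatives — cannot train a classifier; "
            "consider read-across"
        )
    prediction_set = pd.DataFrame(pred_rows, columns=["cas", "smiles"])
    return dataset, prediction_set


def oversample(dataset: BinaryDataset, seed: int = 0) -> BinaryDataset:
    """Double the minority class by duplicating each of its records once.

    Deterministic (the seed is accepted for interface symmetry but the
    construction involves no sampling).  Equal class sizes return the
    dataset unchanged with a notice.
    """
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    if n_pos == 0 or n_neg == 0:
        raise UnmodelableEndpointError("both classes must be non-empty")
    if n_pos == n_neg:
        warnings.warn("classes already balanced; oversampling is a no-op")
        return BinaryDataset(
            records=dataset.records.copy(), endpoint=dataset.endpoint,
            note=dataset.note + "; oversample no-op (balanced)",
        )
    minority = 1 if n_pos < n_neg else 0
    extra = dataset.records[dataset.records["y"] == minority]
    records = pd.concat([dataset.records, extra], ignore_index=True)
    return BinaryDataset(
        records=records, endpoint=dataset.endpoint,
        note=dataset.note + "; minority class doubled",
    )


def partition_ensemble(
    dataset: BinaryDataset, n_subsets: Optional[int] = None, seed: int = 0
) -> EnsemblePartition:
    """Balanced-subset construction for positive-heavy datasets.

    Positives are shuffled and chunked into ``n_subsets`` groups of
    size ``n_negative``; short chunks are topped up by resampling
    positives already used elsewhere, so every subset holds all
    negatives plus exactly as many positives, and the union of subset
    positives covers the full positive set.
    """
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    if n_pos <= n_neg:
        raise PartitionUnnecessaryError(
            "positives do not outnumber negatives; use oversample instead"
        )
    minimum = math.ceil(n_pos / n_neg)
    if n_subsets is None:
        n_subsets = max(minimum, 3)
    if n_subsets < minimum:
        raise ValueError(
            f"n_subsets={n_subsets} cannot cover {n_pos} positives "
            f"in chunks of {n_neg}"
        )
    rng = np.random.default_rng(seed)
    positives = dataset.records[dataset.records["y"] == 1].reset_index(drop=True)
    negatives = dataset.records[dataset.records["y"] == 0].reset_index(drop=True)
    order = rng.permutation(n_pos)
    subsets = []
    for i in range(n_subsets):
        chunk = list(order[i * n_neg:(i + 1) * n_neg])
        if len(chunk) < n_neg:
            pool = np.array([j for j in range(n_pos) if j not in set(chunk)])
            top_up = rng.choice(pool, size=n_neg - len(chunk), replace=False)
            chunk.extend(top_up.tolist())
        records = pd.concat(
            [negatives, positives.iloc[sorted(chunk)]], ignore_index=True
        )
        subsets.append(
            BinaryDataset(
                records=records, endpoint=dataset.endpoint,
                note=f"{dataset.note}; ensemble subset {i + 1}/{n_subsets}",
            )
        )
    return EnsemblePartition(subsets=subsets, seed=seed)
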