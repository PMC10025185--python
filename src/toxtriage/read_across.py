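"""Analogue read-across by Tanimoto fingerprint similarity.

When an endpoint lacks the class balance needed for a classifier (the
endocrine-disruption situation: hundreds of positives, a handful of
negatives), a last-resort analogue approach is used: each uninformed
query is compared against every positively annotated structure using
2048-bit hashed topological-path fingerprints and the Tanimoto index.
Queries strictly above the similarity cutoff (default 0.8) inherit a
positive inference; everything else is reported as "none" — never as a
negative, since absence of a close positive analogue is not evidence
of safety.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from toxtriage.conformal import featurize

DEFAULT_CUTOFF = 0.8


class ReadAcrossImpossibleError(ValueError):
    """No positively annotated structures: read-across cannot run."""


@dataclass(frozen=True)
class RaxResult:
    query_cas: str
    nearest_positive_cas: Optional[str]
    max_similarity: float
    inferred: str  # "positive" | "none"


def fingerprint(smiles_or_mol) -> np.ndarray:
    """2048-bit fingerprint as a binary vector (shared with QSAR)."""
    return featurize(smiles_or_mol)


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| over equal-length bitsets.

    By convention two all-zero bitsets score 0.0 (with a warning):
    featureless structures carry no evidence of similarity.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("bitsets must have equal length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0.0")
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def rax_infer(
    queries: Sequence[tuple],
    positives: Sequence[tuple],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[RaxResult]:
    """Positive-label inference for each query against a positive set.

    ``queries`` and ``positives`` are sequences of ``(cas, fingerprint)``
    pairs.  For each query the maximum Tanimoto similarity over the
    positive set is computed; similarity strictly above ``cutoff``
    yields a positive inference.  Nearest-neighbour ties break by CAS
    lexicographic order; results are sorted by similarity, descending.
    """
    positives = list(positives)
    if not positives:
        raise ReadAcrossImpossibleError(
            "read-across impossible: the positive set is empty"
        )
    results = []
    for cas, fp in queries:
        best_sim, best_cas = -1.0, None
        for pos_cas, pos_fp in positives:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sim = tanimoto(fp, pos_fp)
            if sim > best_sim or (sim == best_sim and
                                  (best_cas is None or pos_cas < best_cas)):
                best_sim, best_cas = sim, pos_cas
        results.append(
            RaxResult(
                query_cas=cas,
                nearest_positive_cas=best_cas,
                max_similarity=best_sim,
                inferred="positive" if best_sim > cutoff else "none",
            )
        )
    results.sort(key=lambda r: (-r.max_similarity, r.query_cas))
    return results


def rax_infer_smiles(
    queries: Iterable[tuple],
    positives: Iterable[tuple],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[RaxResult]:
    """Convenience wrapper taking (cas, smiles) pairs."""
    return rax_infer(
        [(cas, fingerprint(smi)) for cas, smi in queries],
        [(cas, fingerprint(smi)) for cas, smi in positives],
        cutoff=cutoff,
    )
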