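"""Gap-filling bookkeeping: apply models to uninformed substances and
account for label changes.

Predicted labels never touch integrated (source-derived) ones: they are
merged under a separate provenance and only for substances that were
NoInformation before.  The accounting report stores integer counts as
the source of truth; every percentage is recomputed from those integers
on demand, at full precision, and rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from toxtriage.conformal import (
    POSITIVE,
    NEGATIVE,
    UNCERTAIN,
    significance_confidence,
)
from toxtriage.integration import (
    ENDPOINTS,
    YES,
    NO,
    PENDING,
    NO_INFORMATION,
    PROVENANCE_PREDICTED,
)


@dataclass
class HighConfidenceRule:
    """Confidence stratum boundary: inclusive >= threshold (default 80%)."""

    threshold_pct: float = 80.0

    def __post_init__(self):
        if not 0.0 < self.threshold_pct <= 100.0:
            raise ValueError("threshold must be in (0, 100]")

    def is_high(self, confidence_pct: float) -> bool:
        return confidence_pct >= self.threshold_pct


def predict_uninformed(
    labels: pd.DataFrame,
    curation: pd.DataFrame,
    model,
    endpoint: str,
    level: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict every modelable NoInformation substance for one endpoint.

    Returns ``(predictions, failures)``.  Predictions carry p-values,
    the assigned label, significance and confidence.  Substances that
    cannot be predicted are collected in the failures table with a
    reason in {no_structure, discarded_category, featurize_fail} —
    they are routed to other methods, never silently dropped.
    """
    from toxtriage.conformal import featurize, FeaturizationError
    from toxtriage.curation import select_modelable

    report = select_modelable(curation)
    kept = set(report.kept)
    reasons = {cas: reason for cas, reason in report.excluded}
    smiles_by_cas = {
        row.cas: row.canonical_smiles for row in curation.itertuples(index=False)
    }
    uninformed = labels[
        (labels["endpoint"] == endpoint)
        & (labels["provenance"] == "integrated")
        & (labels["value"] == NO_INFORMATION)
    ]["cas"]
    rows, failures = [], []
    queryable = []
    for cas in uninformed:
        if cas not in kept:
            reason = reasons.get(cas, "discarded_category")
            if reason in ("missing_structure", "parse_fail"):
                reason = "no_structure"
            failures.append({"cas": cas, "reason": reason})
            continue
        try:
            fp = featurize(smiles_by_cas[cas])
        except FeaturizationError:
            failures.append({"cas": cas, "reason": "featurize_fail"})
            continue
        queryable.append((cas, fp))
    if queryable:
        X = np.vstack([fp for _, fp in queryable])
        p = model.predict_p(X)
        labels_out = model.predict(X, level)
        for (cas, _), (p0, p1), lab in zip(queryable, p, labels_out):
            sig, conf = significance_confidence(p0, p1)
            rows.append(
                {
                    "cas": cas, "endpoint": endpoint, "label": lab,
                    "p_value_0": float(p0), "p_value_1": float(p1),
                    "significance": sig, "confidence_pct": conf,
                }
            )
    predictions = pd.DataFrame(
        rows,
        columns=["cas", "endpoint", "label", "p_value_0", "p_value_1",
                 "significance", "confidence_pct"],
    )
    failures_df = pd.DataFrame(failures, columns=["cas", "reason"])
    return predictions, failures_df


def merge_predictions(labels: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Append definite predictions as provenance=predicted labels.

    Only NoInformation pairs gain a label; integrated YES/NO/Pending
    rows are never modified (provenance separation).
    """
    uninformed = {
        (r.cas, r.endpoint)
        for r in labels.itertuples(index=False)
        if r.provenance == "integrated" and r.value == NO_INFORMATION
    }
    rows = []
    for r in predictions.itertuples(index=False):
        if r.label == UNCERTAIN or (r.cas, r.endpoint) not in uninformed:
            continue
        rows.append(
            {
                "cas": r.cas, "endpoint": r.endpoint,
                "value": YES if r.label == POSITIVE else NO,
                "provenance": PROVENANCE_PREDICTED,
            }
        )
    return pd.concat([labels, pd.DataFrame(rows, columns=labels.columns)],
                     ignore_index=True)


@dataclass
class EndpointAccounting:
    """Before/after label tallies for one endpoint, integers first.

    All percentages are derived properties recomputed from the stored
    integers; nothing is cached as a float.
    """

    endpoint: str
    before: dict  # label value -> count; sums to n_compounds
    predicted_positive: int = 0
    predicted_negative: int = 0
    predicted_uncertain: int = 0
    new_positive: int = 0
    new_negative: int = 0
    highconf_new_positive: int = 0
    highconf_new_negative: int = 0
    rule: HighConfidenceRule = field(default_factory=HighConfidenceRule)

    @property
    def n_compounds(self) -> int:
        return sum(self.before.values())

    @property
    def n_predicted(self) -> int:
        return (self.predicted_positive + self.predicted_negative
                + self.predicted_uncertain)

    @property
    def n_definite(self) -> int:
        return self.predicted_positive + self.predicted_negative

    @property
    def n_new(self) -> int:
        return self.new_positive + self.new_negative

    @property
    def n_highconf_new(self) -> int:
        return self.highconf_new_positive + self.highconf_new_negative

    @property
    def coverage_pct(self) -> float:
        """Share of predictions that are definite (non-uncertain)."""
        return 100.0 * self.n_definite / self.n_predicted if self.n_predicted else 0.0

    @property
    def filled_pct(self) -> float:
        """Share of previously uninformed pairs that gained a label."""
        noinfo = self.before.get(NO_INFORMATION, 0)
        return 100.0 * self.n_new / noinfo if noinfo else 0.0

    @property
    def filled_highconf_pct(self) -> float:
        noinfo = self.before.get(NO_INFORMATION, 0)
        return 100.0 * self.n_highconf_new / noinfo if noinfo else 0.0

    @property
    def positive_share_pct(self) -> float:
        """Positives among the definite newly assigned labels."""
        return 100.0 * self.new_positive / self.n_new if self.n_new else 0.0

    def after(self, high_confidence_only: bool = False) -> dict:
        """Label tally after merging predictions."""
        out = dict(self.before)
        pos = self.highconf_new_positive if high_confidence_only else self.new_positive
        neg = self.highconf_new_negative if high_confidence_only else self.new_negative
        out[YES] = out.get(YES, 0) + pos
        out[NO] = out.get(NO, 0) + neg
        out[NO_INFORMATION] = out.get(NO_INFORMATION, 0) - pos - neg
        return out

    @property
    def yes_plus_pending_before(self) -> int:
        """Combined positive-leaning stratum (YES + Pending)."""
        return self.before.get(YES, 0) + self.before.get(PENDING, 0)

    def as_dict(self, ndigits: int = 2) -> dict:
        return {
            "endpoint": self.endpoint,
            "before": dict(self.before),
            "predicted": {
                "positive": self.predicted_positive,
                "negative": self.predicted_negative,
                "uncertain": self.predicted_uncertain,
            },
            "new_labels": {"positive": self.new_positive, "negative": self.new_negative},
            "new_labels_highconf": {
                "positive": self.highconf_new_positive,
                "negative": self.highconf_new_negative,
            },
            "coverage_pct": round(self.coverage_pct, ndigits),
            "filled_pct": round(self.filled_pct, ndigits),
            "filled_highconf_pct": round(self.filled_highconf_pct, ndigits),
            "positive_share_pct": round(self.positive_share_pct, ndigits),
            "yes_plus_pending_before": self.yes_plus_pending_before,
        }


def annotated_share_pct(n_annotated: int, n_compounds: int,
                        n_endpoints: int = len(ENDPOINTS)) -> float:
    """Share of all possible (substance, endpoint) annotations covered."""
    total_possible = n_endpoints * n_compounds
    return 100.0 * n_annotated / total_possible if total_possible else 0.0


def account(
    before_labels: pd.DataFrame,
    predictions: pd.DataFrame,
    rule: Optional[HighConfidenceRule] = None,
    endpoint: Optional[str] = None,
) -> EndpointAccounting:
    """Build the before/after accounting for one endpoint.

    ``before_labels`` is the integrated label table; ``predictions`` is
    the output of :func:`predict_uninformed` (must carry confidence).
    Deterministic and invariant to prediction row order.
    """
    rule = rule or HighConfidenceRule()
    if endpoint is None:
        endpoints = set(predictions["endpoint"]) if len(predictions) else set()
        if len(endpoints) != 1:
            raise ValueError("endpoint is ambiguous; pass it explicitly")
        endpoint = endpoints.pop()
    ep_labels = before_labels[
        (before_labels["endpoint"] == endpoint)
        & (before_labels["provenance"] == "integrated")
    ]
    before = {v: 0 for v in (YES, NO, PENDING, NO_INFORMATION)}
    for value, count in ep_labels["value"].value_counts().items():
        before[value] = int(count)
    uninformed = set(ep_labels[ep_labels["value"] == NO_INFORMATION]["cas"])
    acc = EndpointAccounting(endpoint=endpoint, before=before, rule=rule)
    preds = predictions[predictions["endpoint"] == endpoint] if len(predictions) else predictions
    for r in preds.itertuples(index=False):
        if r.label == POSITIVE:
            acc.predicted_positive += 1
        elif r.label == NEGATIVE:
            acc.predicted_negative += 1
        else:
            acc.predicted_uncertain += 1
        if r.cas in uninformed and r.label != UNCERTAIN:
            high = rule.is_high(r.confidence_pct)
            if r.label == POSITIVE:
                acc.new_positive += 1
                acc.highconf_new_positive += high
            else:
                acc.new_negative += 1
                acc.highconf_new_negative += high
    return acc
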