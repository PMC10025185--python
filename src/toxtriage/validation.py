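"""Prospective-validation candidate selection and outcome comparison.

Predictions for uninformed substances are ranked by reliability
(significance first, confidence second) and the extremes of each
predicted class are selected: the most reliable calls should be
confirmed experimentally, the least reliable ones stress-test the
reliability estimates themselves.

Experimental assay outcomes are combined per endpoint convention:
CMR by logical OR over the carcinogenicity / micronucleus /
reprotoxicity assays (any positive makes the substance CMR-positive),
PBT by logical AND over persistence / bioaccumulation / toxicity (all
three required).  Missing outcomes yield *incomplete* rather than a
verdict whenever they could still change the conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

STRATUM_TOP = "top"
STRATUM_BOTTOM = "bottom"

CMR_ASSAYS = ("carcinogenicity", "micronucleus", "reprotoxicity")
PBT_ASSAYS = ("persistent", "bioaccumulative", "toxic")


def rank_candidates(predictions: pd.DataFrame, predicted_class: str) -> pd.DataFrame:
    """Filter to one predicted class and sort by reliability.

    Descending by (significance, confidence_pct); ties break by CAS
    ascending so the ranking is a total, reproducible order.
    """
    subset = predictions[predictions["label"] == predicted_class].copy()
    return subset.sort_values(
        by=["significance", "confidence_pct", "cas"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def select_validation_set(
    ranked_positives: pd.DataFrame,
    ranked_negatives: pd.DataFrame,
    n: int = 10,
) -> pd.DataFrame:
    """Top-n and bottom-n candidates from each ranked class.

    When a class has at most 2n entries the top and bottom strata
    overlap; overlapping rows are kept once, tagged with the stratum
    they entered first (top).
    """
    frames = []
    for ranked in (ranked_positives, ranked_negatives):
        if n == 0 or not len(ranked):
            continue
        top = ranked.head(n).copy()
        top["stratum"] = STRATUM_TOP
        bottom = ranked.tail(n).copy()
        bottom["stratum"] = STRATUM_BOTTOM
        combined = pd.concat([top, bottom], ignore_index=True)
        combined = combined.drop_duplicates(subset=["cas"], keep="first")
        frames.append(combined)
    if not frames:
        columns = list(ranked_positives.columns) + ["stratum"]
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)


def combine_assays(endpoint: str, outcomes: Mapping[str, Optional[bool]]) -> str:
    """Fold named boolean assay outcomes into one experimental verdict.

    CMR: OR — any positive outcome is decisive; all-negative requires
    every assay present.  PBT: AND — any negative outcome is decisive;
    a positive verdict requires all three present and positive.
    Otherwise the verdict is ``incomplete``.
    """
    if endpoint == "CMR":
        names = CMR_ASSAYS
        values = [outcomes.get(name) for name in names]
        if any(v is True for v in values):
            return "positive"
        if all(v is False for v in values):
            return "negative"
        return "incomplete"
    if endpoint == "PBT":
        names = PBT_ASSAYS
        values = [outcomes.get(name) for name in names]
        if any(v is False for v in values):
            return "negative"
        if all(v is True for v in values):
            return "positive"
        return "incomplete"
    raise ValueError(f"no assay combination rule for endpoint {endpoint!r}")


@dataclass
class StratumAgreement:
    stratum: str
    n: int
    agreements: list
    disagreements: list
    incompletes: list


def compare_predictions(
    experimental: pd.DataFrame,
    predictions: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Join experimental verdicts to predictions, stratified by stratum.

    ``experimental`` carries columns cas, verdict (positive / negative /
    incomplete); ``predictions`` carries cas, label, stratum.  Returns
    an agreement table (one row per stratum) and the list of unmatched
    CAS (reported, never dropped).
    """
    exp_by_cas = {r.cas: r.verdict for r in experimental.itertuples(index=False)}
    unmatched = sorted(
        set(exp_by_cas) - set(predictions["cas"]) if len(predictions) else set(exp_by_cas)
    )
    strata: dict[str, StratumAgreement] = {}
    for r in predictions.itertuples(index=False):
        stratum = getattr(r, "stratum", STRATUM_TOP)
        agg = strata.setdefault(
            stratum, StratumAgreement(stratum, 0, [], [], [])
        )
        verdict = exp_by_cas.get(r.cas)
        if verdict is None:
            unmatched.append(r.cas)
            continue
        agg.n += 1
        if verdict == "incomplete":
            agg.incompletes.append(r.cas)
        elif verdict == r.label:
            agg.agreements.append(r.cas)
        else:
            agg.disagreements.append(r.cas)
    rows = [
        {
            "stratum": s.stratum,
            "n": s.n,
            "agreements": len(s.agreements),
            "disagreements": len(s.disagreements),
            "incompletes": len(s.incompletes),
            "disagreement_cas": ";".join(s.disagreements),
            "incomplete_cas": ";".join(s.incompletes),
        }
        for s in strata.values()
    ]
    table = pd.DataFrame(
        rows,
        columns=["stratum", "n", "agreements", "disagreements", "incompletes",
                 "disagreement_cas", "incomplete_cas"],
    )
    return table, sorted(set(unmatched))
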