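"""Validation-candidate selection and assay-outcome combination."""

import pandas as pd
import pytest

from toxtriage.validation import (
    combine_assays,
    compare_predictions,
    rank_candidates,
    select_validation_set,
)


def pred_frame(rows):
    return pd.DataFrame(
        [{"cas": c, "label": lab, "significance": s, "confidence_pct": conf}
         for c, lab, s, conf in rows]
    )


class TestRankCandidates:
    def test_significance_primary(self):
        preds = pred_frame([
            ("5502-75-0", "negative", 0.978, 42.4),
            ("107-36-8", "negative", 0.997, 75.0),
        ])
        ranked = rank_candidates(preds, "negative")
        assert list(ranked["cas"]) == ["107-36-8", "5502-75-0"]

    def test_confidence_breaks_significance_ties(self):
        preds = pred_frame([
            ("2210-25-5", "negative", 0.997, 84.9),
            ("513-42-8", "negative", 0.997, 91.0),
        ])
        ranked = rank_candidates(preds, "negative")
        assert list(ranked["cas"]) == ["513-42-8", "2210-25-5"]

    def test_cas_breaks_remaining_ties(self):
        preds = pred_frame([
            ("98-95-3", "positive", 0.9, 50.0),
            ("103-26-4", "positive", 0.9, 50.0),
        ])
        ranked = rank_candidates(preds, "positive")
        assert list(ranked["cas"]) == ["103-26-4", "98-95-3"]

    def test_filters_to_requested_class_and_handles_empty(self):
        preds = pred_frame([("98-95-3", "positive", 0.9, 50.0)])
        assert len(rank_candidates(preds, "negative")) == 0


class TestSelectValidationSet:
    def big_ranked(self, label, n=25):
        return rank_candidates(
            pred_frame([
                (f"{100 + i}-00-{i % 10}", label, 1 - i * 0.01, 90 - i)
                for i in range(n)
            ]),
            label,
        )

    def test_twenty_plus_twenty_from_large_classes(self):
        selected = select_validation_set(
            self.big_ranked("positive"), self.big_ranked("negative"), n=10
        )
        assert len(selected) == 40
        by_class = selected.groupby("label").size()
        assert by_class["positive"] == by_class["negative"] == 20

    def test_small_class_deduplicates_overlap(self):
        ranked = self.big_ranked("positive", n=12)
        selected = select_validation_set(ranked, ranked.iloc[0:0], n=10)
        assert len(selected) == 12
        assert selected["cas"].is_unique

    def test_n_zero_selects_nothing(self):
        selected = select_validation_set(
            self.big_ranked("positive"), self.big_ranked("negative"), n=0
        )
        assert len(selected) == 0


class TestCombineAssays:
    def test_cmr_is_or_over_outcomes(self):
        verdict = combine_assays("CMR", {"carcinogenicity": True,
                                         "micronucleus": False,
                                         "reprotoxicity": True})
        assert verdict == "positive"

    def test_pbt_is_and_over_outcomes(self):
        assert combine_assays("PBT", {"persistent": True,
                                      "bioaccumulative": False,
                                      "toxic": True}) == "negative"
        assert combine_assays("PBT", {"persistent": True,
                                      "bioaccumulative": True,
                                      "toxic": True}) == "positive"

    def test_missing_outcomes_yield_incomplete_when_undecidable(self):
        assert combine_assays("CMR", {"carcinogenicity": False,
                                      "micronucleus": False}) == "incomplete"
        assert combine_assays("PBT", {"persistent": True,
                                      "bioaccumulative": True}) == "incomplete"

    def test_decisive_outcome_overrides_missing(self):
        # OR: one positive decides; AND: one negative decides
        assert combine_assays("CMR", {"carcinogenicity": True}) == "positive"
        assert combine_assays("PBT", {"bioaccumulative": False}) == "negative"

    def test_cmr_monotone_adding_positive_never_flips_to_negative(self):
        base = {"carcinogenicity": False, "micronucleus": False,
                "reprotoxicity": False}
        assert combine_assays("CMR", base) == "negative"
        assert combine_assays("CMR", {**base, "reprotoxicity": True}) == "positive"

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            combine_assays("vPvB", {})


class TestComparePredictions:
    def test_agreement_disagreement_incomplete(self):
        experimental = pd.DataFrame([
            {"cas": "104-75-6", "verdict": "positive"},
            {"cas": "94-47-3", "verdict": "negative"},
            {"cas": "877-38-3", "verdict": "incomplete"},
        ])
        predictions = pd.DataFrame([
            {"cas": "104-75-6", "label": "positive", "stratum": "top"},
            {"cas": "94-47-3", "label": "positive", "stratum": "bottom"},
            {"cas": "877-38-3", "label": "positive", "stratum": "top"},
        ])
        table, unmatched = compare_predictions(experimental, predictions)
        top = table[table["stratum"] == "top"].iloc[0]
        assert top["agreements"] == 1
        assert top["incompletes"] == 1  # not counted as disagreement
        bottom = table[table["stratum"] == "bottom"].iloc[0]
        assert bottom["disagreements"] == 1
        assert unmatched == []

    def test_unmatched_cas_reported_not_dropped(self):
        experimental = pd.DataFrame([{"cas": "50-00-0", "verdict": "positive"}])
        predictions = pd.DataFrame(
            [{"cas": "104-75-6", "label": "positive", "stratum": "top"}]
        )
        table, unmatched = compare_predictions(experimental, predictions)
        # unmatched on either side of the join is reported
        assert "50-00-0" in unmatched
        assert "104-75-6" in unmatched

    def test_empty_join(self):
        table, unmatched = compare_predictions(
            pd.DataFrame(columns=["cas", "verdict"]),
            pd.DataFrame(columns=["cas", "label", "stratum"]),
        )
        assert len(table) == 0
        assert unmatched == []
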