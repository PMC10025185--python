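"""Dataset construction, oversampling and balanced-subset partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxtriage.cas import format_cas
from toxtriage.datasets import (
    BinaryDataset,
    PartitionUnnecessaryError,
    UnmodelableEndpointError,
    extract_training_set,
    oversample,
    partition_ensemble,
)
from tests.conftest import make_labels


def make_dataset(n_pos, n_neg, endpoint="CMR"):
    rows = [
        {"cas": format_cas(1000 + i), "smiles": "CCO", "y": 1 if i < n_pos else 0}
        for i in range(n_pos + n_neg)
    ]
    return BinaryDataset(records=pd.DataFrame(rows), endpoint=endpoint)


def make_curation(cas_list):
    return pd.DataFrame(
        [{"cas": c, "category": "organic", "status": "ok",
          "canonical_smiles": "CCO"} for c in cas_list]
    )


class TestExtractTrainingSet:
    def labels(self):
        return make_labels([
            ("10-00-0", "CMR", "YES"),
            ("10-01-1", "CMR", "NO"),
            ("10-02-2", "CMR", "Pending"),
            ("10-03-3", "CMR", "NoInformation"),
            ("10-00-0", "PBT", "YES"),
            ("10-01-1", "PBT", "NO"),
            ("10-02-2", "PBT", "Pending"),
        ])

    def curation(self):
        return make_curation(["10-00-0", "10-01-1", "10-02-2", "10-03-3"])

    def test_cmr_pending_defaults_to_positive(self):
        ds, _ = extract_training_set(self.labels(), self.curation(), "CMR")
        pending_row = ds.records[ds.records["cas"] == "10-02-2"]
        assert list(pending_row["y"]) == [1]

    def test_other_endpoints_exclude_pending(self):
        ds, pred = extract_training_set(self.labels(), self.curation(), "PBT")
        assert "10-02-2" not in set(ds.records["cas"])
        assert "10-02-2" not in set(pred["cas"])

    def test_noinformation_goes_only_to_prediction_set(self):
        ds, pred = extract_training_set(self.labels(), self.curation(), "CMR")
        assert "10-03-3" not in set(ds.records["cas"])
        assert set(pred["cas"]) == {"10-03-3"}

    def test_training_and_prediction_sets_disjoint(self):
        ds, pred = extract_training_set(self.labels(), self.curation(), "CMR")
        assert not set(ds.records["cas"]) & set(pred["cas"])

    def test_single_class_endpoint_is_unmodelable(self):
        labels = make_labels([("10-00-0", "ED", "YES"), ("10-01-1", "ED", "YES")])
        with pytest.raises(UnmodelableEndpointError, match="read-across"):
            extract_training_set(labels, self.curation(), "ED")


class TestOversample:
    def test_minority_doubles_majority_untouched(self):
        out = oversample(make_dataset(5, 20))
        assert out.n_positive == 10
        assert out.n_negative == 20

    def test_balanced_input_unchanged_with_notice(self):
        ds = make_dataset(10, 10)
        with pytest.warns(UserWarning, match="no-op"):
            out = oversample(ds)
        assert len(out) == 20

    def test_added_records_are_copies_of_minority(self):
        ds = make_dataset(3, 8)
        out = oversample(ds)
        added = out.records.iloc[len(ds.records):]
        minority_cas = set(ds.records[ds.records["y"] == 1]["cas"])
        assert (added["y"] == 1).all()
        assert set(added["cas"]) <= minority_cas

    def test_deterministic(self):
        ds = make_dataset(4, 9)
        pd.testing.assert_frame_equal(oversample(ds).records,
                                      oversample(ds).records)


class TestPartitionEnsemble:
    def test_nine_pos_three_neg_three_subsets_cover_all_positives(self):
        partition = partition_ensemble(make_dataset(9, 3), 3, seed=1)
        union = set()
        for sub in partition.subsets:
            assert sub.n_positive == 3
            assert sub.n_negative == 3
            union |= set(sub.records[sub.records["y"] == 1]["cas"])
        assert len(union) == 9

    def test_six_pos_three_neg_three_subsets_with_overlap(self):
        ds = make_dataset(6, 3)
        partition = partition_ensemble(ds, 3, seed=2)
        union = set()
        for sub in partition.subsets:
            assert sub.n_positive == sub.n_negative == 3
            union |= set(sub.records[sub.records["y"] == 1]["cas"])
        assert union == set(ds.records[ds.records["y"] == 1]["cas"])

    def test_partition_unnecessary_when_negatives_dominate(self):
        with pytest.raises(PartitionUnnecessaryError):
            partition_ensemble(make_dataset(3, 5))

    def test_deterministic_given_seed(self):
        ds = make_dataset(11, 4)
        p1 = partition_ensemble(ds, seed=7)
        p2 = partition_ensemble(ds, seed=7)
        for a, b in zip(p1.subsets, p2.subsets):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_default_subset_count_has_floor_three(self):
        partition = partition_ensemble(make_dataset(5, 4), seed=0)
        assert len(partition.subsets) == 3


@given(
    n_pos=st.integers(min_value=2, max_value=40),
    n_neg=st.integers(min_value=1, max_value=20),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=120, derandomize=True, deadline=None)
def test_partition_invariants_hold_for_random_shapes(n_pos, n_neg, seed):
    """Every subset: all negatives + equal positives; union = all positives."""
    if n_pos <= n_neg:
        n_pos = n_neg + n_pos  # force the positive-heavy regime
    ds = make_dataset(n_pos, n_neg)
    partition = partition_ensemble(ds, seed=seed)
    negatives = set(ds.records[ds.records["y"] == 0]["cas"])
    union = set()
    for sub in partition.subsets:
        sub_neg = set(sub.records[sub.records["y"] == 0]["cas"])
        sub_pos = sub.records[sub.records["y"] == 1]
        assert sub_neg == negatives
        assert len(sub_pos) == len(negatives)
        assert sub_pos["cas"].is_unique
        union |= set(sub_pos["cas"])
    assert union == set(ds.records[ds.records["y"] == 1]["cas"])
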