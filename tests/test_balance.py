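import numpy as np
import pandas as pd
import pytest

from bioidkit import (
    BalanceConfig,
    REFERENCE_CLASS_COUNTS,
    balance_dataset,
    balanced_train_count,
    default_target,
    encode_table,
    imbalance_ratio,
    smote_class,
    stratified_split,
    train_test_counts,
)



class TestSplitArithmetic:
    @pytest.mark.parametrize("n, train, test", [(58, 41, 17), (10, 7, 3), (1, 1, 0)])
    def test_train_test_counts(self, n, train, test):
        assert train_test_counts(n, 0.3) == (train, test)

    def test_bad_fraction_rejected(self):
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                BalanceConfig(test_fraction=frac)

    def test_default_target_is_ceiling_of_mean(self):
        assert default_target(REFERENCE_CLASS_COUNTS) == 70_551
        assert default_target({"a": 3, "b": 4}) == 4


class TestClosedForm:
    def test_reference_target_reproduces_every_published_count(self, published_balanced):
        """The closed form train(n) + max(0, T - n) matches all 39 published
        balanced cells with T = ceiling of the mean class count."""
        T = default_target(REFERENCE_CLASS_COUNTS)
        for name, n in REFERENCE_CLASS_COUNTS.items():
            assert balanced_train_count(n, T) == published_balanced[name], name

    def test_minority_majority_and_midrange_examples(self):
        T = 70_551
        assert balanced_train_count(58, T) == 70_534  # extreme minority
        assert balanced_train_count(852_763, T) == 596_934  # majority, no undersampling
        assert balanced_train_count(39_780, T) == 58_617  # mid-range

    def test_boundary_class_at_target_gets_no_synthesis(self):
        T = 1000
        train, _ = train_test_counts(T, 0.3)
        assert balanced_train_count(T, T) == train

    def test_imbalance_reduction(self):
        T = default_target(REFERENCE_CLASS_COUNTS)
        after = {k: balanced_train_count(n, T) for k, n in REFERENCE_CLASS_COUNTS.items()}
        assert imbalance_ratio(after) <= imbalance_ratio(REFERENCE_CLASS_COUNTS)


@pytest.fixture(scope="module")
def encoded(registry):
    profile = {"ChEMBL": 40, "HGNC": 120, "Pfam": 80}
    table = registry.generate_dataset(profile, seed=3)
    return encode_table(table)


class TestStratifiedSplit:
    def test_per_class_counts_and_disjointness(self, encoded):
        train, test = stratified_split(encoded, 0.3, seed=5)
        train_counts = pd.Series(train.y).value_counts().to_dict()
        test_counts = pd.Series(test.y).value_counts().to_dict()
        assert train_counts == {"ChEMBL": 28, "HGNC": 84, "Pfam": 56}
        assert test_counts == {"ChEMBL": 12, "HGNC": 36, "Pfam": 24}
        assert len(train) + len(test) == len(encoded)

    def test_unlabelled_data_rejected(self, encoded):
        from bioidkit.preprocess import EncodedMatrix

        bare = EncodedMatrix(encoded.X, None, encoded.encoding)
        with pytest.raises(ValueError):
            stratified_split(bare, 0.3, seed=1)


class TestSmote:
    def test_zero_request_returns_empty(self):
        out = smote_class(np.array([[1, 2], [3, 4]]), 0)
        assert out.shape == (0, 2)

    def test_identical_parents_give_identical_child(self):
        X = np.array([[2, 5, 7], [2, 5, 7]])
        out = smote_class(X, 4, k=1, rng=0)
        assert (out == [2, 5, 7]).all()

    def test_convexity_per_coordinate(self):
        """Children of parents (1,3) and (1,5) keep coordinate 1 fixed and
        stay inside [3,5] on the second coordinate."""
        X = np.array([[1, 3], [1, 5]])
        out = smote_class(X, 200, k=1, rng=1)
        assert (out[:, 0] == 1).all()
        assert out[:, 1].min() >= 3 and out[:, 1].max() <= 5

    def test_children_are_valid_integer_codes(self, encoded):
        Xc = encoded.X[encoded.y == "HGNC"]
        out = smote_class(Xc, 500, k=5, rng=2)
        assert out.dtype == Xc.dtype
        assert set(np.unique(out)) <= set(range(0, encoded.encoding.max_code + 1))
        # per column, children stay within the parents' observed range
        assert (out.min(axis=0) >= Xc.min(axis=0)).all()
        assert (out.max(axis=0) <= Xc.max(axis=0)).all()

    def test_single_row_class_duplicates_with_warning(self):
        with pytest.warns(UserWarning, match="duplication"):
            out = smote_class(np.array([[4, 4]]), 3)
        assert (out == [4, 4]).all() and len(out) == 3

    def test_seed_determinism(self):
        X = np.arange(20).reshape(10, 2)
        a = smote_class(X, 50, k=3, rng=9)
        b = smote_class(X, 50, k=3, rng=9)
        assert (a == b).all()


class TestBalanceDataset:
    def test_counts_follow_closed_form_and_test_side_is_original(self, encoded):
        config = BalanceConfig(target=100, seed=7)
        split = balance_dataset(encoded, config)
        counts = pd.Series(split.train.y).value_counts().to_dict()
        for name, n in {"ChEMBL": 40, "HGNC": 120, "Pfam": 80}.items():
            assert counts[name] == balanced_train_count(n, 100)
        # every test row is an original encoded row
        originals = {tuple(r) for r in encoded.X}
        assert all(tuple(r) in originals for r in split.test.X)
        assert split.report.attrs["ratio_after"] <= split.report.attrs["ratio_before"]

    def test_undersampling_caps_majority_classes(self, encoded):
        config = BalanceConfig(target=50, undersample=True, undersample_ratio=1.0, seed=7)
        split = balance_dataset(encoded, config)
        counts = pd.Series(split.train.y).value_counts()
        assert counts.max() <= 50
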