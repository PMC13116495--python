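"""Synthetic cohort generator: counts, planted effects, splits, round trips."""

import numpy as np
import pandas as pd
import pytest

from ppcsurv import (
    LABEL_COLUMN,
    generate_cohort,
    make_config,
    read_cohort_csv,
    split_cohort,
    write_cohort_csv,
)
from ppcsurv.cohort import (
    CohortConfig,
    ConfigurationError,
    DegenerateSplitError,
    NumericEffect,
)
from ppcsurv.schema import FEATURE_NAMES


def test_exact_positive_count_and_schema_columns():
    table = generate_cohort(make_config(1000, 0.2, seed=7))
    assert int(table[LABEL_COLUMN].sum()) == 200
    assert tuple(table.columns[:-1]) == FEATURE_NAMES
    assert table.columns[-1] == LABEL_COLUMN
    assert not table.isna().any().any()


@pytest.mark.parametrize("seed", range(10))
def test_label_balance_exact_across_seeds(seed):
    table = generate_cohort(make_config(250, 0.2, seed=seed))
    assert int(table[LABEL_COLUMN].sum()) == 50


def test_reproducibility_same_config_same_cohort():
    a = generate_cohort(make_config(300, 0.2, seed=11))
    b = generate_cohort(make_config(300, 0.2, seed=11))
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(make_config(300, 0.2, seed=12))
    assert not a["Age"].equals(c["Age"])


def test_planted_age_shift_recovered():
    config = make_config(5000, 0.2, seed=3).with_shift("Age", 12.0)
    table = generate_cohort(config)
    pos = table[table[LABEL_COLUMN] == 1]["Age"].mean()
    neg = table[table[LABEL_COLUMN] == 0]["Age"].mean()
    assert abs((pos - neg) - 12.0) < 2.0


def test_planted_effect_monotonicity_sign_test():
    """A larger case shift must produce a larger class-conditional gap in
    the clear majority of seeds (sign test over paired draws)."""
    wins = 0
    for seed in range(10):
        gaps = []
        for shift in (4.0, 12.0):
            t = generate_cohort(make_config(5000, 0.2, seed=seed).with_shift("Age", shift))
            gaps.append(
                t[t[LABEL_COLUMN] == 1]["Age"].mean() - t[t[LABEL_COLUMN] == 0]["Age"].mean()
            )
        wins += gaps[1] > gaps[0]
    assert wins >= 9


def test_min_never_exceeds_max():
    table = generate_cohort(make_config(2000, 0.2, seed=5))
    for lo, hi in (("SBP_min", "SBP_max"), ("PR_min", "PR_max"), ("BT_min", "BT_max")):
        assert (table[lo] <= table[hi]).all()


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_patients=100, prevalence=0.0)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_patients=100, effect_profile={"NotAFeature": NumericEffect(0, 1)})
    with pytest.raises(ConfigurationError):
        make_config(100, 0.2, preset="bogus")


def test_split_counts_and_stratification():
    table = generate_cohort(make_config(100, 0.2, seed=0))
    train, test = split_cohort(table, 0.2, stratified=True, seed=0)
    assert (len(train), len(test)) == (80, 20)
    assert int(test[LABEL_COLUMN].sum()) == 4
    assert set(train.index).isdisjoint(test.index)
    # determinism
    train2, test2 = split_cohort(table, 0.2, stratified=True, seed=0)
    pd.testing.assert_frame_equal(test, test2)


def test_split_degenerate_class_raises():
    table = generate_cohort(make_config(100, 0.2, seed=0))
    tiny = pd.concat([table[table[LABEL_COLUMN] == 0].head(30),
                      table[table[LABEL_COLUMN] == 1].head(1)])
    with pytest.raises(DegenerateSplitError):
        split_cohort(tiny, 0.2, stratified=True, seed=0)


def test_csv_round_trip_preserves_values(tmp_path, schema):
    table = generate_cohort(make_config(150, 0.2, seed=9))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(table, path)
    back = read_cohort_csv(path, schema)
    for name in schema.numeric:
        np.testing.assert_allclose(
            back[name].to_numpy(float), table[name].to_numpy(float), rtol=0, atol=1e-9
        )
    for name in schema.boolean + (LABEL_COLUMN,):
        assert (back[name].astype(int) == table[name].astype(int)).all()
    for name in schema.categorical:
        assert (back[name] == table[name]).all()


def test_parquet_round_trip(tmp_path):
    pytest.importorskip("pyarrow")
    from ppcsurv.cohort import read_cohort_parquet, write_cohort_parquet

    table = generate_cohort(make_config(100, 0.2, seed=2))
    path = tmp_path / "cohort.parquet"
    write_cohort_parquet(table, path)
    pd.testing.assert_frame_equal(read_cohort_parquet(path), table)
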