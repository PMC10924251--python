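"""The log10 relative-fitness statistic, its uncertainty, and the synonymous null."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagedms.fitness import (
    CountTableError,
    LOW_COUNT_FLAG,
    SynonymousStats,
    fitness_score,
    fitness_se,
    fitness_table,
    fold_change,
    rereference,
    synonymous_stats,
)


class TestFitnessScore:
    @pytest.mark.parametrize(
        "v_in,v_out,r_in,r_out,expected",
        [
            (500, 500, 500, 500, 0.0),  # reference-rate variant scores 0
            (1000, 10, 1000, 1000, -2.0),  # 100-fold slower
            (300, 600, 600, 300, math.log10(2) - math.log10(0.5)),  # 0.602
        ],
    )
    def test_examples(self, v_in, v_out, r_in, r_out, expected):
        F, low = fitness_score(v_in, v_out, r_in, r_out)
        assert F == pytest.approx(expected, abs=1e-12)
        assert not low

    def test_pseudocount_only_on_zero_and_flagged(self):
        F_pure, low = fitness_score(100, 50, 100, 100)
        assert not low and F_pure == pytest.approx(math.log10(0.5))
        F_zero, low_zero = fitness_score(100, 0, 100, 100)
        assert low_zero
        assert F_zero == pytest.approx(math.log10(0.5 / 100.5) - math.log10(100.5 / 100.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(CountTableError):
            fitness_score(-1, 10, 10, 10)


class TestFoldChange:
    @pytest.mark.parametrize(
        "F,fold", [(-1.0, 0.1), (-2.0, 0.01), (0.0, 1.0), (2.5, 316.22776601683796)]
    )
    def test_examples(self, F, fold):
        assert fold_change(F) == pytest.approx(fold, rel=1e-12)

    def test_monotone(self):
        xs = np.linspace(-4, 4, 50)
        folds = [fold_change(x) for x in xs]
        assert all(a < b for a, b in zip(folds, folds[1:]))


class TestStandardError:
    def test_plug_in_value(self):
        se = fitness_se(100, 100, 100, 100)
        assert se == pytest.approx(math.sqrt(4 / 100) / math.log(10), rel=1e-12)
        assert se == pytest.approx(0.0869, abs=5e-4)

    def test_doubling_counts_scales_by_sqrt2(self):
        assert fitness_se(200, 200, 200, 200) == pytest.approx(
            fitness_se(100, 100, 100, 100) / math.sqrt(2)
        )

    def test_large_count_limit_and_zero_counts(self):
        assert fitness_se(10**9, 10**9, 10**9, 10**9) < 1e-4
        assert math.isnan(fitness_se(0, 10, 10, 10))


def _table(F_map, reference="wt", depth=10_000):
    rows = [{"variant_name": "wt", "input_count": depth, "output_count": depth}]
    for name, F in F_map.items():
        rows.append(
            {
                "variant_name": name,
                "input_count": depth,
                "output_count": int(round(depth * 10**F)),
            }
        )
    return pd.DataFrame(rows)


class TestFitnessTable:
    def test_reference_scores_exactly_zero(self):
        table = fitness_table(_table({"a": -1, "b": 0.5}), reference="wt")
        ref = table.set_index("variant_name").loc["wt"]
        assert ref["F"] == 0.0 and ref["fold"] == 1.0

    def test_zero_count_rows_flagged(self):
        counts = _table({"a": -1})
        counts.loc[counts["variant_name"] == "a", "output_count"] = 0
        table = fitness_table(counts, reference="wt")
        assert table.set_index("variant_name").loc["a", "flags"] == LOW_COUNT_FLAG

    def test_missing_reference_rejected(self):
        with pytest.raises(CountTableError, match="reference"):
            fitness_table(_table({"a": 0}), reference="nope")

    def test_replicates_combine_by_inverse_variance(self):
        # two replicates with different depths -> hand-computed weighted mean
        t1, t2 = _table({"a": -1.0}, depth=1000), _table({"a": -0.5}, depth=4000)
        t1["replicate"], t2["replicate"] = 1, 2
        combined = fitness_table(pd.concat([t1, t2]), reference="wt")
        rows = []
        for t in (t1, t2):
            v = t.set_index("variant_name")
            F, _ = fitness_score(
                v.loc["a", "input_count"], v.loc["a", "output_count"],
                v.loc["wt", "input_count"], v.loc["wt", "output_count"],
            )
            se = fitness_se(
                v.loc["a", "input_count"], v.loc["a", "output_count"],
                v.loc["wt", "input_count"], v.loc["wt", "output_count"],
            )
            rows.append((F, se))
        w = np.array([1 / se**2 for _, se in rows])
        expected = np.sum(w * np.array([F for F, _ in rows])) / w.sum()
        got = combined.set_index("variant_name").loc["a", "F"]
        assert got == pytest.approx(expected, rel=1e-12)


class TestRereference:
    def test_worked_example(self):
        table = pd.DataFrame(
            {"variant_name": ["A", "B", "C"], "F": [0.0, -3.7, -2.7],
             "se": [0.1] * 3, "fold": [1, 10**-3.7, 10**-2.7], "flags": [""] * 3}
        )
        out = rereference(table, "B").set_index("variant_name")
        assert out.loc["A", "F"] == pytest.approx(3.7)
        assert out.loc["B", "F"] == pytest.approx(0.0)
        assert out.loc["C", "F"] == pytest.approx(1.0)

    def test_identity_when_rereferencing_to_current(self):
        table = pd.DataFrame(
            {"variant_name": ["A", "B"], "F": [0.0, 1.2], "se": [0.1, 0.1],
             "fold": [1.0, 10**1.2], "flags": ["", ""]}
        )
        pd.testing.assert_frame_equal(rereference(table, "A"), table)

    def test_absent_reference_is_key_error(self):
        table = pd.DataFrame({"variant_name": ["A"], "F": [0.0]})
        with pytest.raises(KeyError):
            rereference(table, "Z")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        F=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        ref_idx=st.integers(0, 7),
    )
    def test_pairwise_differences_invariant(self, F, ref_idx):
        table = pd.DataFrame(
            {"variant_name": [f"v{i}" for i in range(len(F))], "F": F}
        )
        out = rereference(table, f"v{ref_idx % len(F)}")
        d_old = np.subtract.outer(table["F"].to_numpy(), table["F"].to_numpy())
        d_new = np.subtract.outer(out["F"].to_numpy(), out["F"].to_numpy())
        assert np.allclose(d_old, d_new)


class TestSynonymousStats:
    def test_degenerate_all_equal(self):
        table = pd.DataFrame({"variant_name": ["s1", "s2", "s3"], "F": [0.0] * 3})
        stats = synonymous_stats(table, ["s1", "s2", "s3"])
        assert (stats.band_lo, stats.band_hi) == (0.0, 0.0)
        assert stats.band_fold == 1.0

    def test_normal_null_recovers_fourfold_band(self, rng):
        # SD 0.2 under the 3-SD rule -> 10**0.6 ~ 3.98-fold, about 4-fold
        F = rng.normal(0.0, 0.2, size=200)
        table = pd.DataFrame(
            {"variant_name": [f"s{i}" for i in range(200)], "F": F}
        )
        stats = synonymous_stats(table, list(table["variant_name"]))
        # sample SD of n=200 draws: se(sd) ~ 0.2/sqrt(2*199) -> 3-sigma window
        assert 10 ** (3 * 0.2 - 9 * 0.01) < stats.band_fold < 10 ** (3 * 0.2 + 9 * 0.01)

    def test_translation_equivariance(self):
        base = pd.DataFrame({"variant_name": ["s1", "s2"], "F": [-0.1, 0.3]})
        shifted = base.assign(F=base["F"] + 0.7)
        a = synonymous_stats(base, ["s1", "s2"])
        b = synonymous_stats(shifted, ["s1", "s2"])
        assert b.mean_F == pytest.approx(a.mean_F + 0.7)
        assert b.band_lo == pytest.approx(a.band_lo + 0.7)
        assert b.band_hi == pytest.approx(a.band_hi + 0.7)
        assert b.band_fold == pytest.approx(a.band_fold)

    def test_too_few_synonymous_rejected(self):
        table = pd.DataFrame({"variant_name": ["s1"], "F": [0.0]})
        with pytest.raises(CountTableError):
            synonymous_stats(table, ["s1"])

    def test_band_symmetry_dataclass(self):
        s = SynonymousStats(n=10, mean_F=0.05, sd_F=0.2)
        assert s.band_hi - s.mean_F == pytest.approx(s.mean_F - s.band_lo)
        assert s.band_fold == pytest.approx(10**0.6)
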