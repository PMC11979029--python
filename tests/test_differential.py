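import numpy as np
import pandas as pd
import pytest

from evlong.differential import (
    annotation_percentage,
    missing_track,
    quant_track,
    rollup,
    run_differential,
)
from evlong.quantify import (
    PeptideQuantTable,
    SampleAnnotation,
    missingness_profile,
    stratify,
)
from evlong.synthetic_data import SyntheticConfig, generate_cohort


def _cohort(n_per_group, n_null, n_signal=0, seed=0, shift=10.0):
    """Complete table: n_null exchangeable peptides plus n_signal peptides
    fully separated between the groups (long above short)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    data = {f"N__{j}": rng.normal(size=n) for j in range(n_null)}
    for j in range(n_signal):
        base = rng.normal(size=n) * 0.1
        base[:n_per_group] += shift
        data[f"SIG__{j}"] = base
    table = PeptideQuantTable(pd.DataFrame(data, index=samples) + 100.0)
    annotation = SampleAnnotation(
        pd.DataFrame(
            {"group": ["long_lived"] * n_per_group + ["short_lived"] * n_per_group,
             "volume_for_20ug": 5.0},
            index=samples,
        )
    )
    return table, annotation


class TestQuantTrack:
    def test_many_separated_peptides_all_rejected_with_direction(self):
        # at n=4/group the exact min p is 2/70 ~ 0.0286; a block of separated
        # peptides jointly clears the BH step-up at q=0.05, and each carries
        # the higher_in_long direction
        table, annotation = _cohort(4, n_null=20, n_signal=30, seed=1)
        res = quant_track(table, annotation, table.peptide_ids, q_level=0.05)
        sig = res[res["peptide_id"].str.startswith("SIG")]
        assert sig["reject"].all()
        assert (sig["direction"] == "higher_in_long").all()
        null = res[res["peptide_id"].str.startswith("N")]
        assert not null["reject"].any()

    def test_exchangeable_groups_reject_nothing_at_strict_level(self):
        # min attainable p at 4v4 is 2/70 > 0.01, so q=0.01 can reject nothing
        table, annotation = _cohort(4, n_null=40, seed=2)
        res = quant_track(table, annotation, table.peptide_ids, q_level=0.01)
        assert not res["reject"].any()

    def test_missing_value_violates_stratification_contract(self, toy_table, toy_annotation):
        with pytest.raises(ValueError):
            quant_track(toy_table, toy_annotation, ["A__2"], q_level=0.05)

    def test_planted_shift_recovered_across_seeds(self):
        """2-SD standardized shifts at 24/group are recovered with the right
        direction in nearly every replicate."""
        hits = trials = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=900 + seed, n_proteins=100, peptides_per_protein_mean=10,
                frac_differential=0.02, effect_size=2.0,
                frac_informative_missing=0.0, n_markers=0,
            )
            bundle = generate_cohort(cfg)
            profile = missingness_profile(bundle.table, bundle.annotation)
            complete, _ = stratify(profile)
            res = quant_track(bundle.table, bundle.annotation, complete, q_level=0.01)
            res = res.set_index("peptide_id")
            planted = [
                p for p in bundle.truth.differential_peptide_ids if p in res.index
            ]
            for pid in planted:
                trials += 1
                row = res.loc[pid]
                if row["reject"] and row["direction"] == bundle.truth.differential_directions[pid]:
                    hits += 1
        assert trials > 100
        assert hits / trials >= 0.9


class TestMissingTrack:
    @staticmethod
    def _table_with_mask(mask_long, mask_short):
        n_long, n_short = len(mask_long), len(mask_short)
        samples = [f"l{i}" for i in range(n_long)] + [f"s{i}" for i in range(n_short)]
        values = np.ones(n_long + n_short)
        values[np.array(mask_long + mask_short, dtype=bool)] = np.nan
        rng = np.random.default_rng(0)
        table = PeptideQuantTable(
            pd.DataFrame({"P__1": values, "Q__1": rng.lognormal(size=len(values))},
                         index=samples)
        )
        annotation = SampleAnnotation(
            pd.DataFrame({"group": ["long_lived"] * n_long + ["short_lived"] * n_short,
                          "volume_for_20ug": 5.0}, index=samples)
        )
        return table, annotation

    def test_fully_separated_missingness_rejected_higher_in_long(self):
        # observed in all 24 long-lived, missing in all 24 short-lived
        table, annotation = self._table_with_mask([0] * 24, [1] * 24)
        res = missing_track(table, annotation, ["P__1"], q_level=0.01)
        row = res.set_index("peptide_id").loc["P__1"]
        assert row["reject"]
        assert row["direction"] == "higher_in_long"
        # chi2 closed form on (0,24,24,0): n(ad-bc)^2/prod(margins) = 48
        assert row["statistic"] == pytest.approx(48.0)

    def test_equal_missing_counts_give_p_one(self):
        table, annotation = self._table_with_mask([1, 1, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0])
        res = missing_track(table, annotation, ["P__1"], q_level=0.05)
        row = res.set_index("peptide_id").loc["P__1"]
        assert row["p"] == 1.0
        assert not row["reject"]

    def test_fully_observed_peptide_violates_contract(self):
        table, annotation = self._table_with_mask([1, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            missing_track(table, annotation, ["Q__1"], q_level=0.05)

    def test_all_missing_peptide_excluded_not_patched(self):
        samples = [f"x{i}" for i in range(8)]
        values = np.full(8, np.nan)
        table = PeptideQuantTable(
            pd.DataFrame({"P__1": values, "R__1": [np.nan, 1, 1, 1, 1, 1, 1, 1]},
                         index=samples)
        )
        annotation = SampleAnnotation(
            pd.DataFrame({"group": ["long_lived"] * 4 + ["short_lived"] * 4,
                          "volume_for_20ug": 5.0}, index=samples)
        )
        res = missing_track(table, annotation, ["P__1", "R__1"], q_level=0.05)
        assert list(res["peptide_id"]) == ["R__1"]


class TestFamilySeparation:
    def test_tracks_are_independent_bh_families(self, small_bundle):
        profile = missingness_profile(small_bundle.table, small_bundle.annotation)
        complete, incomplete = stratify(profile)
        miss_full = missing_track(
            small_bundle.table, small_bundle.annotation, incomplete, profile=profile
        )
        # shrink the quantitative family drastically; missingness q-values
        # must not move
        quant_small = quant_track(
            small_bundle.table, small_bundle.annotation, complete[:5]
        )
        miss_again = missing_track(
            small_bundle.table, small_bundle.annotation, incomplete, profile=profile
        )
        pd.testing.assert_frame_equal(miss_full, miss_again)
        assert len(quant_small) == 5


class TestRollup:
    def test_hand_counted_categories(self):
        results = pd.DataFrame(
            {
                "peptide_id": ["a__1", "a__2", "b__1", "c__1", "d__1"],
                "track": ["quantitative"] * 4 + ["missingness"],
                "reject": [True, True, True, True, False],
                "direction": ["higher_in_long", "higher_in_long", "higher_in_long",
                              "lower_in_long", "none"],
            }
        )
        mapping = {"a__1": "A", "a__2": "A", "b__1": "B", "c__1": "C", "d__1": "D"}
        counts = rollup(results, mapping).table
        assert counts.loc[("quantitative", "higher_in_long"), "n_peptides"] == 3
        assert counts.loc[("quantitative", "higher_in_long"), "n_proteins"] == 2
        assert counts.loc[("quantitative", "lower_in_long"), "n_peptides"] == 1
        assert counts.loc[("quantitative", "lower_in_long"), "n_proteins"] == 1
        assert counts["n_peptides"].sum() == 4

    def test_protein_counted_once_per_category(self):
        results = pd.DataFrame(
            {
                "peptide_id": ["a__1", "a__2"],
                "track": ["quantitative"] * 2,
                "reject": [True, True],
                "direction": ["higher_in_long", "lower_in_long"],
            }
        )
        counts = rollup(results, {"a__1": "A", "a__2": "A"}).table
        assert counts.loc[("quantitative", "higher_in_long"), "n_proteins"] == 1
        assert counts.loc[("quantitative", "lower_in_long"), "n_proteins"] == 1

    def test_no_rejections_all_zero(self):
        results = pd.DataFrame(
            {"peptide_id": ["a__1"], "track": ["quantitative"],
             "reject": [False], "direction": ["none"]}
        )
        counts = rollup(results, {"a__1": "A"}).table
        assert (counts == 0).all().all()

    def test_unmapped_rejected_peptide_is_an_error(self):
        results = pd.DataFrame(
            {"peptide_id": ["a__1"], "track": ["quantitative"],
             "reject": [True], "direction": ["higher_in_long"]}
        )
        with pytest.raises(ValueError):
            rollup(results, {})


class TestAnnotationPercentage:
    def test_share_rounded_to_one_decimal(self):
        assert annotation_percentage(1, 3) == 33.3

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            annotation_percentage(5, 4)
        with pytest.raises(ValueError):
            annotation_percentage(1, 0)


def test_run_differential_covers_every_testable_peptide(small_bundle):
    res = run_differential(small_bundle.table, small_bundle.annotation)
    profile = missingness_profile(small_bundle.table, small_bundle.annotation)
    complete, incomplete = stratify(profile)
    assert set(res[res["track"] == "quantitative"]["peptide_id"]) == set(complete)
    # incomplete peptides appear unless degenerate (all-missing)
    tested = set(res[res["track"] == "missingness"]["peptide_id"])
    assert tested <= set(incomplete)
    assert (res["q"] >= res["p"] - 1e-15).all()
    assert ((res["direction"] == "none") == ~res["reject"]).all()
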