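"""Tests for the all-2-one sweep, consistency filter, ranking and cuts."""

import math

import numpy as np
import pandas as pd
import pytest

from regscreen.dynamics import PairwiseFit, PairwiseModel, SeriesPair, fit_with_delay_scan
from regscreen.screen import (
    ScreenConfig,
    ScreenTable,
    all2one,
    candidate_filters,
    collapse_to_genes,
    consistency_filter,
    rank_models,
    top_percentile,
)
from regscreen.synth import TARGET_IDS, SynthTruth, generate_screen_dataset


def _fit(input_id, output_id, donor_id, beta=1.0, fitness=50.0, degenerate=False,
         delay=0):
    model = PairwiseModel(0.5, beta, 0.0, delay)
    sign = None if degenerate else ("activator" if beta > 0 else "repressor")
    return PairwiseFit(
        model=model,
        fitness=math.nan if degenerate else fitness,
        sign=sign,
        n_fit_points=19 - delay,
        degenerate=degenerate,
        input_id=input_id,
        output_id=output_id,
        donor_id=donor_id,
    )


def _table(fitness_values, ids=None, symbols=None, delays=None):
    n = len(fitness_values)
    ids = ids or [f"T{i}" for i in range(n)]
    df = pd.DataFrame({
        "rank": np.arange(1, n + 1),
        "input_id": ids,
        "gene_symbol": symbols or ids,
        "output_id": "OUT",
        "delay_min": delays or [40.0] * n,
        "fitness": fitness_values,
        "sign": "activator",
    })
    return ScreenTable(df)


@pytest.fixture(scope="module")
def small_world():
    """Noiseless screen world: 1 planted regulator, 10 decoys, 2 donors."""
    truth = SynthTruth.create(n_true=1, n_decoys=10, noise_frac_of_sd=0.0, seed=21)
    datasets, truth = generate_screen_dataset(truth)
    return datasets, truth


class TestAll2One:
    def test_fit_count(self, small_world):
        datasets, truth = small_world
        cfg = ScreenConfig(target_output_ids=TARGET_IDS)
        fits = all2one(datasets, cfg)
        # 11 inputs x 2 outputs x 2 donors
        assert len(fits) == 11 * 2 * 2

    def test_targets_never_their_own_inputs(self, small_world):
        datasets, _ = small_world
        cfg = ScreenConfig(target_output_ids=TARGET_IDS)
        fits = all2one(datasets, cfg)
        assert not any(f.input_id in TARGET_IDS for f in fits)

    def test_missing_target_named(self, small_world):
        datasets, _ = small_world
        cfg = ScreenConfig(target_output_ids=("NOPE",))
        with pytest.raises(ValueError, match="NOPE"):
            all2one(datasets, cfg)

    def test_noiseless_true_regulator_fits_perfectly(self, small_world):
        datasets, truth = small_world
        cfg = ScreenConfig(target_output_ids=TARGET_IDS)
        fits = all2one(datasets, cfg)
        reg = [f for f in fits if f.input_id == "REG_01"]
        assert len(reg) == 4
        for f in reg:
            assert f.fitness == pytest.approx(100.0, abs=1e-7)
            truth_model = truth.models[f.donor_id]["REG_01"]
            assert f.model.delay_steps == truth_model.delay_steps
            assert f.sign == truth_model.sign

    def test_batched_path_matches_per_pair_fits(self, small_world):
        """The vectorised sweep is numerically identical to fit_with_delay_scan."""
        datasets, _ = small_world
        cfg = ScreenConfig(target_output_ids=TARGET_IDS)
        fits = all2one(datasets, cfg)
        grid = datasets[0].grid
        delays = [grid.delay_min_to_steps(d) for d in cfg.delay_grid_min]
        checked = 0
        for f in fits:
            ds = next(d for d in datasets if d.donor_id == f.donor_id)
            pair = SeriesPair(ds.series(f.input_id), ds.series(f.output_id))
            ref = fit_with_delay_scan(pair, delays)
            assert f.degenerate == ref.degenerate
            if not ref.degenerate:
                assert f.model.delay_steps == ref.model.delay_steps
                np.testing.assert_allclose(
                    [f.model.alpha, f.model.beta, f.model.gamma, f.fitness],
                    [ref.model.alpha, ref.model.beta, ref.model.gamma, ref.fitness],
                    rtol=1e-8, atol=1e-10,
                )
            checked += 1
        assert checked == len(fits)

    def test_mismatched_orderings_rejected(self, small_world):
        datasets, _ = small_world
        reversed_ds = datasets[1].subset(list(reversed(datasets[1].transcript_ids)))
        cfg = ScreenConfig(target_output_ids=TARGET_IDS)
        with pytest.raises(ValueError, match="ordering"):
            all2one([datasets[0], reversed_ds], cfg)


class TestConsistencyFilter:
    CFG = ScreenConfig(target_output_ids=("O1", "O2"))

    def test_agreeing_signs_kept(self):
        fits = [_fit("g", o, d, beta=+1) for o in ("O1", "O2") for d in ("d1", "d2")]
        kept, discarded = consistency_filter(fits, self.CFG)
        assert len(kept) == 4 and not discarded

    def test_disagreeing_sign_on_one_output_discards_all(self):
        fits = [
            _fit("g", "O1", "d1", beta=+1),
            _fit("g", "O1", "d2", beta=-1),
            _fit("g", "O2", "d1", beta=+1),
            _fit("g", "O2", "d2", beta=+1),
        ]
        kept, discarded = consistency_filter(fits, self.CFG)
        assert kept == [] and "g" in discarded

    def test_degenerate_fit_discards_input(self):
        fits = [
            _fit("g", "O1", "d1", beta=+1),
            _fit("g", "O1", "d2", degenerate=True),
        ]
        kept, discarded = consistency_filter(fits, self.CFG)
        assert kept == [] and "degenerate" in discarded["g"]

    def test_per_output_rule_does_not_require_cross_output_agreement(self):
        # activator toward O1, repressor toward O2, consistently in both donors
        fits = [_fit("g", "O1", d, beta=+1) for d in ("d1", "d2")]
        fits += [_fit("g", "O2", d, beta=-1) for d in ("d1", "d2")]
        kept, discarded = consistency_filter(fits, self.CFG)
        assert len(kept) == 4 and not discarded


class TestRankModels:
    CFG = ScreenConfig(target_output_ids=("O1",), ranking_donor="d2")

    def test_descending_rank_permutation(self):
        fits = [
            _fit("a", "O1", "d2", fitness=50.0),
            _fit("b", "O1", "d2", fitness=60.0),
            _fit("c", "O1", "d2", fitness=40.0),
        ]
        table = rank_models(fits, self.CFG)
        assert table.df["input_id"].tolist() == ["b", "a", "c"]
        assert table.df["rank"].tolist() == [1, 2, 3]

    def test_ties_broken_lexicographically(self):
        fits = [
            _fit("zzz", "O1", "d2", fitness=50.0),
            _fit("aaa", "O1", "d2", fitness=50.0),
        ]
        table = rank_models(fits, self.CFG)
        assert table.df["input_id"].tolist() == ["aaa", "zzz"]

    def test_other_donor_fitness_carried(self):
        fits = [
            _fit("a", "O1", "d2", fitness=50.0),
            _fit("a", "O1", "d1", fitness=33.0),
        ]
        table = rank_models(fits, self.CFG)
        assert table.df.loc[0, "fitness_d1"] == 33.0
        assert len(table) == 1  # only the ranking donor's models become rows

    def test_empty_input_empty_table(self):
        assert len(rank_models([], self.CFG)) == 0

    def test_deterministic(self):
        fits = [_fit(f"t{i}", "O1", "d2", fitness=float(i % 7)) for i in range(30)]
        t1 = rank_models(list(fits), self.CFG)
        t2 = rank_models(list(reversed(fits)), self.CFG)
        pd.testing.assert_frame_equal(t1.df, t2.df)


class TestTopPercentile:
    def test_7030_rows_cut_to_176(self):
        table = _table(np.linspace(70, 40, 7030))
        assert len(top_percentile(table, 0.025)) == 176

    def test_ceiling_on_small_table(self):
        table = _table(np.linspace(70, 40, 100))
        assert len(top_percentile(table, 0.025)) == 3

    def test_fraction_one_keeps_all(self):
        table = _table(np.linspace(70, 40, 10))
        assert len(top_percentile(table, 1.0)) == 10


class TestCollapseToGenes:
    def test_unique_symbols_identity(self):
        table = _table([60.0, 50.0, 40.0], symbols=["G1", "G2", "G3"])
        summary = collapse_to_genes(table)
        assert summary.n_distinct == 3 and summary.n_collapsed == 0

    def test_duplicate_gene_keeps_best_rank(self):
        table = _table(
            [60.0, 50.0, 40.0], ids=["t1", "t2", "t3"], symbols=["G", "X", "G"]
        )
        summary = collapse_to_genes(table)
        assert summary.n_distinct == 2
        g_row = summary.df[summary.df["identity"] == "G"]
        assert g_row["rank"].item() == 1

    def test_missing_symbol_keeps_probe_identity(self):
        table = _table([60.0, 50.0], ids=["123_at", "t2"], symbols=["", "G"])
        summary = collapse_to_genes(table)
        assert set(summary.df["identity"]) == {"123_at", "G"}


class TestCandidateFilters:
    def test_multi_gene_rows_dropped(self):
        table = _table([60.0, 50.0], symbols=["A///B", "C"])
        out = candidate_filters(table)
        assert out.df["gene_symbol"].tolist() == ["C"]

    def test_delay_window(self):
        table = _table([60.0, 50.0, 40.0], delays=[100.0, 40.0, 0.0])
        out = candidate_filters(table, delay_window_min=(20, 60))
        assert out.df["delay_min"].tolist() == [40.0]

    def test_full_window_no_delay_drops(self):
        table = _table([60.0, 50.0, 40.0], delays=[100.0, 40.0, 0.0])
        out = candidate_filters(table, delay_window_min=(0, 100), exclude_multi_gene=False)
        assert len(out) == 3


def test_count_bookkeeping_retained_inputs_times_outputs(small_world):
    datasets, _ = small_world
    cfg = ScreenConfig(target_output_ids=TARGET_IDS)
    fits = all2one(datasets, cfg)
    kept, discarded = consistency_filter(fits, cfg)
    n_inputs_total = len({f.input_id for f in fits})
    n_retained = n_inputs_total - len(discarded)
    table = rank_models(kept, cfg)
    assert len(table) == n_retained * len(TARGET_IDS)


def test_screen_table_rejects_unsorted_fitness():
    df = pd.DataFrame({"rank": [1, 2], "fitness": [10.0, 20.0]})
    with pytest.raises(ValueError):
        ScreenTable(df)
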