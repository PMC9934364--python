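"""Search protocols: space enumeration, halving schedule, meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from epishape.model_zoo import ArchSpec
from epishape.search import (
    GRID_FILTERS,
    HYPERBAND_FILTERS,
    KERNEL_SIZES,
    enumerate_space,
    fit_meta_tree,
    grid_search,
    hyperband,
    successive_halving,
)
from epishape.train_eval import TrainConfig


class TestEnumerateSpace:
    def test_cardinalities(self):
        assert len(enumerate_space(1, GRID_FILTERS, KERNEL_SIZES)) == 30
        assert len(enumerate_space(2, GRID_FILTERS, KERNEL_SIZES)) == 900
        assert len(enumerate_space(3, HYPERBAND_FILTERS, KERNEL_SIZES)) == 15_625

    def test_deterministic_order(self):
        a = enumerate_space(1, (2, 4), (3, 5))
        b = enumerate_space(1, (2, 4), (3, 5))
        assert a == b
        assert a[0].blocks == ((2, 3),)
        assert a[-1].blocks == ((4, 5),)

    def test_all_specs_valid(self):
        for arch in enumerate_space(2, (2, 64), (3, 11)):
            assert arch.n_layers == 2


class TestSuccessiveHalving:
    def test_trace_matches_hand_simulation(self):
        """Injected losses reproduce the exact halving schedule."""
        # candidate i has loss i at any budget; 8 candidates, eta=2
        cands = list(range(8))
        calls = []

        def trainer(c, r):
            calls.append((c, r))
            return float(c)

        trace = successive_halving(cands, trainer, r_min=5, r_max=40, eta=2)
        budgets = [t[0] for t in trace]
        survivors = [[c for _, c in t[1]] for t in trace]
        assert budgets == [5, 10, 20, 40]
        assert survivors[0] == [0, 1, 2, 3, 4, 5, 6, 7]
        assert survivors[1] == [0, 1, 2, 3]
        assert survivors[2] == [0, 1]
        assert survivors[3] == [0]
        # every rung evaluates exactly its survivor set
        assert calls == (
            [(c, 5) for c in range(8)] + [(c, 10) for c in range(4)]
            + [(c, 20) for c in range(2)] + [(0, 40)]
        )

    def test_budget_dependent_losses_can_reorder(self):
        # a candidate that looks bad early but improves with budget survives
        # only if it makes the cut at the early rung
        losses = {(0, 2): 1.0, (1, 2): 0.5, (1, 4): 0.1}
        trace = successive_halving([0, 1], lambda c, r: losses[(c, r)],
                                   r_min=2, r_max=8, eta=2)
        assert [t[0] for t in trace] == [2, 4]  # lone survivor stops early
        assert [c for _, c in trace[-1][1]] == [1]

    def test_single_candidate(self):
        trace = successive_halving(["a"], lambda c, r: 0.0, 1, 4, eta=2)
        assert [t[0] for t in trace] == [1]  # lone survivor: no further rungs


class TestHyperband:
    def _space(self):
        return enumerate_space(1, (2, 4, 8, 16), (3, 5), input_size=32)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            hyperband([], train_to_budget=lambda a, r: 0.0)

    def test_single_spec_space(self):
        space = [ArchSpec([(4, 3)], input_size=32)]
        calls = []

        def trainer(arch, epochs):
            calls.append(epochs)
            return 1.0

        res = hyperband(space, train_to_budget=trainer, max_epochs=8, seed=0)
        assert res.best == space[0]
        assert max(calls) == 8

    def test_deterministic_sampling(self):
        space = self._space()
        seen = []

        def trainer(arch, epochs):
            seen.append((arch.blocks, epochs))
            return float(arch.blocks[0][0])

        hyperband(space, train_to_budget=trainer, max_epochs=8, seed=4)
        first = list(seen)
        seen.clear()
        hyperband(space, train_to_budget=trainer, max_epochs=8, seed=4)
        assert seen == first

    def test_total_budget_bounded(self):
        space = self._space()
        total = {"epochs": 0}

        def trainer(arch, epochs):
            total["epochs"] += epochs
            return float(np.sum(arch.blocks))

        R, eta = 16, 2
        hyperband(space, train_to_budget=trainer, max_epochs=R, eta=eta, seed=0)
        s_max = int(np.floor(np.log(R) / np.log(eta)))
        assert total["epochs"] <= (s_max + 1) ** 2 * R * eta  # schedule bound

    def test_best_tracks_lowest_loss(self):
        space = self._space()
        improvements = []
        res = hyperband(
            space,
            train_to_budget=lambda a, r: float(np.sum(a.blocks)),
            max_epochs=8,
            seed=1,
            on_improvement=lambda arch, loss: improvements.append(loss),
        )
        assert improvements == sorted(improvements, reverse=True)
        table = res.sorted()
        assert table.iloc[0]["mae_mean"] == min(table["mae_mean"])


class TestGridSearch:
    def test_reduced_grid_finds_argmin(self, small_dataset):
        space = enumerate_space(1, (2, 8), (3, 5), input_size=64)
        ds = small_dataset.subset(np.arange(40))
        res = grid_search(space, ds, TrainConfig(max_epochs=1, seed=0))
        assert len(res.table) == 4
        best_row = res.sorted().iloc[0]
        assert best_row["mae_mean"] == res.table["mae_mean"].min()

    def test_pivot_is_group_mean(self):
        table = pd.DataFrame(
            dict(
                n1=[2, 2, 4, 4], k1=[3, 5, 3, 5], n2=[8, 8, 8, 8], k2=[3, 3, 3, 3],
                mae_mean=[1.0, 2.0, 3.0, 5.0], trainable_params=[1, 2, 3, 4],
                arch=list("abcd"),
            )
        )
        from epishape.search import SearchResult

        piv = SearchResult(table=table).pivot("filters")
        assert piv.loc[2, 8] == pytest.approx(1.5)
        assert piv.loc[4, 8] == pytest.approx(4.0)

    def test_resume_skips_completed_rows(self, small_dataset, tmp_path):
        space = enumerate_space(1, (2, 4), (3,), input_size=64)
        ds = small_dataset.subset(np.arange(40))
        csv = tmp_path / "scores.csv"
        r1 = grid_search(space, ds, TrainConfig(max_epochs=1, seed=0), csv_path=csv)
        # drop one row and resume: only that row is recomputed
        pd.read_csv(csv).iloc[:1].to_csv(csv, index=False)
        r2 = grid_search(space, ds, TrainConfig(max_epochs=1, seed=0), csv_path=csv)
        pd.testing.assert_frame_equal(
            r1.table.reset_index(drop=True),
            r2.table[r1.table.columns].reset_index(drop=True),
            check_dtype=False,
        )


class TestMetaTree:
    @staticmethod
    def _table(rng, f=None):
        rows = []
        for n1 in (2, 4, 8, 16, 32, 64):
            for k1 in KERNEL_SIZES:
                for n2 in (2, 4, 8, 16, 32, 64):
                    for k2 in KERNEL_SIZES:
                        mae = f(n1, k1, n2, k2) if f else rng.random()
                        rows.append(dict(n1=n1, k1=k1, n2=n2, k2=k2, mae_mean=mae))
        return pd.DataFrame(rows)

    def test_importance_concentrates_on_driving_parameter(self, rng):
        """MAE depending only on n2 gives n2 importance ~ 1."""
        table = self._table(rng, f=lambda n1, k1, n2, k2: 1.0 / n2)
        meta = fit_meta_tree(table, seed=0)
        assert meta.importances["n2"] > 0.9
        assert all(v < 0.05 for k, v in meta.importances.items() if k != "n2")
        assert meta.pearson["n2"] < 0  # larger n2, lower MAE

    def test_memorization_at_full_depth(self, rng):
        table = self._table(rng)
        meta = fit_meta_tree(table, train_fraction=0.7, seed=1)
        from sklearn.model_selection import train_test_split

        X = table[["n1", "k1", "n2", "k2"]].to_numpy(float)
        y = table["mae_mean"].to_numpy()
        Xtr, _, ytr, _ = train_test_split(X, y, train_size=0.7, random_state=1)
        assert np.allclose(meta.tree.predict(Xtr), ytr)

    def test_noise_parameter_uncorrelated(self, rng):
        table = self._table(rng, f=lambda n1, k1, n2, k2: 1.0 / n2)
        table["mae_mean"] += rng.normal(0, 1e-3, len(table))
        meta = fit_meta_tree(table, seed=0)
        assert abs(meta.pearson["k1"]) < 0.2
        assert sum(meta.importances.values()) == pytest.approx(1.0)

    def test_constant_target_rejected(self):
        table = pd.DataFrame(dict(n1=[2, 4], k1=[3, 3], mae_mean=[1.0, 1.0]))
        with pytest.raises(ValueError):
            fit_meta_tree(table)
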