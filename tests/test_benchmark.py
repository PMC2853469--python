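import io
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cbpot.benchmark import (
    CandidateModel,
    DecoyRecord,
    DecoySet,
    assign_ranks,
    gdt_ts,
    rank_of_selection,
    read_manifest,
    read_scores,
    select_decoys,
    summarize,
    wilcoxon_one_tailed,
    write_manifest,
    write_scores,
)


def _set(target, gdts, native=False):
    records = [DecoyRecord(f"{target}_m{k}", g) for k, g in enumerate(gdts)]
    if native:
        records.append(DecoyRecord(f"{target}_native", 100.0, is_native=True))
    return DecoySet(target, records)


class TestGdtTs:
    def test_native_identity(self):
        assert gdt_ts(100, 100, 100, 100) == 100

    def test_arithmetic(self):
        assert gdt_ts(40, 60, 80, 100) == 70

    def test_zero(self):
        assert gdt_ts(0, 0, 0, 0) == 0

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            gdt_ts(50, 40, 80, 100)

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            gdt_ts(-1, 0, 0, 0)


class TestAssignRanks:
    def test_binning_example(self):
        ds = _set("t", [82.0, 80.1, 79.0])
        ranks = assign_ranks(ds)
        assert ranks["t_m0"] == 1
        assert ranks["t_m1"] == 1  # delta 1.9 < 2.5
        assert ranks["t_m2"] == 2

    def test_native_to_65_is_14_bins(self):
        ds = _set("t", [65.0], native=True)
        ranks = assign_ranks(ds)
        assert ranks["t_native"] == 1
        assert ranks["t_m0"] == 15
        assert ranks["t_m0"] - ranks["t_native"] == 14

    def test_all_equal_rank_one(self):
        ds = _set("t", [50.0, 50.0, 50.0])
        assert set(assign_ranks(ds).values()) == {1}

    def test_translation_invariance(self, rng):
        for _ in range(50):
            g = rng.uniform(30, 90, size=6)
            shift = float(rng.uniform(-20, 5))
            r0 = assign_ranks([DecoyRecord(f"m{k}", v) for k, v in enumerate(g)])
            r1 = assign_ranks([DecoyRecord(f"m{k}", v + shift) for k, v in enumerate(g)])
            assert r0 == r1

    def test_rank_bounds(self, rng):
        for _ in range(50):
            g = rng.uniform(20, 95, size=8)
            ranks = assign_ranks([DecoyRecord(f"m{k}", v) for k, v in enumerate(g)])
            assert min(ranks.values()) == 1
            assert max(ranks.values()) == 1 + math.floor((g.max() - g.min()) / 2.5 + 1e-9)


class TestRankOfSelection:
    def test_native_lowest_energy(self):
        ds = _set("t", [70.0, 50.0], native=True)
        energies = {"t_m0": -1.0, "t_m1": 0.0, "t_native": -5.0}
        assert rank_of_selection(ds, energies, "with_native") == 1

    def test_best_non_native_gets_rank_two(self):
        ds = _set("t", [70.0, 50.0], native=True)
        energies = {"t_m0": -5.0, "t_m1": 0.0, "t_native": -1.0}
        assert rank_of_selection(ds, energies, "with_native") == 2

    def test_worse_non_native_offset(self):
        ds = _set("t", [70.0, 50.0], native=True)
        energies = {"t_m0": 0.0, "t_m1": -5.0, "t_native": -1.0}
        # the 50.0 model is 8 bins below the best non-native -> rank 9 + 1
        assert rank_of_selection(ds, energies, "with_native") == 10

    def test_without_native_anticorrelated(self):
        gdts = [80.0, 72.0, 64.0, 55.0, 41.0]
        ds = _set("t", gdts)
        energies = {f"t_m{k}": float(g) for k, g in enumerate(gdts)}  # worst picked
        got = rank_of_selection(ds, energies, "without_native")
        assert got == assign_ranks(ds)["t_m4"]

    def test_monotone_energy_transform_invariance(self, rng):
        ds = _set("t", list(rng.uniform(30, 90, size=6)))
        e = {f"t_m{k}": float(v) for k, v in enumerate(rng.normal(size=6))}
        base = rank_of_selection(ds, e, "without_native")
        for f in (lambda x: 3 * x + 7, math.exp, lambda x: x**3):
            assert rank_of_selection(ds, {k: f(v) for k, v in e.items()}, "without_native") == base

    def test_with_native_requires_native(self):
        ds = _set("t", [70.0, 50.0])
        with pytest.raises(ValueError, match="no native"):
            rank_of_selection(ds, {"t_m0": 0.0, "t_m1": 1.0}, "with_native")

    def test_energy_tie_broken_by_model_id(self):
        ds = _set("t", [80.0, 40.0])
        energies = {"t_m0": 1.0, "t_m1": 1.0}
        # lexicographic: t_m0 wins the tie -> rank 1
        assert rank_of_selection(ds, energies, "without_native") == 1


class TestSummarize:
    def _toy_sets(self):
        return [
            _set("t1", [80.0, 70.0, 60.0]),
            _set("t2", [75.0, 74.0, 40.0]),
            _set("t3", [90.0, 65.0]),
        ]

    def test_oracle_scorer(self):
        sets = self._toy_sets()
        energies = {
            ds.target_id: {r.model_id: -r.gdt_ts for r in ds.records} for ds in sets
        }
        s = summarize(sets, energies, "without_native")
        assert s.average_rank == 1.0
        assert s.ranked_1_count == len(sets)

    def test_worst_case_scorer(self):
        sets = self._toy_sets()
        energies = {
            ds.target_id: {r.model_id: +r.gdt_ts for r in ds.records} for ds in sets
        }
        s = summarize(sets, energies, "without_native")
        expected = np.mean([max(assign_ranks(ds).values()) for ds in sets])
        assert s.average_rank == pytest.approx(expected)

    def test_random_scorer_matches_enumeration(self):
        # expectation over all energy orderings == mean of per-model ranks
        sets = self._toy_sets()
        for ds in sets:
            ids = [r.model_id for r in ds.records]
            total = 0.0
            n_perm = 0
            for perm in itertools.permutations(range(len(ids))):
                energies = {mid: float(p) for mid, p in zip(ids, perm)}
                total += rank_of_selection(ds, energies, "without_native")
                n_perm += 1
            enum_mean = total / n_perm
            # independent oracle: argmin is uniform over models
            g_max = max(r.gdt_ts for r in ds.records)
            oracle = np.mean(
                [1 + math.floor((g_max - r.gdt_ts) / 2.5 + 1e-9) for r in ds.records]
            )
            assert enum_mean == pytest.approx(oracle)

    def test_embedded_energies(self):
        ds = DecoySet("t", [DecoyRecord("a", 80.0, energy=0.5), DecoyRecord("b", 60.0, energy=-1.0)])
        s = summarize([ds], None, "without_native")
        assert s.per_target_rank["t"] == assign_ranks(ds)["b"]


def _exact_oracle_p(diffs):
    """Independent 2^n enumeration of the one-sided signed-rank p-value."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_one_tailed([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.p_value == 1.0
        assert res.n_effective == 0

    def test_uniform_wins_n6_is_1_over_64(self):
        a = [1, 2, 3, 4, 5, 6]
        b = [2, 3, 4, 5, 6, 7]
        res = wilcoxon_one_tailed(a, b)
        assert res.p_value == pytest.approx(1 / 64)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_exact_oracle_p(np.array(a) - np.array(b)))

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            res = wilcoxon_one_tailed(a, b)
            assert res.p_value == pytest.approx(_exact_oracle_p(a - b))

    def test_exact_with_ties_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.integers(1, 5, size=7).astype(float)
            b = rng.integers(1, 5, size=7).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_one_tailed(a, b)
            assert res.p_value == pytest.approx(_exact_oracle_p(a - b))

    def test_super_uniform_under_null(self, rng):
        n_rep = 10_000
        hits = 0
        for _ in range(n_rep):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            if wilcoxon_one_tailed(a, b).p_value <= 0.05:
                hits += 1
        rate = hits / n_rep
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_swap_consistency(self, rng):
        # with continuous data: p(a<b) + p(b<a) = 1 + P(W = w_obs) under the exact null
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        p_ab = wilcoxon_one_tailed(a, b).p_value
        p_ba = wilcoxon_one_tailed(b, a).p_value
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        point = sum(
            1
            for signs in itertools.product([1, -1], repeat=9)
            if abs(sum(r for s, r in zip(signs, ranks) if s > 0) - w_obs) < 1e-9
        ) / 2**9
        assert p_ab + p_ba == pytest.approx(1.0 + point)

    def test_monotone_under_shift(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(size=12)
        p0 = wilcoxon_one_tailed(a, b).p_value
        p1 = wilcoxon_one_tailed(a - 5.0, b).p_value
        assert p1 <= p0

    def test_normal_approximation_path(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(loc=0.5, size=40)
        res = wilcoxon_one_tailed(a, b)
        assert res.method == "normal"
        ref = stats.wilcoxon(a, b, alternative="less", correction=True, method="approx").pvalue
        assert res.p_value == pytest.approx(ref, abs=0.02)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed([1, 2], [1, 2, 3])


class TestSelectDecoys:
    def test_best_below_threshold_rejected(self):
        cands = [CandidateModel(f"m{k}", g, 100) for k, g in enumerate([64.9, 50.0, 30.0])]
        res = select_decoys("t", cands)
        assert not res.accepted
        assert res.reason == "best_model_below_threshold"

    def test_threshold_inclusive(self):
        cands = [CandidateModel("m0", 65.0, 100)]
        assert select_decoys("t", cands).accepted

    def test_one_representative_per_occupied_bin(self):
        gdts = [80.0, 79.0, 76.0, 75.5, 72.0, 71.0, 70.9, 68.0, 66.0, 65.5]
        cands = [CandidateModel(f"m{k}", g, 100) for k, g in enumerate(gdts)]
        res = select_decoys("t", cands, seed=5)
        occupied = {int(math.floor((80.0 - g) / 2.5 + 1e-9)) for g in gdts}
        assert res.accepted
        assert len(res.records) == len(occupied)

    def test_most_populated_length_cluster(self):
        cands = [CandidateModel(f"a{k}", 70.0 + k, 120) for k in range(7)]
        cands += [CandidateModel(f"b{k}", 70.0 + k, 80) for k in range(3)]
        res = select_decoys("t", cands, seed=0)
        assert res.accepted
        assert all(r.model_id.startswith("a") for r in res.records)

    def test_all_atom_filter(self):
        cands = [
            CandidateModel("good", 70.0, 100, is_all_atom=True),
            CandidateModel("trace", 90.0, 100, is_all_atom=False),
        ]
        res = select_decoys("t", cands)
        assert res.accepted
        assert [r.model_id for r in res.records] == ["good"]
        res2 = select_decoys("t", [CandidateModel("trace", 90.0, 100, is_all_atom=False)])
        assert not res2.accepted and res2.reason == "no_all_atom_models"

    def test_seeded_determinism(self):
        cands = [CandidateModel(f"m{k}", 70.0 + 0.1 * k, 100) for k in range(20)]
        r1 = select_decoys("t", cands, seed=9)
        r2 = select_decoys("t", cands, seed=9)
        assert [x.model_id for x in r1.records] == [x.model_id for x in r2.records]


class TestDecoyIO:
    def test_manifest_roundtrip(self):
        sets = [
            DecoySet("t1", [DecoyRecord("a", 70.0, energy=-3.0),
                            DecoyRecord("n", 100.0, is_native=True)]),
            DecoySet("t2", [DecoyRecord("b", 55.5)]),
        ]
        buf = io.StringIO()
        write_manifest(sets, buf)
        buf.seek(0)
        back = read_manifest(buf)
        assert [s.target_id for s in back] == ["t1", "t2"]
        assert back[0].native is not None
        assert back[0].records[0].energy == -3.0
        assert back[1].records[0].gdt_ts == 55.5

    def test_score_file_roundtrip(self):
        buf = io.StringIO()
        write_scores({"a": -1.5, "b": 2.25}, buf, extra={"a": 10, "b": 12})
        buf.seek(0)
        assert read_scores(buf) == {"a": -1.5, "b": 2.25}

    def test_manifest_missing_columns(self):
        with pytest.raises(ValueError):
            read_manifest(io.StringIO("target_id\tmodel_id\n"))

    def test_native_must_have_gdt_100(self):
        with pytest.raises(ValueError):
            DecoyRecord("n", 90.0, is_native=True)

    def test_at_most_one_native(self):
        with pytest.raises(ValueError):
            DecoySet("t", [
                DecoyRecord("m", 50.0),
                DecoyRecord("n1", 100.0, is_native=True),
                DecoyRecord("n2", 100.0, is_native=True),
            ])
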