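"""Windowing, sequence and split arithmetic, including the reference counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainrate.sequencing import (SequencingConfig, SplitPlan, assemble_dataset,
                                  build_sequences, monte_carlo_plans, slide_windows,
                                  split_by_trial)


class TestSlideWindows:
    def test_deap_trial_yields_489_windows(self):
        """63 s at 128 Hz, 2-s windows, 125-ms shift: 8064 samples -> 489 windows."""
        starts = slide_windows(8064, 256, 16)
        assert len(starts) == 489
        assert starts[0] == 0 and starts[-1] == 488 * 16
        assert starts[-1] + 256 <= 8064

    def test_exact_fit_gives_one_window(self):
        assert len(slide_windows(256, 256, 16)) == 1

    def test_300_samples_gives_three_windows(self):
        assert list(slide_windows(300, 256, 16)) == [0, 16, 32]

    def test_window_longer_than_signal_gives_empty(self):
        assert len(slide_windows(100, 256, 16)) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 5000), L=st.integers(1, 512), S=st.integers(1, 64))
    def test_count_identity_vs_enumeration(self, n, L, S):
        """floor((N-L)/S)+1 against brute-force enumeration of valid starts."""
        starts = slide_windows(n, L, S)
        brute = [s for s in range(0, n, S) if s + L <= n]
        assert list(starts) == brute
        if L <= n:
            assert len(starts) == (n - L) // S + 1

    def test_config_sample_conversion(self):
        cfg = SequencingConfig()
        assert cfg.window_samples(128) == 256 and cfg.shift_samples(128) == 16
        with pytest.raises(ValueError):
            SequencingConfig(window_seconds=0.3).window_samples(128)  # 38.4 samples


class TestBuildSequences:
    def test_489_windows_give_482_sequences(self):
        seqs = build_sequences(list(range(489)), np.arange(489.0), z=7)
        assert len(seqs) == 482

    def test_eight_windows_one_sequence_targets_the_eighth(self):
        seqs = build_sequences(list(range(8)), 10.0 + np.arange(8.0), z=7)
        assert len(seqs) == 1
        assert seqs[0].tensors == (0, 1, 2, 3, 4, 5, 6)
        assert seqs[0].target_br == 17.0
        assert seqs[0].target_window_index == 7

    def test_z_windows_give_no_sequences(self):
        assert build_sequences(list(range(7)), np.arange(7.0), z=7) == []

    def test_target_alignment_every_instance(self):
        brs = np.arange(50.0) * 3.5
        for inst in build_sequences(list(range(50)), brs, z=7):
            assert inst.target_br == brs[inst.first_window_index + 7]


class TestSplitByTrial:
    def test_40_trials_split_28_6_6(self):
        plan = split_by_trial([f"t{i}" for i in range(40)], seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (28, 6, 6)

    def test_10_trials_split_7_2_1(self):
        plan = split_by_trial([f"t{i}" for i in range(10)], seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (7, 2, 1)

    def test_different_seeds_same_sizes_different_membership(self):
        ids = [f"t{i}" for i in range(40)]
        a, b = split_by_trial(ids, seed=1), split_by_trial(ids, seed=2)
        assert len(a.train) == len(b.train)
        assert set(a.train) != set(b.train)

    def test_no_leakage_union_and_disjointness(self):
        ids = [f"t{i}" for i in range(17)]
        plan = split_by_trial(ids, seed=3)
        assert plan.all_trials == set(ids)
        assert not (set(plan.train) & set(plan.validation))
        assert not (set(plan.train) & set(plan.test))
        assert not (set(plan.validation) & set(plan.test))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_by_trial(["a", "b"], seed=0)

    def test_json_roundtrip(self):
        plan = split_by_trial([f"t{i}" for i in range(10)], seed=5)
        assert SplitPlan.from_json(plan.to_json()) == plan


def _fake_study(n_participants, n_trials, n_windows=489, z=7):
    out = {}
    for p in range(n_participants):
        pid = f"p{p}"
        out[pid] = {
            f"t{t}": build_sequences(list(range(n_windows)), np.arange(float(n_windows)),
                                     z=z, participant_id=pid, trial_id=f"t{t}")
            for t in range(n_trials)
        }
    return out


class TestAssembleDataset:
    def test_single_participant_reference_counts(self):
        """40 trials of 482 sequences split 28/6/6 -> 13,496 / 2,892 / 2,892."""
        seqs = _fake_study(1, 40)
        plans = {"p0": split_by_trial([f"t{t}" for t in range(40)], seed=0)}
        ds = assemble_dataset(seqs, plans)
        assert ds.counts == {"train": 13496, "validation": 2892, "test": 2892,
                             "total": 19280}

    def test_three_participants_training_count(self):
        """Across-subject concatenation: 3 x 13,496 = 40,488 training sequences."""
        seqs = _fake_study(3, 40)
        plans = {p: split_by_trial([f"t{t}" for t in range(40)], seed=i)
                 for i, p in enumerate(seqs)}
        ds = assemble_dataset(seqs, plans)
        assert ds.counts["train"] == 40488
        assert ds.counts["total"] == 3 * 19280

    def test_single_trial_goes_whole_into_one_part(self):
        seqs = _fake_study(1, 3)
        plans = {"p0": SplitPlan(("t0",), ("t1",), ("t2",))}
        ds = assemble_dataset(seqs, plans)
        assert ds.counts["train"] == 482 and ds.counts["validation"] == 482

    def test_no_trial_leakage_across_parts(self):
        seqs = _fake_study(2, 10, n_windows=20)
        plans = {p: split_by_trial([f"t{t}" for t in range(10)], seed=i)
                 for i, p in enumerate(seqs)}
        ds = assemble_dataset(seqs, plans)
        seen = {}
        for part in ("train", "validation", "test"):
            for inst in getattr(ds, part):
                key = (inst.participant_id, inst.trial_id)
                assert seen.setdefault(key, part) == part

    def test_inconsistent_trial_structure_names_the_trial(self):
        seqs = _fake_study(2, 3, n_windows=20)
        seqs["p1"]["t2"] = seqs["p1"]["t2"][:-1]
        plans = {p: SplitPlan(("t0",), ("t1",), ("t2",)) for p in seqs}
        with pytest.raises(ValueError, match="t2"):
            assemble_dataset(seqs, plans)


class TestMonteCarloPlans:
    def test_subset_sizes_and_repetitions(self):
        pids = [f"p{i}" for i in range(32)]
        trials = {p: [f"t{t}" for t in range(40)] for p in pids}
        plans = monte_carlo_plans(pids, 3, repetitions=10, trial_ids_of=trials, seed=0)
        assert len(plans) == 10
        for subset, per_pid in plans:
            assert len(subset) == len(set(subset)) == 3
            assert set(per_pid) == set(subset)

    def test_full_cohort_single_repetition(self):
        pids = ["a", "b", "c"]
        trials = {p: [f"t{t}" for t in range(10)] for p in pids}
        [(subset, _)] = monte_carlo_plans(pids, 3, repetitions=1, trial_ids_of=trials, seed=0)
        assert set(subset) == set(pids)

    def test_reproducible_from_seed(self):
        pids = [f"p{i}" for i in range(8)]
        trials = {p: [f"t{t}" for t in range(6)] for p in pids}
        a = monte_carlo_plans(pids, 2, repetitions=4, trial_ids_of=trials, seed=9)
        b = monte_carlo_plans(pids, 2, repetitions=4, trial_ids_of=trials, seed=9)
        assert [(s, {k: v.to_json() for k, v in d.items()}) for s, d in a] == \
               [(s, {k: v.to_json() for k, v in d.items()}) for s, d in b]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_plans(["a"], 2, trial_ids_of={"a": ["t0"]}, seed=0)
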