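"""Binding-event detection, strict runs and duration statistics."""

import itertools

import numpy as np
import pytest

from lipsite.core import SiteDefinition, ConfigError
from lipsite.events import (SiteContactCounts, detect_binding_events,
                            event_statistics, interaction_count_matrix,
                            site_contact_counts, strict_interaction_times,
                            strict_run_lengths)
from lipsite.synth import event_oracle, strict_run_oracle
from lipsite.contacts import contact_timeline

from conftest import build_system


def make_counts(rows, times=None, n_core=4):
    rows = np.atleast_2d(np.asarray(rows, dtype=np.int16))
    n_lip, n_frames = rows.shape
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return SiteContactCounts(
        lipid_ids=np.arange(n_lip),
        lipid_species=np.array(["SYN"] * n_lip, dtype=object),
        times=np.asarray(times, dtype=float), counts=rows,
        site_name="test", n_core_residues=n_core)


class TestSiteContactCounts:
    def test_counts_sum_indicators(self):
        # residue ring with one lipid touching residues 1 and 2 only
        res = [[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [4.0, 4.0, 4.0],
               [6.0, 6.0, 6.0]]
        topo, traj = build_system(res, [[[1.25, 1.0, 1.0]]])
        tl = contact_timeline(traj, topo, cutoff=0.7)
        site = SiteDefinition("s", (1, 2, 3, 4))
        counts = site_contact_counts(tl, site)
        assert counts.counts[0, 0] == 2
        assert np.all(counts.counts <= 4)

    def test_missing_site_residue_errors(self):
        topo, traj = build_system([[1, 1, 1]], [[[2, 2, 2]]])
        tl = contact_timeline(traj, topo)
        with pytest.raises(ConfigError):
            site_contact_counts(tl, SiteDefinition("s", (1, 9)))

    def test_no_contacts_all_zero(self):
        topo, traj = build_system([[1, 1, 1]], [[[5, 5, 5]], [[5, 5, 5]]])
        tl = contact_timeline(traj, topo)
        counts = site_contact_counts(tl, SiteDefinition("s", (1,)))
        assert not counts.counts.any()


class TestStrictInteractionTimes:
    @pytest.mark.parametrize("row,expected", [
        ([0, 2, 2, 2, 0], [2.0]),
        ([0, 1, 2, 2, 1, 2, 0], [1.0, 0.0]),
        ([0, 0, 0], []),
        ([2, 2, 2], [2.0]),
    ])
    def test_hand_examples(self, row, expected):
        assert strict_interaction_times(make_counts(row)) == expected

    def test_run_lengths_count_frames(self):
        assert strict_run_lengths(make_counts([0, 2, 2, 2, 0])) == [3]
        assert strict_run_lengths(make_counts([2, 0, 2])) == [1, 1]


class TestDetectBindingEvents:
    @pytest.mark.parametrize("row,spans", [
        ([0, 1, 2, 2, 1, 2, 0], [(2, 5)]),   # bridged through the dip to 1
        ([2, 1, 1, 1, 2], [(0, 4)]),          # spans all frames
        ([0, 1, 1, 0], []),                   # never reaches 2 contacts
        ([0, 2, 0, 2, 0], [(1, 1), (3, 3)]),  # two zero-duration events
    ])
    def test_hand_examples(self, row, spans):
        evs = detect_binding_events(make_counts(row))
        assert [(e.start_frame, e.end_frame) for e in evs] == spans

    def test_exhaustive_oracle_equivalence_short_sequences(self):
        """All 4^6 count sequences of length 6 match the O(n^2) window
        oracles exactly (the full length-8 sweep runs in the acceptance
        checks)."""
        for seq in itertools.product(range(4), repeat=6):
            counts = make_counts(list(seq))
            impl = [(e.start_frame, e.end_frame)
                    for e in detect_binding_events(counts)]
            orac = [(e.start_frame, e.end_frame)
                    for e in event_oracle(counts)]
            assert impl == orac, seq
            assert strict_interaction_times(counts) == \
                strict_run_oracle(counts), seq

    def test_every_strict_run_lies_inside_one_event(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            row = rng.integers(0, 4, size=40)
            counts = make_counts(row)
            events = detect_binding_events(counts)
            spans = [(e.start_frame, e.end_frame) for e in events]
            run_starts, run_ends = [], []
            durations = strict_interaction_times(counts)
            # reconstruct runs directly
            mask = row >= 2
            f = 0
            runs = []
            while f < len(row):
                if mask[f]:
                    f0 = f
                    while f + 1 < len(row) and mask[f + 1]:
                        f += 1
                    runs.append((f0, f))
                f += 1
            for r0, r1 in runs:
                containing = [s for s in spans if s[0] <= r0 and r1 <= s[1]]
                assert len(containing) == 1
            assert len(events) <= max(1, len(runs)) or len(runs) == 0

    def test_durations_shift_invariant_and_scale_linear(self):
        row = [0, 1, 2, 2, 1, 2, 0]
        base = detect_binding_events(make_counts(row))
        shifted = detect_binding_events(
            make_counts(row, times=np.arange(7) + 100.0))
        dilated = detect_binding_events(
            make_counts(row, times=np.arange(7) * 2.5))
        assert [e.duration for e in shifted] == [e.duration for e in base]
        assert [e.duration for e in dilated] == \
            [2.5 * e.duration for e in base]

    def test_engaged_residues_recorded(self):
        res = [[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [6.0, 6.0, 6.0]]
        lip = [[[1.25, 1.0, 1.0]], [[1.25, 1.0, 1.0]], [[6.0, 6.0, 6.0]]]
        topo, traj = build_system(res, lip)
        tl = contact_timeline(traj, topo, cutoff=0.7)
        site = SiteDefinition("s", (1, 2, 3))
        counts = site_contact_counts(tl, site)
        evs = detect_binding_events(counts, tl, site)
        assert len(evs) == 1
        assert evs[0].engaged_residues == (1, 2)


class TestEventStatistics:
    def test_threshold_counts(self):
        evs = detect_binding_events(make_counts(
            [2] * 2 + [0] + [2] * 4 + [0] + [2] * 13 + [0] + [2] * 16,
            times=np.arange(38) * 1000.0))  # durations 1, 3, 12, 15 us
        table, _ = event_statistics(evs, thresholds=[2000.0, 10000.0])
        all_rows = table[table["species"] == "all"]
        assert all_rows.set_index("threshold_ns")["n_events"].tolist() == [3, 2]

    def test_empty_event_list(self):
        table, _ = event_statistics([], thresholds=[2000.0])
        assert (table["n_events"] == 0).all()

    def test_species_split(self):
        rows = np.array([[2, 2, 2, 2, 0, 0], [0, 0, 2, 2, 2, 2]])
        counts = make_counts(rows, times=np.arange(6) * 1000.0)
        counts.lipid_species = np.array(["A", "B"], dtype=object)
        evs = detect_binding_events(counts)
        table, _ = event_statistics(evs, thresholds=[2000.0])
        by = table.set_index("species")["n_events"]
        assert by["A"] == 1 and by["B"] == 1 and by["all"] == 2


class TestInteractionCountMatrix:
    def _system(self):
        # residues 1-2 = group A; residues 3-4 = group B
        res = [[1.0, 1.0, 1.0], [1.5, 1.0, 1.0],
               [3.0, 3.0, 3.0], [3.5, 3.0, 3.0]]
        frames = [
            [[3.25, 3.0, 3.0]],   # 0 in A, 2 in B
            [[3.25, 3.0, 3.0]],
            [[1.25, 1.0, 1.0]],   # 2 in A, 0 in B
            [[1.25, 1.0, 1.0]],
        ]
        return build_system(res, frames)

    def test_two_point_distribution(self):
        topo, traj = self._system()
        tl = contact_timeline(traj, topo, cutoff=0.7)
        site = SiteDefinition("s", (1, 2, 3, 4))
        evs = detect_binding_events(site_contact_counts(tl, site), tl, site)
        cm = interaction_count_matrix(tl, evs, (1, 2), (3, 4))
        cm.validate()
        assert cm.matrix[0, 2] == pytest.approx(0.5)
        assert cm.matrix[2, 0] == pytest.approx(0.5)

    def test_marginal_matches_direct_tally(self):
        rng = np.random.default_rng(9)
        res = rng.uniform(0, 5, (4, 3))
        frames = rng.uniform(0, 5, (60, 2, 3))
        topo, traj = build_system(res, frames, box=(5, 5, 5))
        tl = contact_timeline(traj, topo, cutoff=1.6)
        site = SiteDefinition("s", (1, 2, 3, 4))
        counts = site_contact_counts(tl, site)
        evs = detect_binding_events(counts, tl, site)
        assert evs  # this draw produces events
        cm = interaction_count_matrix(tl, evs, (1, 2), (3, 4))
        counts_b = site_contact_counts(tl, SiteDefinition("b", (3, 4)))
        direct = np.zeros(3)
        n = 0
        lip_row = {int(l): i for i, l in enumerate(tl.lipid_ids)}
        for e in evs:
            seg = counts_b.counts[lip_row[e.lipid_id],
                                  e.start_frame:e.end_frame + 1]
            for v in seg:
                direct[int(v)] += 1
                n += 1
        np.testing.assert_allclose(cm.matrix.sum(axis=0), direct / n,
                                   atol=1e-12)

    def test_zero_event_frames_errors(self):
        topo, traj = self._system()
        tl = contact_timeline(traj, topo, cutoff=0.7)
        with pytest.raises(ConfigError):
            interaction_count_matrix(tl, [], (1, 2), (3, 4))
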