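"""Counting-frame rule, disector decisions and the count ledger."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from disector import (
    CountTable,
    CountingFrame,
    ParticleProfile,
    RigidTransform,
    SectionPair,
    disector_count,
    frame_decision,
    profiles_from_mask,
    tally_counts,
)
from disector.counting import discs_sampled_by_frame
from disector.exceptions import AlignmentMissingError, ValidationError

FRAME = CountingFrame(origin=(0.0, 0.0), width=100.0, height=100.0)


def disc(x, y, r=5.0, pid=None, section=None):
    return ParticleProfile(
        centroid=(x, y), radius=r, particle_id=pid, section_index=section
    )


class TestFrameDecision:
    def test_strictly_inside_is_sampled(self):
        assert frame_decision(disc(50, 50), FRAME)

    def test_touching_left_exclusion_edge_not_sampled(self):
        assert not frame_decision(disc(-5.0, 50.0), FRAME)  # tangent to x=0

    def test_touching_bottom_exclusion_edge_not_sampled(self):
        assert not frame_decision(disc(50.0, -5.0), FRAME)

    def test_touching_top_inclusion_edge_sampled(self):
        assert frame_decision(disc(50.0, 105.0), FRAME)

    def test_touching_right_inclusion_edge_sampled(self):
        assert frame_decision(disc(105.0, 50.0), FRAME)

    def test_upward_extension_excludes(self):
        # crosses the top (inclusion) edge but touches the infinite
        # extension of the left exclusion line above the frame
        assert not frame_decision(disc(2.0, 103.0, r=6.0), FRAME)

    def test_far_outside_not_sampled(self):
        assert not frame_decision(disc(300.0, 300.0), FRAME)

    def test_polygon_profile_follows_same_rule(self):
        square_in = ParticleProfile(
            centroid=(50, 50),
            polygon=np.array([[45, 45], [55, 45], [55, 55], [45, 55]]),
        )
        square_on_left = ParticleProfile(
            centroid=(0, 50),
            polygon=np.array([[-5, 45], [5, 45], [5, 55], [-5, 55]]),
        )
        assert frame_decision(square_in, FRAME)
        assert not frame_decision(square_on_left, FRAME)


class TestTiling:
    """Exhaustively tiled frames count every convex profile exactly once."""

    @given(st.integers(0, 10_000))
    def test_random_discs_counted_once(self, seed):
        rng = np.random.default_rng(seed)
        step = 50.0
        n = 40
        cx = rng.uniform(0, 200, n)
        cy = rng.uniform(0, 200, n)
        r = rng.uniform(0.5, 60.0, n)  # some discs far larger than a frame
        total = np.zeros(n)
        lo = np.floor((min(cx.min() - r.max(), 0)) / step) - 1
        hi = np.ceil((max(cx.max(), cy.max()) + r.max()) / step) + 1
        for i in np.arange(lo, hi + 1):
            for j in np.arange(lo, hi + 1):
                total += discs_sampled_by_frame(
                    cx, cy, r, i * step, j * step, step, step
                )
        np.testing.assert_array_equal(total, np.ones(n))


class TestDisectorCount:
    def frames(self):
        return [FRAME]

    def test_identical_sections_count_zero(self):
        profs = tuple(disc(20 + 10 * i, 30, pid=i) for i in range(4))
        pair = SectionPair(reference=profs, lookup=profs)
        c = disector_count(pair, self.frames())
        assert c.forward == 0 and c.reverse == 0

    def test_lone_reference_profile_counts_forward_only(self):
        pair = SectionPair(reference=(disc(50, 50, pid=1),), lookup=())
        c = disector_count(pair, self.frames())
        assert (c.forward, c.reverse) == (1, 0)

    def test_bidirectional_hand_case(self):
        # reference {P1, P2}, lookup {P2, P3}: forward counts P1, reverse P3
        pair = SectionPair(
            reference=(disc(30, 30, pid=1), disc(60, 60, pid=2)),
            lookup=(disc(60, 60, pid=2), disc(80, 40, pid=3)),
        )
        c = disector_count(pair, self.frames())
        assert (c.forward, c.reverse) == (1, 1)
        assert c.total == 2

    def test_swap_symmetry(self):
        ref = tuple(disc(10 + 17 * i, 20 + 11 * i, pid=i) for i in range(5))
        look = tuple(disc(14 + 13 * i, 25 + 9 * i, pid=10 + i) for i in range(3))
        a = disector_count(SectionPair(reference=ref, lookup=look), self.frames())
        b = disector_count(SectionPair(reference=look, lookup=ref), self.frames())
        assert (a.forward, a.reverse) == (b.reverse, b.forward)

    def test_missing_alignment_raises(self):
        pair = SectionPair(reference=(disc(50, 50, pid=1),), lookup=(), transform=None)
        with pytest.raises(AlignmentMissingError):
            disector_count(pair, self.frames())

    def test_centroid_matching_equivalent_to_id_matching(self):
        ref = tuple(disc(20 + 15 * i, 40, pid=i) for i in range(4))
        look = tuple(
            disc(20 + 15 * i + 0.5, 40.2, pid=i) for i in range(3)
        )  # slightly jittered, one missing
        pair = SectionPair(reference=ref, lookup=look)
        by_id = disector_count(pair, self.frames(), matcher="id")
        by_xy = disector_count(pair, self.frames(), matcher="centroid")
        assert (by_id.forward, by_id.reverse) == (by_xy.forward, by_xy.reverse) == (1, 0)

    def test_counts_invariant_under_common_translation(self):
        # translating both sections and the frame together leaves Q⁻ unchanged
        rng = np.random.default_rng(7)
        shift = RigidTransform(dx=13.0, dy=-8.0)
        ref = [disc(*rng.uniform(0, 100, 2), pid=i) for i in range(12)]
        look = [disc(*rng.uniform(0, 100, 2), pid=20 + i) for i in range(12)]
        base = disector_count(
            SectionPair(reference=tuple(ref), lookup=tuple(look)), self.frames()
        )

        def move(p):
            x, y = shift.apply([p.centroid])[0]
            return disc(x, y, r=p.radius, pid=p.particle_id)

        moved = disector_count(
            SectionPair(
                reference=tuple(move(p) for p in ref),
                lookup=tuple(move(p) for p in look),
            ),
            [CountingFrame(origin=(13.0, -8.0), width=100.0, height=100.0)],
        )
        assert (base.forward, base.reverse) == (moved.forward, moved.reverse)


class TestTally:
    def test_worked_example_total(self, table2_q):
        table = CountTable.from_q_list(table2_q)
        assert table.sum_q == 158

    def test_empty_and_singleton(self):
        assert CountTable.from_q_list([]).sum_q == 0
        assert CountTable.from_q_list([5]).sum_q == 5

    def test_tally_preserves_order_and_sums_directions(self):
        from disector.counting import DisectorCounts

        counts = [
            DisectorCounts(np.array([2, 1]), np.array([0, 1])),
            DisectorCounts(np.array([0]), np.array([3])),
        ]
        table = tally_counts(counts, p_points=[7, 9])
        assert table.q_list == [4, 3]
        assert table.q_forward.tolist() == [3, 0]
        assert table.sum_p == 16

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            CountTable.from_q_list([3, -1])


class TestRasterMode:
    def test_labelled_objects_become_profiles(self):
        mask = np.zeros((60, 80), dtype=int)
        mask[10:20, 10:20] = 1          # 10x10 object
        mask[40:44, 60:64] = 2          # 4x4 object
        profs = profiles_from_mask(mask, pixel_size=2.0, section_index=3)
        assert len(profs) == 2
        big = max(profs, key=lambda p: p.radius)
        assert big.centroid == pytest.approx((14.5 * 2.0, 14.5 * 2.0))
        assert big.radius == pytest.approx(2.0 * np.sqrt(100 / np.pi))
        assert all(p.section_index == 3 for p in profs)
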