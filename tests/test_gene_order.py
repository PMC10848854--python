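"""Gene-order extraction, shared blocks, breakpoint distance and TDRL."""

import itertools
import random
from collections import deque

import pytest

from mitochar import (GeneFeature, MitoAnnotation, apply_tdrl,
                      breakpoint_distance, find_duplicates, linearize,
                      shared_blocks, tdrl_min_steps)
from mitochar.gene_order import GeneOrder, GeneOrderError, compare_orders


# ---------------------------------------------------------------- oracles

def tdrl_successors(perm):
    """All orders reachable from ``perm`` by one TDRL (duplicate a
    contiguous segment, keep one copy of each duplicated gene)."""
    n = len(perm)
    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = perm[i:j]
            for mask in range(2 ** len(seg)):
                firsts = tuple(g for k, g in enumerate(seg)
                               if mask & (1 << k))
                seconds = tuple(g for k, g in enumerate(seg)
                                if not mask & (1 << k))
                out.add(perm[:i] + firsts + seconds + perm[j:])
    return out


def bfs_tdrl_distances(n):
    """Exact TDRL distance from the identity to every permutation of n."""
    start = tuple(range(n))
    dist = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in tdrl_successors(cur):
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                queue.append(nxt)
    return dist


def brute_force_blocks(a, b, allow_inversion):
    """Enumerate every common contiguous run directly, then keep the
    position-maximal ones — an independent check of shared_blocks."""
    def runs(order):
        labels, n = order.labels, len(order.labels)
        out = []
        for i in range(n):
            max_len = n if order.circular else n - i
            for length in range(1, max_len + 1):
                idx = tuple((i + k) % n for k in range(length))
                out.append((tuple(labels[p] for p in idx), idx))
        return out

    runs_a, runs_b = runs(a), runs(b)
    common = []
    for la, ia in runs_a:
        for lb, ib in runs_b:
            if la == lb:
                common.append((ia, ib, False))
            elif allow_inversion and len(la) >= 2 and la == lb[::-1]:
                common.append((ia, tuple(reversed(ib)), True))
    kept = []
    for ia, ib, inv in common:
        contained = any(
            (set(ia) <= set(ja) and set(ib) <= set(jb)
             and len(ja) > len(ia))
            for ja, jb, _ in common)
        if not contained:
            kept.append((frozenset(ia), frozenset(ib), inv))
    return set(kept)


# ------------------------------------------------------------------ tests

class TestLinearize:
    def test_pcg_order_of_reference_genome(self, reference_annotation):
        order = linearize(reference_annotation, "Cox1", {"PCG"})
        assert order.labels == (
            "Cox1", "Nad1", "Nad3", "Cox2", "Cytb", "Nad2", "Nad5",
            "Nad6", "Nad4", "Atp6", "Nad4L", "Cox3")

    def test_trna_order_has_26_labels(self, reference_annotation):
        order = linearize(reference_annotation, "Cox1", {"tRNA"})
        assert len(order) == 26
        assert order.labels[0] == "trnM1"

    def test_empty_class_selection_rejected(self, reference_annotation):
        with pytest.raises(GeneOrderError):
            linearize(reference_annotation, "Cox1", set())

    def test_absent_start_gene_rejected(self, reference_annotation):
        with pytest.raises(GeneOrderError, match="Atp8"):
            linearize(reference_annotation, "Atp8", {"PCG"})

    def test_start_gene_rotates_the_order(self, reference_annotation):
        order = linearize(reference_annotation, "Nad3", {"PCG"})
        assert order.labels[0] == "Nad3" and order.labels[-1] == "Nad1"


class TestSharedBlocks:
    def test_identical_orders_give_one_full_block(self):
        a = GeneOrder(tuple("abcde"))
        blocks = shared_blocks(a, a)
        assert len(blocks) == 1 and blocks[0].labels == tuple("abcde")

    def test_rotated_circles_give_one_full_block(self):
        a = GeneOrder(tuple("abcde"), circular=True)
        b = GeneOrder(tuple("cdeab"), circular=True)
        blocks = shared_blocks(a, b)
        assert len(blocks) == 1 and len(blocks[0]) == 5

    def test_inverted_block_detected(self):
        a = GeneOrder(("1", "2", "3", "4", "5"))
        b = GeneOrder(("4", "3", "2", "1", "5"))
        blocks = shared_blocks(a, b, allow_inversion=True)
        inv = [blk for blk in blocks if blk.inverted]
        assert len(inv) == 1 and inv[0].labels == ("1", "2", "3", "4")

    def test_reference_pcg_orders_identical(self, reference_pcg_orders):
        a = reference_pcg_orders["Hyotissa_sinensis"]
        b = reference_pcg_orders["Hyotissa_hyotis"]
        blocks = shared_blocks(a, b)
        assert len(blocks) == 1 and len(blocks[0]) == 12
        assert a.same_circle(b)

    def test_wraparound_block_in_circular_orders(self):
        a = GeneOrder(("x", "y", "p", "q", "z"), circular=True)
        b = GeneOrder(("q", "z", "x", "p", "y"), circular=True)
        blocks = shared_blocks(a, b)
        # q-z-x is contiguous in both circles; in a it wraps the seam
        assert any(blk.labels == ("q", "z", "x") for blk in blocks)

    @pytest.mark.parametrize("circular", [False, True])
    @pytest.mark.parametrize("allow_inversion", [False, True])
    def test_agrees_with_brute_force_on_random_orders(
            self, circular, allow_inversion):
        rng = random.Random(11)
        for trial in range(25):
            n = rng.randrange(2, 11)
            labels = [str(x) for x in range(n)]
            a_labels = rng.sample(labels, n)
            b_labels = rng.sample(labels, n)
            a = GeneOrder(tuple(a_labels), circular=circular)
            b = GeneOrder(tuple(b_labels), circular=circular)
            if circular and a.same_circle(b):
                continue  # full-circle case covered separately
            got = {(frozenset(blk.positions_a), frozenset(blk.positions_b),
                    blk.inverted)
                   for blk in shared_blocks(a, b, allow_inversion)}
            assert got == brute_force_blocks(a, b, allow_inversion)


class TestBreakpointDistance:
    def test_identity_and_symmetric_zero(self):
        a = GeneOrder(tuple("abcd"), circular=True)
        assert breakpoint_distance(a, a) == 0

    def test_rotation_has_zero_distance(self):
        a = GeneOrder(("1", "2"), circular=True)
        b = GeneOrder(("2", "1"), circular=True)
        assert breakpoint_distance(a, b) == 0

    def test_transposed_middle_pair(self):
        # adjacencies of A: 1>2 2>3 3>4 4>1; of B: 1>3 3>2 2>4 4>1
        # shared: 4>1 only -> 3 breakpoints each way
        a = GeneOrder(("1", "2", "3", "4"), circular=True)
        b = GeneOrder(("1", "3", "2", "4"), circular=True)
        assert breakpoint_distance(a, b) == 3
        assert breakpoint_distance(b, a) == 3

    def test_label_set_mismatch_lists_asymmetry(self):
        a = GeneOrder(("1", "2", "3"))
        b = GeneOrder(("1", "2", "9"))
        with pytest.raises(GeneOrderError, match="9"):
            breakpoint_distance(a, b)

    def test_duplicates_rejected(self):
        a = GeneOrder(("1", "1", "2"))
        with pytest.raises(GeneOrderError, match="duplicate"):
            breakpoint_distance(a, a)


class TestApplyTdrl:
    def test_keep_all_first_copies_is_identity(self):
        a = GeneOrder(tuple("abcd"))
        assert apply_tdrl(a, 0, 4, ["first"] * 4).labels == a.labels

    def test_hand_simulated_loss_pattern(self):
        a = GeneOrder(("1", "2", "3"))
        got = apply_tdrl(a, 0, 3, ["first", "second", "first"])
        assert got.labels == ("1", "3", "2")

    def test_keeping_both_copies_creates_marked_duplicate(self):
        a = GeneOrder(("1", "2", "3"))
        got = apply_tdrl(a, 0, 3, ["first", "both", "first"])
        assert got.labels == ("1", "2", "3", "2'")

    def test_mask_length_mismatch_rejected(self):
        with pytest.raises(GeneOrderError, match="mask"):
            apply_tdrl(GeneOrder(("1", "2")), 0, 2, ["first"])

    def test_single_step_products_are_within_one_step(self):
        rng = random.Random(3)
        a = GeneOrder(tuple(str(i) for i in range(8)))
        for _ in range(50):
            start = rng.randrange(0, 8)
            length = rng.randrange(1, 9 - start)
            keep = [rng.choice(["first", "second"]) for _ in range(length)]
            b = apply_tdrl(a, start, length, keep)
            assert tdrl_min_steps(a, b) <= 1


class TestTdrlMinSteps:
    def test_identity_is_zero(self):
        a = GeneOrder(tuple("abcdef"))
        assert tdrl_min_steps(a, a) == 0

    def test_two_run_permutation_is_one_step(self):
        a = GeneOrder(("1", "2", "3", "4"))
        b = GeneOrder(("1", "3", "2", "4"))
        assert tdrl_min_steps(a, b) == 1

    def test_full_reversal_of_six(self):
        a = GeneOrder(tuple("123456"))
        b = GeneOrder(tuple("654321"))
        assert tdrl_min_steps(a, b) == 3

    def test_circular_orders_rejected(self):
        a = GeneOrder(tuple("abc"), circular=True)
        with pytest.raises(GeneOrderError, match="linear"):
            tdrl_min_steps(a, a)

    def test_duplicate_labels_rejected(self):
        a = GeneOrder(("x", "x", "y"))
        with pytest.raises(GeneOrderError):
            tdrl_min_steps(a, a)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_exhaustive_bfs_small(self, n):
        dist = bfs_tdrl_distances(n)
        a = GeneOrder(tuple(str(i) for i in range(n)))
        for perm in itertools.permutations(range(n)):
            b = GeneOrder(tuple(str(i) for i in perm))
            assert tdrl_min_steps(a, b) == dist[perm], perm

    def test_never_exceeds_log2_bound(self):
        rng = random.Random(5)
        import math
        for n in range(2, 12):
            bound = math.ceil(math.log2(n))
            a = GeneOrder(tuple(str(i) for i in range(n)))
            for _ in range(20):
                perm = rng.sample(range(n), n)
                b = GeneOrder(tuple(str(i) for i in perm))
                assert tdrl_min_steps(a, b) <= bound


class TestFindDuplicates:
    def _genome(self, seqs):
        feats, chunks, pos = [], [], 1
        for name, cls, s in seqs:
            feats.append(GeneFeature(name, cls, pos, pos + len(s) - 1))
            chunks.append(s)
            pos += len(s)
        return "".join(chunks), MitoAnnotation(pos - 1, tuple(feats))

    def test_exact_duplicate_found_at_full_identity(self):
        rrna = "ACGT" * 25
        seq, ann = self._genome([("rrnS1", "rRNA", rrna),
                                 ("rrnS2", "rRNA", rrna),
                                 ("trnM", "tRNA", "TTTTGGGGCCCCAAAA")])
        pairs = find_duplicates(ann, seq, 0.95)
        assert [(p.name_a, p.name_b) for p in pairs] == [("rrnS1", "rrnS2")]
        assert pairs[0].identity == 1.0

    def test_identity_thresholding_with_two_mismatches(self):
        x = "A" * 50 + "G" * 50
        y = "C" + x[1:-1] + "T"  # 2 mismatches over 100 nt -> 98%
        seq, ann = self._genome([("rrnS1", "rRNA", x), ("rrnS2", "rRNA", y)])
        hits95 = find_duplicates(ann, seq, 0.95)
        assert hits95 and hits95[0].identity == pytest.approx(0.98)
        assert find_duplicates(ann, seq, 0.99) == []

    def test_missing_sequence_is_an_error(self, reference_annotation):
        from mitochar.model import MitocharError
        with pytest.raises(MitocharError, match="sequence"):
            find_duplicates(reference_annotation, None)

    def test_cross_class_pairs_not_compared(self):
        s = "ACGTACGTACGT"
        seq, ann = self._genome([("rrnS", "rRNA", s), ("trnX", "tRNA", s)])
        assert find_duplicates(ann, seq, 0.9) == []


class TestCompareOrders:
    def test_report_for_identical_orders(self, reference_pcg_orders):
        a = reference_pcg_orders["Hyotissa_sinensis"]
        b = reference_pcg_orders["Hyotissa_hyotis"]
        report = compare_orders(a, b)
        assert report["identical"]
        assert report["breakpoint_distance"] == 0
        assert report["tdrl_min_steps"] == 0

    def test_tdrl_reported_absent_for_duplicates(self):
        a = GeneOrder(("x", "x", "y"))
        report = compare_orders(a, a)
        assert report["tdrl_min_steps"] is None
        assert "duplicate" in report["tdrl_unavailable"]
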