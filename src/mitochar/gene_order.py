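"""Gene-order extraction and pairwise rearrangement analysis.

Covers shared-block detection (with optional inverted blocks), breakpoint
distance, duplicate-gene discovery by sequence identity, and minimal-step
estimation under the tandem-duplication-random-loss (TDRL) model.

One TDRL operation duplicates a contiguous segment in tandem and then, for
each gene in the segment, deletes one of its two copies.  On a linear order
with a fixed origin, the minimal number of TDRLs transforming order A into
order B is ``ceil(log2(r))``, where ``r`` is the number of maximal ascending
runs of B's genes written in A's index order: a single TDRL can at most
halve the run count, and a halving step always exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .model import MitocharError, MitoAnnotation


class GeneOrderError(MitocharError):
    """Invalid gene-order input for the requested operation."""


@dataclass(frozen=True)
class GeneOrder:
    """An ordered list of gene labels, optionally circular.

    Duplicate labels are allowed; operations that require a permutation
    (breakpoint distance, TDRL steps) reject them explicitly.
    """

    labels: tuple[str, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise GeneOrderError("a gene order must be non-empty")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def has_duplicates(self) -> bool:
        return len(set(self.labels)) != len(self.labels)

    def rotations(self) -> list[tuple[str, ...]]:
        n = len(self.labels)
        return [self.labels[i:] + self.labels[:i] for i in range(n)]

    def canonical(self) -> tuple[str, ...]:
        """Rotation-canonical form: the lexicographically smallest rotation
        (circular orders only; linear orders are returned unchanged)."""
        if not self.circular:
            return self.labels
        return min(self.rotations())

    def same_circle(self, other: "GeneOrder") -> bool:
        """True if the two orders are identical up to rotation."""
        if len(self) != len(other):
            return False
        if self.circular and other.circular:
            return self.canonical() == other.canonical()
        return self.labels == other.labels


def linearize(annotation: MitoAnnotation, start_gene: str,
              classes: Iterable[str]) -> GeneOrder:
    """Gene order read around the genome from ``start_gene``, filtered to
    the requested gene classes.

    ``start_gene`` may belong to any class; the order begins at the first
    selected feature at or after it.  Duplicate gene copies keep their
    numbered labels.
    """
    classes = set(classes)
    if not classes:
        raise GeneOrderError("at least one gene class must be selected")
    names = [f.name for f in annotation.features]
    if start_gene not in names:
        raise GeneOrderError(f"start gene {start_gene!r} not in annotation")
    i = names.index(start_gene)
    rotated = annotation.features[i:] + annotation.features[:i]
    labels = [f.name for f in rotated if f.gene_class in classes]
    if not labels:
        raise GeneOrderError(f"no features of classes {sorted(classes)}")
    return GeneOrder(tuple(labels), circular=False)


@dataclass(frozen=True)
class Block:
    """A maximal run of labels contiguous in both orders.

    ``positions_a`` / ``positions_b`` list the matched indices in each
    order (B's indices run backwards for an inverted block).
    """

    labels: tuple[str, ...]
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]
    inverted: bool = False

    def __len__(self) -> int:
        return len(self.labels)


def _match_positions(order: GeneOrder, i: int, k: int, step: int = 1) -> int:
    """Index ``i + step*k`` with circular wrapping (or -1 off a linear end)."""
    n = len(order)
    j = i + step * k
    if order.circular:
        return j % n
    return j if 0 <= j < n else -1


def _run_matches(a: GeneOrder, b: GeneOrder, i: int, j: int,
                 length: int, inverted: bool) -> bool:
    for k in range(length):
        ia = _match_positions(a, i, k)
        ib = _match_positions(b, j, -k if inverted else k)
        if ia < 0 or ib < 0 or a.labels[ia] != b.labels[ib]:
            return False
    return True


def shared_blocks(a: GeneOrder, b: GeneOrder,
                  allow_inversion: bool = False) -> list[Block]:
    """All maximal gene blocks contiguous in both orders.

    A block is maximal when it cannot be extended at either end, and blocks
    wholly contained (in both coordinate sets) within a longer block are
    suppressed.  With ``allow_inversion``, a run in A may also match a run
    of B read backwards; such inverted blocks need length >= 2.  Circular
    adjacency is honoured across the rotation seam.
    """
    n, m = len(a), len(b)
    cap = min(n, m)
    if a.circular and b.circular and a.same_circle(b):
        idx = tuple(range(n))
        return [Block(a.labels, idx, idx)]
    if not a.circular and not b.circular and a.labels == b.labels:
        idx = tuple(range(n))
        return [Block(a.labels, idx, idx)]
    # reverse-circle identity: the whole circle matches inverted, so no
    # left-maximal anchor exists — emit the full inverted block directly
    if allow_inversion and a.circular and b.circular and n == m and n >= 2:
        for j in range(m):
            if _run_matches(a, b, 0, j, cap, True):
                return [Block(a.labels, tuple(range(n)),
                              tuple((j - k) % m for k in range(n)),
                              inverted=True)]

    found: dict[tuple, Block] = {}
    for inverted in ([False, True] if allow_inversion else [False]):
        for i in range(n):
            for j in range(m):
                if a.labels[i] != b.labels[j]:
                    continue
                # only start at a left-maximal anchor
                ip = _match_positions(a, i, -1)
                jp = _match_positions(b, j, 1 if inverted else -1)
                if ip >= 0 and jp >= 0 and a.labels[ip] == b.labels[jp]:
                    continue
                length = 1
                while length < cap and _run_matches(a, b, i, j, length + 1,
                                                    inverted):
                    length += 1
                if inverted and length < 2:
                    continue
                pos_a = tuple(_match_positions(a, i, k)
                              for k in range(length))
                pos_b = tuple(_match_positions(b, j, -k if inverted else k)
                              for k in range(length))
                key = (frozenset(pos_a), frozenset(pos_b), inverted)
                found[key] = Block(
                    labels=tuple(a.labels[p] for p in pos_a),
                    positions_a=pos_a, positions_b=pos_b, inverted=inverted)

    blocks = list(found.values())
    kept = []
    for blk in blocks:
        sa, sb = set(blk.positions_a), set(blk.positions_b)
        contained = any(
            other is not blk and len(other) > len(blk)
            and sa <= set(other.positions_a) and sb <= set(other.positions_b)
            for other in blocks)
        if not contained:
            kept.append(blk)
    kept.sort(key=lambda blk: (-len(blk), blk.positions_a))
    return kept


def _adjacencies(order: GeneOrder) -> set[tuple[str, str]]:
    """Directed neighbour pairs, including the circular closure pair."""
    labels = order.labels
    pairs = set(zip(labels, labels[1:]))
    if order.circular and len(labels) > 1:
        pairs.add((labels[-1], labels[0]))
    return pairs


def _require_permutation_pair(a: GeneOrder, b: GeneOrder, op: str) -> None:
    if a.has_duplicates or b.has_duplicates:
        raise GeneOrderError(f"{op} requires duplicate-free orders")
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        raise GeneOrderError(
            f"{op} requires identical label sets; only in A: "
            f"{sorted(sa - sb)}; only in B: {sorted(sb - sa)}")


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of directed adjacencies of A that are absent from B.

    Directed (reading-direction-sensitive) adjacencies make the distance 0
    exactly when the two orders are identical up to rotation in the
    circular case, matching the rotation-only equivalence used throughout
    (all genes lie on one strand, so reading direction is fixed).
    """
    _require_permutation_pair(a, b, "breakpoint distance")
    return len(_adjacencies(a) - _adjacencies(b))


def _ascending_runs(seq: Sequence[int]) -> int:
    runs = 1
    for prev, cur in zip(seq, seq[1:]):
        if cur < prev:
            runs += 1
    return runs


def tdrl_min_steps(a: GeneOrder, b: GeneOrder) -> int:
    """Minimal number of TDRL operations transforming A into B.

    Defined for duplicate-free linear orders over the same label set (fix an
    origin first for circular genomes, e.g. with :func:`linearize`).
    """
    if a.circular or b.circular:
        raise GeneOrderError(
            "TDRL steps are defined on linear orders; linearize at a fixed "
            "start gene first")
    _require_permutation_pair(a, b, "TDRL step count")
    index_in_a = {label: i for i, label in enumerate(a.labels)}
    image = [index_in_a[label] for label in b.labels]
    r = _ascending_runs(image)
    return (r - 1).bit_length()


def apply_tdrl(order: GeneOrder, start: int, length: int,
               keep: Sequence[str]) -> GeneOrder:
    """Apply one tandem-duplication-random-loss operation.

    The segment ``order.labels[start:start+length]`` is duplicated in
    tandem; ``keep[k]`` chooses which copy of the k-th segment gene
    survives: ``"first"``, ``"second"``, or ``"both"``.  Keeping both copies
    models an incompletely resolved duplication and yields a duplicate
    label marked with a trailing apostrophe.
    """
    labels = order.labels
    if not (0 <= start and start + length <= len(labels) and length >= 1):
        raise GeneOrderError(
            f"segment [{start}, {start + length}) out of range")
    if len(keep) != length:
        raise GeneOrderError(
            f"keep mask has {len(keep)} entries for a segment of {length}")
    bad = [k for k in keep if k not in ("first", "second", "both")]
    if bad:
        raise GeneOrderError(f"invalid keep choices: {bad}")
    segment = labels[start:start + length]
    first_copy = [g for g, k in zip(segment, keep) if k in ("first", "both")]
    second_copy = [(g + "'" if k == "both" else g)
                   for g, k in zip(segment, keep) if k in ("second", "both")]
    new = (list(labels[:start]) + first_copy + second_copy
           + list(labels[start + length:]))
    return GeneOrder(tuple(new), circular=order.circular)


@dataclass(frozen=True)
class DuplicatePair:
    """Two same-class features whose sequences exceed the identity cutoff."""

    name_a: str
    name_b: str
    identity: float
    aligned_length: int


def _pairwise_identity(x: str, y: str) -> tuple[float, int]:
    if len(x) == len(y):
        matches = sum(1 for p, q in zip(x, y) if p == q)
        return matches / len(x), len(x)
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=0, gap_score=0)
    matches = int(aligner.score(x, y))
    return matches / max(len(x), len(y)), max(len(x), len(y))


def find_duplicates(annotation: MitoAnnotation, sequence: Optional[str],
                    identity_threshold: float = 0.95) -> list[DuplicatePair]:
    """Same-class feature pairs with sequence identity >= the threshold.

    Equal-length pairs are compared ungapped (Hamming); unequal lengths go
    through a global alignment, with identity = matches / longer length.
    """
    if sequence is None:
        raise MitocharError("duplicate detection needs the genome sequence")
    feats = annotation.features
    pairs = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            fa, fb = feats[i], feats[j]
            if fa.gene_class != fb.gene_class:
                continue
            ident, length = _pairwise_identity(fa.extract(sequence),
                                               fb.extract(sequence))
            if ident >= identity_threshold:
                pairs.append(DuplicatePair(fa.name, fb.name, ident, length))
    pairs.sort(key=lambda p: -p.identity)
    return pairs


def compare_orders(a: GeneOrder, b: GeneOrder,
                   allow_inversion: bool = True) -> dict:
    """Bundle the pairwise comparison into one JSON-serialisable report."""
    blocks = shared_blocks(a, b, allow_inversion=allow_inversion)
    report: dict = {
        "n_labels": {"A": len(a), "B": len(b)},
        "identical": a.same_circle(b),
        "shared_blocks": [
            {"labels": list(blk.labels),
             "positions_a": list(blk.positions_a),
             "positions_b": list(blk.positions_b),
             "inverted": blk.inverted}
            for blk in blocks],
    }
    try:
        report["breakpoint_distance"] = breakpoint_distance(a, b)
    except GeneOrderError as exc:
        report["breakpoint_distance"] = None
        report["breakpoint_distance_unavailable"] = str(exc)
    try:
        report["tdrl_min_steps"] = tdrl_min_steps(a, b)
    except GeneOrderError as exc:
        report["tdrl_min_steps"] = None
        report["tdrl_unavailable"] = str(exc)
    return report
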