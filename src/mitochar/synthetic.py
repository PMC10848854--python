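"""Synthetic annotated mitogenomes with controlled statistical structure.

The generator emulates the features the analysis modules consume: a
circular single-strand genome with an ordered gene plan (protein-coding,
tRNA and rRNA genes), intergenic spacers drawn from a target composition,
codon-biased coding sequences with configurable (possibly truncated) stop
codons, and near-identical duplicated genes produced by per-site
substitution from a source copy.  Every sampled quantity is recorded in a
truth dictionary so recovery tests can compare measured statistics against
what was actually drawn.

Base probabilities are solved analytically from (AT content, AT skew,
GC skew): with ``s = at_content``, ``P(A) = s (1 + at_skew) / 2``,
``P(T) = s (1 - at_skew) / 2`` and symmetrically for G/C on ``1 - s`` —
the unique solution on the simplex, so infeasible targets are rejected
before sampling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .codon_usage import ALL_CODONS, GeneticCode
from .gene_order import apply_tdrl, GeneOrder
from .model import GeneFeature, MitoAnnotation, MitocharError
from .validate import intergenic_gaps

_BASES = ("A", "T", "G", "C")


class FeasibilityError(MitocharError):
    """The requested composition or gene plan cannot be realised."""


@dataclass(frozen=True)
class CompositionTarget:
    """Per-region base-composition target.

    Defaults are the whole-genome values of the Hyotissa sinensis
    mitogenome: AT content 57.2%, AT skew -0.15, GC skew 0.27.
    """

    at_content: float = 0.572
    at_skew: float = -0.15
    gc_skew: float = 0.27

    def base_probs(self) -> tuple[float, float, float, float]:
        s = self.at_content
        if not 0.0 <= s <= 1.0:
            raise FeasibilityError(f"AT content {s} outside [0, 1]")
        if not -1.0 <= self.at_skew <= 1.0 or not -1.0 <= self.gc_skew <= 1.0:
            raise FeasibilityError("skews must lie in [-1, 1]")
        if s == 0.0 and self.at_skew != 0.0:
            raise FeasibilityError(
                "nonzero AT skew requested with zero AT content")
        if s == 1.0 and self.gc_skew != 0.0:
            raise FeasibilityError(
                "nonzero GC skew requested with zero GC content")
        pa = s * (1 + self.at_skew) / 2
        pt = s * (1 - self.at_skew) / 2
        pg = (1 - s) * (1 + self.gc_skew) / 2
        pc = (1 - s) * (1 - self.gc_skew) / 2
        return pa, pt, pg, pc


@dataclass(frozen=True)
class GeneEntry:
    """One planned gene.

    ``copies > 1`` expands into adjacent numbered copies mutated from the
    first at ``copy_mutation_rate`` per site; ``copy_of`` instead declares
    this single entry to be a mutated copy of an earlier, equal-length
    entry (for duplicates that are not adjacent in the genome).
    """

    name: str
    gene_class: str
    length: int
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    copies: int = 1
    copy_mutation_rate: float = 0.01
    copy_of: Optional[str] = None
    composition: Optional[CompositionTarget] = None


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic circular mitogenome.

    ``codon_weights`` gives per-codon sampling weights for PCG bodies
    (RNA or DNA keys; stop codons are excluded from body sampling —
    terminal stops come from each entry's directive).  ``gap_lengths``
    fixes every intergenic spacer explicitly (one per feature, the last
    being the circular closure); otherwise the slack up to
    ``genome_length`` is spread evenly with the remainder on the closure
    gap.
    """

    genes: tuple[GeneEntry, ...]
    genome_length: Optional[int] = None
    spacer_composition: CompositionTarget = field(
        default_factory=CompositionTarget)
    codon_weights: Optional[Mapping[str, float]] = None
    gap_lengths: Optional[tuple[int, ...]] = None
    translation_table: int = 5
    seed: int = 0

    def validate(self) -> None:
        code = GeneticCode.from_ncbi_id(self.translation_table)
        names = set()
        for g in self.genes:
            if g.length <= 0:
                raise FeasibilityError(f"{g.name}: non-positive length")
            if g.copies < 1:
                raise FeasibilityError(f"{g.name}: copies must be >= 1")
            if g.name in names:
                raise FeasibilityError(f"duplicate plan name {g.name!r}")
            names.add(g.name)
            if g.gene_class == "PCG":
                body = g.length - 3 - len(g.stop_codon)
                if body < 0 or body % 3:
                    raise FeasibilityError(
                        f"{g.name}: length {g.length} incompatible with "
                        f"stop codon {g.stop_codon!r}")
                if len(g.stop_codon) == 3 \
                        and g.stop_codon.upper() not in code.stop_codons:
                    raise FeasibilityError(
                        f"{g.name}: {g.stop_codon!r} is not a stop codon "
                        f"of table {self.translation_table}")
        if self.codon_weights is not None:
            if any(w < 0 for w in self.codon_weights.values()):
                raise FeasibilityError("codon weights must be non-negative")
        self.spacer_composition.base_probs()
        for g in self.genes:
            if g.composition is not None:
                g.composition.base_probs()


def _sample_bases(rng: np.random.Generator, n: int,
                  target: CompositionTarget) -> str:
    if n == 0:
        return ""
    probs = np.array(target.base_probs())
    return "".join(rng.choice(list(_BASES), size=n, p=probs / probs.sum()))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != base]))
        else:
            out.append(base)
    return "".join(out)


def _sense_weights(weights: Optional[Mapping[str, float]],
                   code: GeneticCode) -> tuple[list[str], np.ndarray]:
    if weights is None:
        w = {c: 1.0 for c in ALL_CODONS}
    else:
        w = {k.upper().replace("U", "T"): float(v)
             for k, v in weights.items()}
    sense = [c for c in ALL_CODONS if code.forward[c] != "*"]
    arr = np.array([w.get(c, 0.0) for c in sense])
    if arr.sum() <= 0:
        raise FeasibilityError("codon weights sum to zero over sense codons")
    return sense, arr / arr.sum()


def _expand_entries(genes: Sequence[GeneEntry]) -> list[GeneEntry]:
    out = []
    for g in genes:
        if g.copies == 1:
            out.append(g)
            continue
        for k in range(1, g.copies + 1):
            out.append(replace(
                g, name=f"{g.name}{k}", copies=1,
                copy_of=None if k == 1 else f"{g.name}1"))
    return out


def generate_genome(spec: GenomeSpec,
                    ) -> tuple[str, MitoAnnotation, dict]:
    """Draw one genome: returns (sequence, annotation, truth record).

    Deterministic given ``spec.seed``.  The produced annotation always
    closes exactly: declared sizes and gaps are set from the realised
    layout, so it passes :func:`mitochar.validate.validate_annotation`
    with zero residual by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.from_ncbi_id(spec.translation_table)
    sense, probs = _sense_weights(spec.codon_weights, code)
    entries = _expand_entries(spec.genes)

    seqs: dict[str, str] = {}
    sampled_codons: Counter[str] = Counter()
    for g in entries:
        if g.copy_of is not None:
            if g.copy_of not in seqs:
                raise FeasibilityError(
                    f"{g.name}: copy source {g.copy_of!r} not generated yet")
            src = seqs[g.copy_of]
            if len(src) != g.length:
                raise FeasibilityError(
                    f"{g.name}: length {g.length} != copy source length "
                    f"{len(src)}")
            seqs[g.name] = _mutate(rng, src, g.copy_mutation_rate)
        elif g.gene_class == "PCG":
            n_body = (g.length - 3 - len(g.stop_codon)) // 3
            body = rng.choice(sense, size=n_body, p=probs) if n_body else []
            sampled_codons.update(body)
            seqs[g.name] = (g.start_codon.upper() + "".join(body)
                            + g.stop_codon.upper())
        else:
            target = g.composition or spec.spacer_composition
            seqs[g.name] = _sample_bases(rng, g.length, target)

    total_genes = sum(len(s) for s in seqs.values())
    n = len(entries)
    if spec.gap_lengths is not None:
        gaps = list(spec.gap_lengths)
        if len(gaps) != n:
            raise FeasibilityError(
                f"{len(gaps)} gap lengths for {n} features")
        if any(g < 0 for g in gaps):
            raise FeasibilityError("gap lengths must be non-negative")
        genome_length = total_genes + sum(gaps)
        if spec.genome_length is not None \
                and spec.genome_length != genome_length:
            raise FeasibilityError(
                f"gap lengths imply genome length {genome_length}, "
                f"spec says {spec.genome_length}")
    elif spec.genome_length is not None:
        slack = spec.genome_length - total_genes
        if slack < 0:
            raise FeasibilityError(
                f"genome length {spec.genome_length} shorter than the "
                f"{total_genes} bp of planned genes")
        gaps = [slack // n] * n
        gaps[-1] += slack - n * (slack // n)
        genome_length = spec.genome_length
    else:
        gaps = [0] * n
        genome_length = total_genes

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for g, gap in zip(entries, gaps):
        seq = seqs[g.name]
        features.append(GeneFeature(
            name=g.name, gene_class=g.gene_class,
            start=pos, end=pos + len(seq) - 1, strand="H",
            start_codon=seq[:3] if g.gene_class == "PCG" else None,
            stop_codon=(seq[-(len(seq) % 3 or 3):]
                        if g.gene_class == "PCG" else None),
            declared_size=len(seq), declared_gap=gap))
        chunks.append(seq)
        chunks.append(_sample_bases(rng, gap, spec.spacer_composition))
        pos += len(seq) + gap
    sequence = "".join(chunks)
    annotation = MitoAnnotation(genome_length=genome_length,
                                features=tuple(features))

    truth = {
        "seed": spec.seed,
        "genome_length": genome_length,
        "order": [g.name for g in entries],
        "gap_lengths": gaps,
        "feature_sequences": dict(seqs),
        "sampled_codon_counts": dict(sampled_codons),
        "spacer_composition": {
            "at_content": spec.spacer_composition.at_content,
            "at_skew": spec.spacer_composition.at_skew,
            "gc_skew": spec.spacer_composition.gc_skew,
        },
    }
    return sequence, annotation, truth


def scramble_order(annotation: MitoAnnotation, n_tdrl: int,
                   seed: int) -> tuple[MitoAnnotation, list[dict]]:
    """Apply ``n_tdrl`` random TDRL operations to the feature order.

    Each operation duplicates a random contiguous segment and keeps one
    copy of every gene (never both), so the result stays duplicate-free and
    is reachable from the original in at most ``n_tdrl`` TDRL steps.
    Feature lengths are preserved; the intergenic spacer lengths keep their
    positions, so the genome length is unchanged.  The log is sufficient to
    replay the operations.
    """
    if n_tdrl < 0:
        raise MitocharError("n_tdrl must be >= 0")
    rng = np.random.default_rng(seed)
    order = GeneOrder(tuple(f.name for f in annotation.features),
                      circular=False)
    log: list[dict] = []
    for _ in range(n_tdrl):
        n = len(order)
        start = int(rng.integers(0, n))
        length = int(rng.integers(1, n - start + 1))
        keep = [("first", "second")[int(b)]
                for b in rng.integers(0, 2, size=length)]
        order = apply_tdrl(order, start, length, keep)
        log.append({"start": start, "length": length, "keep": keep})

    by_name = {f.name: f for f in annotation.features}
    gap_values = [g for _, g in intergenic_gaps(annotation)]
    features = []
    pos = 1
    for label, gap in zip(order.labels, gap_values):
        f = by_name[label]
        features.append(f.with_(start=pos, end=pos + f.length - 1,
                                declared_size=f.length, declared_gap=gap))
        pos += f.length + gap
    return (MitoAnnotation(genome_length=annotation.genome_length,
                           features=tuple(features)), log)


def hyotissa_like_spec(seed: int = 0) -> GenomeSpec:
    """A genome plan mirroring the published H. sinensis architecture.

    Gene names, classes, lengths, start/stop codons (including the
    truncated Nad3 stop ``T``) and every intergenic spacer reproduce the
    annotation table; codon weights are proportional to the published
    codon counts; tRNA/rRNA and spacer compositions use the published
    class-level values.  The duplicate pairs trnM2/trnM3, trnL2/trnL3 and
    rrnS1/rrnS2 are generated as 1-2% mutated copies.
    """
    from .datasets import load_reference_annotation, \
        load_reference_codon_counts

    annotation = load_reference_annotation()
    counts = load_reference_codon_counts()
    weights = {row.codon: float(row.count) for row in counts.itertuples()}

    class_comp = {
        "tRNA": CompositionTarget(0.563, -0.14, 0.19),
        "rRNA": CompositionTarget(0.576, -0.03, 0.20),
    }
    copy_links = {"trnM3": "trnM2", "trnL3": "trnL2", "rrnS2": "rrnS1"}
    rates = {"trnM3": 0.02, "trnL3": 0.02, "rrnS2": 0.01}

    entries = []
    for f in annotation.features:
        entries.append(GeneEntry(
            name=f.name, gene_class=f.gene_class, length=f.length,
            start_codon=f.start_codon or "ATG",
            stop_codon=f.stop_codon or "TAA",
            copy_of=copy_links.get(f.name),
            copy_mutation_rate=rates.get(f.name, 0.01),
            composition=class_comp.get(f.gene_class)))
    gap_lengths = tuple(g for _, g in intergenic_gaps(annotation))
    return GenomeSpec(
        genes=tuple(entries),
        genome_length=annotation.genome_length,
        spacer_composition=CompositionTarget(0.572, -0.15, 0.27),
        codon_weights=weights,
        gap_lengths=gap_lengths,
        seed=seed,
    )
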