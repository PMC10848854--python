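"""Annotation-consistency checks: size arithmetic, intergenic accounting and
circular closure.

For a circular annotation sorted by start, the gap following feature *i* is
``start(i+1) - end(i) - 1``; the last feature's gap wraps around the origin:
``genome_length - end(last) + start(first) - 1``.  Negative gaps are genuine
overlaps and are reported as such, never clipped.  Summing feature lengths
and (signed) gaps over a full circle must reproduce the genome length, which
is what ``closure_residual`` measures against the declared table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import AnnotationError, GeneFeature, MitoAnnotation


def feature_length(feature: GeneFeature) -> int:
    """Length in bp of a 1-based inclusive feature: ``end - start + 1``."""
    return feature.end - feature.start + 1


def intergenic_gaps(annotation: MitoAnnotation) -> list[tuple[str, int]]:
    """Gap (in bp) following each feature, in genome order.

    The final entry is the circular closure gap.  Overlapping neighbours
    yield negative values.
    """
    feats = annotation.features
    if not feats:
        raise AnnotationError("cannot compute gaps of an empty annotation")
    gaps = []
    for cur, nxt in zip(feats, feats[1:]):
        gaps.append((cur.name, nxt.start - cur.end - 1))
    last, first = feats[-1], feats[0]
    if annotation.circular:
        wrap = annotation.genome_length - last.end + first.start - 1
    else:
        wrap = annotation.genome_length - last.end
    gaps.append((last.name, wrap))
    return gaps


def _strip_copy_suffix(f: GeneFeature) -> str:
    if f.gene_class in ("tRNA", "rRNA"):
        return re.sub(r"\d+$", "", f.name)
    return f.name


@dataclass
class ValidationReport:
    """Outcome of checking an annotation table against its own coordinates."""

    size_mismatches: list[tuple[str, int, int]]   # (gene, declared, computed)
    gap_mismatches: list[tuple[str, int, int]]    # (gene, declared, computed)
    gap_table: list[tuple[str, int]]              # (gene, following gap bp)
    overlaps: list[tuple[str, int]]               # gap_table entries < 0
    largest_gap: tuple[tuple[str, str], int]      # ((left, right), bp)
    closure_residual: int
    genome_length: int
    n_feature_rows: int
    n_distinct_genes: int
    class_census: dict[str, int]
    missing_declared_gaps: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (not self.size_mismatches and not self.gap_mismatches
                and self.closure_residual == 0)

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "genome_length": self.genome_length,
            "closure_residual": self.closure_residual,
            "n_feature_rows": self.n_feature_rows,
            "n_distinct_genes": self.n_distinct_genes,
            "class_census": self.class_census,
            "size_mismatches": [list(t) for t in self.size_mismatches],
            "gap_mismatches": [list(t) for t in self.gap_mismatches],
            "missing_declared_gaps": self.missing_declared_gaps,
            "overlaps": [list(t) for t in self.overlaps],
            "largest_gap": {
                "between": list(self.largest_gap[0]),
                "bp": self.largest_gap[1],
            },
            "gap_table": [list(t) for t in self.gap_table],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["gene\tfollowing_gap_bp"]
        lines += [f"{name}\t{gap}" for name, gap in self.gap_table]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_annotation(annotation: MitoAnnotation,
                        declared: Optional[MitoAnnotation] = None,
                        ) -> ValidationReport:
    """Check declared sizes and intergenic gaps against the coordinates.

    ``declared`` defaults to ``annotation`` itself, whose features carry the
    declared cells when read from a table.  Absent declared cells are
    skipped (recorded in ``missing_declared_gaps``), not counted as
    mismatches.
    """
    if declared is None:
        declared = annotation
    decl = {f.name: f for f in declared.features}

    feats = annotation.features
    gaps = intergenic_gaps(annotation)

    size_mismatches = []
    for f in feats:
        d = decl.get(f.name)
        if d is not None and d.declared_size is not None \
                and d.declared_size != f.length:
            size_mismatches.append((f.name, d.declared_size, f.length))

    gap_mismatches = []
    missing = []
    for name, gap in gaps:
        d = decl.get(name)
        if d is None or d.declared_gap is None:
            missing.append(name)
        elif d.declared_gap != gap:
            gap_mismatches.append((name, d.declared_gap, gap))

    names = [f.name for f in feats]
    largest_idx = max(range(len(gaps)), key=lambda i: gaps[i][1])
    right = names[(largest_idx + 1) % len(names)]
    largest = ((gaps[largest_idx][0], right), gaps[largest_idx][1])

    last, first = feats[-1], feats[0]
    trailing = last.declared_gap if last.declared_gap is not None \
        else gaps[-1][1]
    closure_residual = annotation.genome_length - (
        last.end + trailing + first.start - 1)

    census: dict[str, int] = {}
    for f in feats:
        census[f.gene_class] = census.get(f.gene_class, 0) + 1

    return ValidationReport(
        size_mismatches=size_mismatches,
        gap_mismatches=gap_mismatches,
        gap_table=gaps,
        overlaps=[(n, g) for n, g in gaps if g < 0],
        largest_gap=largest,
        closure_residual=closure_residual,
        genome_length=annotation.genome_length,
        n_feature_rows=len(feats),
        n_distinct_genes=len({_strip_copy_suffix(f) for f in feats}),
        class_census=census,
        missing_declared_gaps=missing,
    )
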