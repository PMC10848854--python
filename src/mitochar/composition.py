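"""Nucleotide composition and strand-skew statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed from
occurrence counts on a stated strand.  AT content is (A + T) / (A + T + G + C).
Ambiguity codes are tallied separately and excluded from every denominator,
so a run of Ns depresses nothing silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .model import MitocharError, MitoAnnotation, reverse_complement


class UndefinedStatisticError(MitocharError):
    """A skew or content value has a zero denominator."""


@dataclass(frozen=True)
class CompositionStats:
    """Base counts for a region, with derived content and skew values."""

    a: int
    t: int
    g: int
    c: int
    ambiguous: int = 0

    @property
    def total(self) -> int:
        """Unambiguous bases counted (A+T+G+C)."""
        return self.a + self.t + self.g + self.c

    @property
    def at_content(self) -> float:
        if self.total == 0:
            raise UndefinedStatisticError("AT content of an all-ambiguous "
                                          "or empty region is undefined")
        return (self.a + self.t) / self.total

    @property
    def at_skew(self) -> float:
        if self.a + self.t == 0:
            raise UndefinedStatisticError("AT skew undefined: A + T = 0")
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        if self.g + self.c == 0:
            raise UndefinedStatisticError("GC skew undefined: G + C = 0")
        return (self.g - self.c) / (self.g + self.c)

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(self.a + other.a, self.t + other.t,
                                self.g + other.g, self.c + other.c,
                                self.ambiguous + other.ambiguous)


def base_counts(sequence: str) -> CompositionStats:
    """Exact base occurrence counts (case-insensitive, U counted as T)."""
    if not sequence:
        raise MitocharError("cannot compute composition of an empty sequence")
    s = sequence.upper().replace("U", "T")
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    return CompositionStats(a, t, g, c, ambiguous=len(s) - a - t - g - c)


def at_skew(counts: CompositionStats) -> float:
    return counts.at_skew


def gc_skew(counts: CompositionStats) -> float:
    return counts.gc_skew


def at_content(counts: CompositionStats) -> float:
    return counts.at_content


def _class_concat(sequence: str, annotation: MitoAnnotation,
                  gene_class: str) -> str:
    parts = [f.extract(sequence) for f in annotation.by_class(gene_class)]
    return "".join(parts)


def region_stats(sequence: str, annotation: MitoAnnotation,
                 selector: str) -> pd.DataFrame:
    """Composition rows for a named region selection.

    ``selector`` is one of ``"whole"``, ``"genes"`` (one row per feature),
    a class concatenation (``"PCGs"``, ``"tRNAs"``, ``"rRNAs"``), or a single
    gene name.  Class concatenations follow genome order.  Returns a
    DataFrame with raw counts and full-precision statistics; use
    :func:`format_stats_table` for report rounding.
    """
    if len(sequence) != annotation.genome_length:
        raise MitocharError(
            f"sequence length {len(sequence)} != annotated genome length "
            f"{annotation.genome_length}")
    rows: list[tuple[str, CompositionStats]] = []
    if selector == "whole":
        rows.append(("Whole genome", base_counts(sequence)))
    elif selector == "genes":
        for f in annotation.features:
            rows.append((f.name, base_counts(f.extract(sequence))))
    elif selector in ("PCGs", "tRNAs", "rRNAs"):
        gene_class = {"PCGs": "PCG", "tRNAs": "tRNA", "rRNAs": "rRNA"}[selector]
        concat = _class_concat(sequence, annotation, gene_class)
        if not concat:
            raise MitocharError(f"no features of class {gene_class!r}")
        rows.append((selector, base_counts(concat)))
    else:
        try:
            f = annotation.get(selector)
        except KeyError:
            raise MitocharError(f"selector {selector!r} matches no feature")
        rows.append((f.name, base_counts(f.extract(sequence))))
    return _to_frame(rows)


def _maybe(getter) -> Optional[float]:
    try:
        return getter()
    except UndefinedStatisticError:
        return None


def _to_frame(rows: Iterable[tuple[str, CompositionStats]]) -> pd.DataFrame:
    """Tabulate regions; statistics with zero denominators become None
    (rendered "NA" by the formatter), never silent NaN arithmetic."""
    records = []
    for name, cs in rows:
        records.append({
            "feature": name,
            "length": cs.total + cs.ambiguous,
            "A": cs.a, "T": cs.t, "G": cs.g, "C": cs.c,
            "ambiguous": cs.ambiguous,
            "at_content": _maybe(lambda: cs.at_content),
            "at_skew": _maybe(lambda: cs.at_skew),
            "gc_skew": _maybe(lambda: cs.gc_skew),
        })
    return pd.DataFrame.from_records(records)


def codon_position_stats(cds_list: Sequence[str],
                         ) -> tuple[CompositionStats, CompositionStats,
                                    CompositionStats]:
    """Per-codon-position composition over a set of coding sequences.

    Position *k* (1, 2, 3) pools the *k*-th base of every codon across all
    CDS, in the order given.  A trailing truncated codon contributes only
    the positions it actually has.
    """
    buckets = ["", "", ""]
    for cds in cds_list:
        for k in range(3):
            buckets[k] += cds[k::3]
    return tuple(base_counts(b) if b else CompositionStats(0, 0, 0, 0)
                 for b in buckets)  # type: ignore[return-value]


def composition_report(sequence: str, annotation: MitoAnnotation,
                       include_stop_in_pcgs: bool = True) -> pd.DataFrame:
    """Full composition table: whole genome, PCG concatenation, PCG codon
    positions, each PCG, tRNA concatenation and each rRNA copy.

    ``include_stop_in_pcgs=False`` drops each protein-coding gene's terminal
    (possibly truncated) stop codon from the concatenations.
    """
    rows: list[tuple[str, CompositionStats]] = []
    rows.append(("Whole genome", base_counts(sequence)))

    pcgs = annotation.by_class("PCG")
    if pcgs:
        seqs = []
        for f in pcgs:
            s = f.extract(sequence)
            if not include_stop_in_pcgs:
                tail = len(s) % 3 or 3
                s = s[:-tail]
            seqs.append(s)
        rows.append(("PCGs", base_counts("".join(seqs))))
        for k, cs in enumerate(codon_position_stats(seqs), start=1):
            rows.append((f"PCGs{k}", cs))
        for f in sorted(pcgs, key=lambda f: f.name):
            rows.append((f.name, base_counts(f.extract(sequence))))

    if annotation.by_class("tRNA"):
        rows.append(("tRNAs", base_counts(
            _class_concat(sequence, annotation, "tRNA"))))
    for f in annotation.by_class("rRNA"):
        rows.append((f.name, base_counts(f.extract(sequence))))
    return _to_frame(rows)


def format_stats_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Report-style rounding: AT% to 1 decimal, skews to 2 decimals;
    undefined values print as "NA"."""

    def fmt(x, scale, nd):
        return "NA" if x is None else round_half_up(x * scale, nd)

    out = pd.DataFrame({
        "Feature": frame["feature"],
        "(A+T)%": [fmt(x, 100, 1) for x in frame["at_content"]],
        "AT skew": [fmt(x, 1, 2) for x in frame["at_skew"]],
        "GC skew": [fmt(x, 1, 2) for x in frame["gc_skew"]],
    })
    return out
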