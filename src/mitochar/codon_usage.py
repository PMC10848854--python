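"""Codon extraction and relative synonymous codon usage (RSCU).

RSCU follows the Sharp & Li definition: for codon *c* encoding amino acid
*aa*,

    RSCU(c) = count(c) * degeneracy(aa) / sum of counts over aa's codons,

so within each synonymous family the mean RSCU is 1 and unbiased usage gives
1 for every codon.  The default genetic code is the invertebrate
mitochondrial code (NCBI translation table 5), under which serine is
eight-fold degenerate (UCN plus AGN), AUA encodes Met, UGA encodes Trp, and
the stop class holds exactly UAA and UAG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from ._util import dna, rna, round_half_up
from .model import GeneFeature, MitocharError

_BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(a + b + c for a in _BASES
                                    for b in _BASES for c in _BASES)

AA_3LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with synonymous-family bookkeeping.

    ``forward`` maps all 64 DNA codons to one-letter amino acids, with
    ``"*"`` for stops.  ``families`` groups codons by amino acid.
    """

    table_id: int
    forward: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        for stop in table.stop_codons:
            forward[stop] = "*"
        if len(forward) != 64:
            raise MitocharError(
                f"translation table {table_id} does not map all 64 codons")
        families: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            families.setdefault(forward[codon], []).append(codon)
        return cls(table_id=table_id, forward=dict(forward),
                   families={aa: tuple(cs) for aa, cs in families.items()})

    def amino_acid(self, codon: str) -> str:
        return self.forward[dna(codon)]

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families["*"]


@dataclass(frozen=True)
class CDS:
    """A codon-split coding sequence.

    ``codons`` holds the full triplets (including a complete terminal stop,
    when there is one); ``stop_codon`` is the final coding unit — a full
    triplet, or the trailing 1-2 base remainder of a truncated stop.
    """

    name: str
    codons: tuple[str, ...]
    start_codon: str
    stop_codon: str

    @property
    def has_truncated_stop(self) -> bool:
        return len(self.stop_codon) < 3


def extract_cds(sequence: str, feature: GeneFeature) -> CDS:
    """Split a protein-coding feature into codons.

    A trailing 1- or 2-base remainder is kept as an incomplete stop codon,
    not dropped: mitochondrial genes routinely end on ``T`` or ``TA``
    completed by polyadenylation.
    """
    if feature.gene_class != "PCG":
        raise MitocharError(f"{feature.name} is not a protein-coding gene")
    seq = feature.extract(sequence).upper().replace("U", "T")
    if len(seq) < 6:
        raise MitocharError(
            f"{feature.name}: CDS of {len(seq)} nt is too short")
    n_full = len(seq) // 3
    codons = tuple(seq[3 * i:3 * i + 3] for i in range(n_full))
    tail = len(seq) % 3
    stop = seq[3 * n_full:] if tail else codons[-1]
    return CDS(name=feature.name, codons=codons,
               start_codon=codons[0], stop_codon=stop)


def classify_stop(stop_codon: str,
                  code: Optional[GeneticCode] = None) -> str:
    """``"complete"`` for a genuine stop triplet of the code, ``"truncated"``
    for the polyadenylation-completed forms T / TA, else ``"unknown"``."""
    if code is None:
        code = GeneticCode.from_ncbi_id(5)
    s = dna(stop_codon)
    if s in ("T", "TA"):
        return "truncated"
    if s in code.stop_codons:
        return "complete"
    return "unknown"


def codon_counts(cds_list: Iterable[CDS], include_stops: bool = True,
                 code: Optional[GeneticCode] = None) -> dict[str, int]:
    """Aggregate codon counts over a set of coding sequences.

    The terminal stop of each CDS is counted only when it is a complete
    stop triplet and ``include_stops`` is set; truncated stops are never
    counted (they are not codons of the code).
    """
    if code is None:
        code = GeneticCode.from_ncbi_id(5)
    counts: Counter[str] = Counter()
    for cds in cds_list:
        body = cds.codons
        if body and not cds.has_truncated_stop \
                and code.forward[body[-1]] == "*" and not include_stops:
            body = body[:-1]
        counts.update(body)
    return {codon: counts.get(codon, 0) for codon in ALL_CODONS}


def rscu(counts: Mapping[str, int],
         code: Optional[GeneticCode] = None) -> dict[str, Optional[float]]:
    """RSCU per codon; ``None`` for codons of families with zero total.

    Input keys may be DNA or RNA codons; output keys are DNA codons.
    """
    if code is None:
        code = GeneticCode.from_ncbi_id(5)
    cnt = {dna(k): v for k, v in counts.items()}
    for v in cnt.values():
        if v < 0:
            raise MitocharError("codon counts must be non-negative")
    out: dict[str, Optional[float]] = {}
    for aa, family in code.families.items():
        total = sum(cnt.get(c, 0) for c in family)
        for c in family:
            out[c] = None if total == 0 \
                else cnt.get(c, 0) * len(family) / total
    return out


def usage_report(counts: Mapping[str, int],
                 code: Optional[GeneticCode] = None) -> pd.DataFrame:
    """Codon-usage table in publication layout.

    One row per codon with a nonzero family, RNA-alphabet codons, counts to
    one decimal and RSCU to two, plus an amino-acid total column.  Codons
    are ordered by family, most-used families first among sense codons,
    with the stop class last.
    """
    if code is None:
        code = GeneticCode.from_ncbi_id(5)
    cnt = {dna(k): v for k, v in counts.items()}
    values = rscu(cnt, code)
    records = []
    for aa, family in code.families.items():
        total = sum(cnt.get(c, 0) for c in family)
        if total == 0:
            continue
        for c in family:
            records.append({
                "amino_acid": AA_3LETTER[aa],
                "aa_total": total,
                "codon": rna(c),
                "count": float(cnt.get(c, 0)),
                "rscu": round_half_up(values[c], 2),
                "formatted": f"{cnt.get(c, 0):.1f}"
                             f"({round_half_up(values[c], 2):.2f})",
                "_is_stop": aa == "*",
            })
    frame = pd.DataFrame.from_records(records)
    if frame.empty:
        return pd.DataFrame(columns=["amino_acid", "aa_total", "codon",
                                     "count", "rscu", "formatted"])
    frame = frame.sort_values(
        by=["_is_stop", "aa_total", "amino_acid", "count"],
        ascending=[True, False, True, False], kind="stable")
    return frame.drop(columns="_is_stop").reset_index(drop=True)


def most_frequent_amino_acid(counts: Mapping[str, int],
                             code: Optional[GeneticCode] = None) -> str:
    """Three-letter name of the most used amino acid (sense codons only)."""
    if code is None:
        code = GeneticCode.from_ncbi_id(5)
    cnt = {dna(k): v for k, v in counts.items()}
    totals = {aa: sum(cnt.get(c, 0) for c in family)
              for aa, family in code.families.items() if aa != "*"}
    if not totals or all(v == 0 for v in totals.values()):
        raise MitocharError("no sense-codon counts")
    return AA_3LETTER[max(totals, key=lambda aa: totals[aa])]
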