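"""Readers and writers for annotation tables, GenBank records, FASTA and
gene-order files, plus gene-name normalisation.

The annotation table is a 7-column, tab-separated mirror of the gene table
conventionally published with a mitogenome: Gene / Strand / Location /
Size (bp) / Start Codon / Stop codon / Intergenic nucleotides.  Blank
numeric cells are preserved as "absent" (``None``), never coerced to zero,
so a validator can distinguish "not stated" from "stated as 0".
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AnnotationError, GeneFeature, MitoAnnotation, ParseError

TABLE_COLUMNS = (
    "Gene",
    "Strand",
    "Location",
    "Size (bp)",
    "Start Codon",
    "Stop codon",
    "Intergenic nucleotides",
)

_LOCATION_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_TRNA_LONG_RE = re.compile(r"^t?rna[-_ ]?([a-z]{3})(\d*)$", re.IGNORECASE)
_TRNA_SHORT_RE = re.compile(r"^trn([a-z])(\d*)$", re.IGNORECASE)
_RRNA_RE = re.compile(r"^rrn[-_ ]?([ls])(\d*)$", re.IGNORECASE)

_AA_3TO1 = {k.lower(): v for k, v in protein_letters_3to1.items()}


def load_synonyms(path: Optional[str | Path] = None) -> dict[str, str]:
    """Load the gene-name synonym map (packaged default or a user file)."""
    if path is None:
        text = (resources.files("mitochar.data") / "gene_synonyms.yaml"
                ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    loaded = yaml.safe_load(text) or {}
    return {str(k).lower(): str(v) for k, v in loaded.items()}


def normalize_gene_name(raw: str,
                        synonyms: Optional[dict[str, str]] = None) -> str:
    """Canonicalise a gene label.

    ``tRNA-Met2`` / ``trnM2`` -> ``trnM2``; ``rrnL`` -> ``rrnL``;
    ``COX1`` / ``COI`` -> ``Cox1`` (via the synonym map).  Unknown names are
    returned stripped but otherwise untouched.
    """
    name = raw.strip().strip("*").replace(" ", "")
    if not name:
        raise ParseError("empty gene name")
    m = _TRNA_LONG_RE.match(name)
    if m and m.group(1).lower() in _AA_3TO1:
        return f"trn{_AA_3TO1[m.group(1).lower()]}{m.group(2)}"
    m = _TRNA_SHORT_RE.match(name)
    if m:
        return f"trn{m.group(1).upper()}{m.group(2)}"
    m = _RRNA_RE.match(name)
    if m:
        return f"rrn{m.group(1).upper()}{m.group(2)}"
    if synonyms is None:
        synonyms = load_synonyms()
    return synonyms.get(name.lower(), name)


def number_duplicate_names(names: Sequence[str]) -> list[str]:
    """Suffix repeated, un-numbered labels with 1..k in list order.

    Already-numbered labels (``trnM2``) are left alone; a second ``rrnL``
    becomes ``rrnL1`` / ``rrnL2``.
    """
    from collections import Counter

    counts = Counter(names)
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if counts[n] > 1:
            seen[n] = seen.get(n, 0) + 1
            out.append(f"{n}{seen[n]}")
        else:
            out.append(n)
    return out


def _parse_int(cell: str, row: str, what: str) -> Optional[int]:
    cell = cell.strip().replace(",", "")
    if not cell:
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise ParseError(f"row {row!r}: bad {what} value {cell!r}") from exc


def infer_gene_class(name: str, start_codon: Optional[str]) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "PCG" if start_codon else "other"


def read_annotation_tsv(path: str | Path,
                        genome_length: Optional[int] = None,
                        synonyms: Optional[dict[str, str]] = None,
                        ) -> MitoAnnotation:
    """Read a 7-column annotation table.

    ``genome_length`` may be given explicitly, stated in the file as a
    ``# genome_length: N`` comment, or — failing both — reconstructed from
    the circular closure: the last feature's end plus its declared trailing
    intergenic gap plus the first feature's leading offset.
    """
    if synonyms is None:
        synonyms = load_synonyms()
    path = Path(path)
    rows: list[dict] = []
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        m = re.match(r"^#\s*genome_length\s*[:=]\s*(\d+)", line)
        if m:
            if genome_length is None:
                genome_length = int(m.group(1))
            continue
        if line.lstrip().startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if not header_seen:
            if cells[0].strip().lower() != "gene":
                raise ParseError(
                    f"{path}: expected header starting with 'Gene', "
                    f"got {cells[0]!r}")
            header_seen = True
            continue
        cells += [""] * (len(TABLE_COLUMNS) - len(cells))
        raw_name, strand, loc, size, start_c, stop_c, gap = (
            c.strip() for c in cells[:7])
        m = _LOCATION_RE.match(loc)
        if not m:
            raise ParseError(
                f"row {raw_name!r}: malformed location {loc!r} "
                "(expected 'start-end')")
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise ParseError(
                f"row {raw_name!r}: end {end} < start {start}")
        rows.append(dict(
            name=normalize_gene_name(raw_name, synonyms),
            strand=strand or "H",
            start=start,
            end=end,
            start_codon=start_c.upper() or None,
            stop_codon=stop_c.upper() or None,
            declared_size=_parse_int(size, raw_name, "size"),
            declared_gap=_parse_int(gap, raw_name, "intergenic"),
        ))
    if not rows:
        raise ParseError(f"{path}: no annotation rows")

    names = number_duplicate_names([r["name"] for r in rows])
    features = []
    for name, r in zip(names, rows):
        features.append(GeneFeature(
            name=name,
            gene_class=infer_gene_class(name, r["start_codon"]),
            start=r["start"],
            end=r["end"],
            strand=r["strand"],
            start_codon=r["start_codon"],
            stop_codon=r["stop_codon"],
            declared_size=r["declared_size"],
            declared_gap=r["declared_gap"],
        ))

    if genome_length is None:
        by_start = sorted(features, key=lambda f: f.start)
        last, first = by_start[-1], by_start[0]
        if last.declared_gap is None:
            raise ParseError(
                f"{path}: genome length not given and the last feature "
                f"({last.name}) has no declared trailing gap to "
                "reconstruct it from")
        genome_length = last.end + last.declared_gap + first.start - 1
    return MitoAnnotation(genome_length=genome_length,
                          features=tuple(features))


def write_annotation_tsv(annotation: MitoAnnotation, path: str | Path,
                         include_length_comment: bool = True) -> None:
    lines = []
    if include_length_comment:
        lines.append(f"# genome_length: {annotation.genome_length}")
    lines.append("\t".join(TABLE_COLUMNS))
    for f in annotation.features:
        size = f.declared_size if f.declared_size is not None else f.length
        lines.append("\t".join([
            f.name,
            f.strand,
            f"{f.start}-{f.end}",
            str(size),
            f.start_codon or "",
            f.stop_codon or "",
            "" if f.declared_gap is None else str(f.declared_gap),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path,
                 synonyms: Optional[dict[str, str]] = None,
                 ) -> tuple[str, MitoAnnotation]:
    """Read a single-record GenBank flat file.

    Gene names are normalised through the synonym map; repeated names are
    numbered in coordinate order (three tRNA-Met features become
    ``trnM1``..``trnM3``).  CDS features get their start/stop codon read off
    the sequence.  Features of unrecognised type are retained with class
    ``other`` and a warning.
    """
    if synonyms is None:
        synonyms = load_synonyms()
    record = SeqIO.read(str(path), "genbank")  # raises on multi-record files
    sequence = str(record.seq).upper()

    raw: list[tuple[str, str, int, int, str]] = []
    for feat in record.features:
        if feat.type in ("source", "gene", "misc_feature", "D-loop"):
            continue
        gene_class = _GENBANK_CLASS.get(feat.type)
        if gene_class is None:
            warnings.warn(
                f"feature type {feat.type!r} not recognised; kept with "
                "class 'other'")
            gene_class = "other"
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product")
                 or quals.get("locus_tag") or [feat.type])[0]
        if len(feat.location.parts) > 1:
            raise AnnotationError(
                f"{label}: compound (origin-spanning) locations are not "
                "supported")
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "L" if feat.location.strand == -1 else "H"
        raw.append((normalize_gene_name(label, synonyms), gene_class,
                    start, end, strand))

    raw.sort(key=lambda r: (r[2], r[3]))
    max_end = max((r[3] for r in raw), default=0)
    if max_end > len(sequence):
        raise AnnotationError(
            f"record length {len(sequence)} is shorter than the furthest "
            f"feature end {max_end}")

    names = number_duplicate_names([r[0] for r in raw])
    features = []
    for name, (_, gene_class, start, end, strand) in zip(names, raw):
        start_codon = stop_codon = None
        if gene_class == "PCG":
            sub = sequence[start - 1:end]
            if strand == "L":
                sub = str(Seq(sub).reverse_complement())
            start_codon = sub[:3]
            tail = len(sub) % 3
            stop_codon = sub[-tail:] if tail else sub[-3:]
        features.append(GeneFeature(
            name=name, gene_class=gene_class, start=start, end=end,
            strand=strand, start_codon=start_codon, stop_codon=stop_codon))
    return sequence, MitoAnnotation(genome_length=len(sequence),
                                    features=tuple(features))


def read_fasta(path: str | Path) -> str:
    """Read a single-sequence FASTA file, returning the upper-cased sequence."""
    record = SeqIO.read(str(path), "fasta")
    return str(record.seq).upper()


def write_fasta(sequence: str, path: str | Path,
                name: str = "sequence", description: str = "") -> None:
    record = SeqRecord(Seq(sequence), id=name, description=description)
    SeqIO.write([record], str(path), "fasta")


def read_gene_orders(path: str | Path) -> dict[str, list[str]]:
    """Read a FASTA-like gene-order file.

    ``>`` lines name an order; other non-comment lines contribute
    whitespace-separated gene labels; ``#`` starts a comment.
    """
    orders: dict[str, list[str]] = {}
    current = "order"
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].strip() or f"order{len(orders) + 1}"
            orders[current] = []
        else:
            orders.setdefault(current, []).extend(line.split())
    if not orders or all(not v for v in orders.values()):
        raise ParseError(f"{path}: no gene orders found")
    return {k: v for k, v in orders.items() if v}


def write_gene_orders(orders: dict[str, Sequence[str]],
                      path: str | Path) -> None:
    lines = []
    for name, labels in orders.items():
        lines.append(f"> {name}")
        lines.append(" ".join(labels))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
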