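"""Packaged reference tables for the Hyotissa sinensis mitogenome
(GenBank accession OQ333008), transcribed from the published annotation,
plus the congener H. hyotis (OP151093) protein-coding gene order.

These are the printed desk-scale inputs: the 42-row gene table of the
30,385 bp genome, the codon-usage counts of its 12 protein-coding genes,
and the linearised PCG orders of the two gryphaeid oysters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gene_order import GeneOrder
from .io import read_annotation_tsv, read_gene_orders
from .model import MitoAnnotation

GENOME_LENGTH = 30385  # bp, Hyotissa sinensis (OQ333008)


def _data_path(name: str):
    return resources.files("mitochar.data") / name


def load_reference_annotation() -> MitoAnnotation:
    """The 42-feature H. sinensis annotation table (declared cells kept)."""
    with resources.as_file(_data_path("hyotissa_sinensis_annotation.tsv")) \
            as path:
        return read_annotation_tsv(path)


def load_reference_codon_counts() -> pd.DataFrame:
    """Published codon counts (and printed RSCU) of the 12 PCGs.

    Columns: ``amino_acid`` (three-letter, ``*`` for stops), ``codon``
    (RNA alphabet), ``count``, ``rscu_published``.
    """
    with resources.as_file(_data_path("hyotissa_sinensis_codon_counts.tsv")) \
            as path:
        return pd.read_csv(path, sep="\t")


def load_reference_pcg_orders() -> dict[str, GeneOrder]:
    """Linearised 12-gene PCG orders of H. sinensis and H. hyotis."""
    with resources.as_file(_data_path("ostreoidea_pcg_orders.txt")) as path:
        raw = read_gene_orders(path)
    return {name: GeneOrder(tuple(labels), circular=False)
            for name, labels in raw.items()}
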