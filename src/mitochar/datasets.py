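"""Packaged reference fixtures.

* the transcribed gene-organization table of the *Desmaulus extinctorium*
  mitogenome (GenBank OQ511529), genome length 16,608 nt;
* the ancestral gastropod signed gene order used as the rearrangement
  reference;
* the published codon counts with their RSCU values;
* the published per-region composition table.
"""

from __future__ import annotations

from importlib import resources

from .annotation import MitogenomeAnnotation, parse_gene_table
from .gene_order import SignedGeneOrder


def _read(name: str) -> str:
    return resources.files("mitochar.data").joinpath(name).read_text()


def desmaulus_annotation() -> MitogenomeAnnotation:
    """Published gene organization: 37 genes on a 16,608 nt circle
    (coordinates only, no sequence)."""
    return parse_gene_table(_read("desmaulus_table2.tsv"))


def ancestral_gastropod_order() -> SignedGeneOrder:
    """The ancestral gastropod gene arrangement (reconstruction; see file
    header) as a signed circular order."""
    return SignedGeneOrder.from_text(_read("ancestral_gastropod_order.tsv"))


def desmaulus_codon_counts() -> "pandas.DataFrame":
    """Published codon counts and RSCU values (columns: codon, aa, count,
    rscu_published)."""
    import pandas as pd

    return pd.read_csv(
        resources.files("mitochar.data").joinpath("desmaulus_codon_counts.tsv"),
        sep="\t", comment="#")


def desmaulus_composition() -> "pandas.DataFrame":
    """Published per-region composition and skews (see file header for the
    duplicated whole-genome row)."""
    import pandas as pd

    return pd.read_csv(
        resources.files("mitochar.data").joinpath("desmaulus_composition.tsv"),
        sep="\t", comment="#")
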