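"""Packaged reference tables for the TBP and TFIIB repeat families.

The shipped fixture is the published per-species summary of the two
transcription-factor families: identical/compared base counts between the
first and second repeat copies, percent identity, d_DR under the
composite-likelihood model, and the archaeal/eukaryotic domain of each of
the 34 species. It drives the downstream statistics (ranking, cross-family
regression, emergence-order inference) and the identity-recomputation
checks; the underlying curated nucleotide alignments are not
redistributed here.

Species are abbreviated (Mj = Methanocaldococcus jannaschii,
Mm = Methanococcus maripaludis, Hs = Homo sapiens, ...).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

FAMILIES = ("tbp", "tfiib")


def load_repeat_table(family: str) -> pd.DataFrame:
    """Load the per-species repeat-identity/d_DR table for one family.

    Columns: species, identical, compared, identity_pct, ddr, domain.
    Rows are in ascending d_DR order as published.
    """
    family = family.lower()
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    path = files("ddrclock.data").joinpath(f"repeat_table_{family}.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_paired_ddr() -> pd.DataFrame:
    """d_DR of both families joined on species (34 rows).

    Columns: species, ddr_tbp, ddr_tfiib, domain. This is the input to the
    cross-family correlation and emergence-order analysis.
    """
    tbp = load_repeat_table("tbp")[["species", "ddr", "domain"]]
    tfiib = load_repeat_table("tfiib")[["species", "ddr"]]
    merged = tbp.merge(tfiib, on="species", suffixes=("_tbp", "_tfiib"))
    if len(merged) != len(tbp):
        raise ValueError("species sets of the two families do not match")
    return merged[["species", "ddr_tbp", "ddr_tfiib", "domain"]]
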