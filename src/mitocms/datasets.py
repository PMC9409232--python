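"""Small bundled worked-example datasets.

``cotton_cms_snp_table`` is the published annotation of the 14 genic SNPs
found between a cotton CMS line's mitochondrial genome and its restorer
line's: per gene, the nucleotide pair, the amino-acid pair, and the
reported synonymous/non-synonymous and transition/transversion labels.  It
serves as a worked example for the variant classifiers: recomputing the
labels from the base and residue pairs must reproduce the reported columns
(5 synonymous / 9 non-synonymous; 12 transversions / 2 transitions).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def cotton_cms_snp_table() -> pd.DataFrame:
    """The 14-row genic SNP annotation table (see module docstring)."""
    ref = resources.files("mitocms.data").joinpath("cotton_cms_snp_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def classify_snp_table(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute effect and SNP class for each row of the worked-example table.

    Adds ``computed_effect`` (S/N from the amino-acid pair) and
    ``computed_snp_class`` (from the nucleotide pair) columns.
    """
    from .variants import classify_snp

    df = cotton_cms_snp_table() if df is None else df.copy()
    df["computed_effect"] = [
        "S" if a == b else "N" for a, b in zip(df["aa_ref"], df["aa_alt"])
    ]
    df["computed_snp_class"] = [
        classify_snp(r, a) for r, a in zip(df["nt_ref"], df["nt_alt"])
    ]
    return df
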