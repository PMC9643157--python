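"""IMGT physicochemical amino-acid classes.

Replacement mutations are characterised by the change they induce in six
standard IMGT class systems: charge, hydropathy, volume, chemical type,
hydrogen donor/acceptor atoms, and polarity.
"""

from __future__ import annotations

__all__ = ["CLASS_SYSTEMS", "aa_class", "classify_amino_change"]


def _invert(d: dict[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for cls, aas in d.items():
        for aa in aas:
            out[aa] = cls
    return out


#: class system -> amino acid -> class label (one-letter amino-acid codes)
CLASS_SYSTEMS: dict[str, dict[str, str]] = {
    "charge": _invert(
        {
            "positive": "HKR",
            "negative": "DE",
            "neutral": "ACFGILMNPQSTVWY",
        }
    ),
    "hydropathy": _invert(
        {
            "hydrophobic": "ACFILMVW",
            "neutral": "GHPSTY",
            "hydrophilic": "DEKNQR",
        }
    ),
    "volume": _invert(
        {
            "very_small": "AGS",
            "small": "CDNPT",
            "medium": "EHQV",
            "large": "IKLMR",
            "very_large": "FWY",
        }
    ),
    "chemical": _invert(
        {
            "aliphatic": "AGILPV",
            "aromatic": "FWY",
            "sulfur": "CM",
            "hydroxyl": "ST",
            "basic": "HKR",
            "acidic": "DE",
            "amide": "NQ",
        }
    ),
    "hydrogen": _invert(
        {
            "donor": "KRW",
            "acceptor": "DE",
            "donor_acceptor": "HNQSTY",
            "none": "ACFGILMPV",
        }
    ),
    "polarity": _invert(
        {
            "polar": "CDEHKNQRSTY",
            "nonpolar": "AFGILMPVW",
        }
    ),
}


def aa_class(system: str, aa: str) -> str:
    """Class label of one amino acid in one IMGT class system."""
    return CLASS_SYSTEMS[system][aa]


def classify_amino_change(from_aa: str, to_aa: str) -> dict[str, tuple[str, str]]:
    """(source class, destination class) per class system for a replacement.

    Both arguments must be standard one-letter amino acids; stop codons are
    handled upstream (such events are non-classifiable and carry no
    property record).
    """
    for aa in (from_aa, to_aa):
        if aa not in CLASS_SYSTEMS["charge"]:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    return {
        system: (table[from_aa], table[to_aa])
        for system, table in CLASS_SYSTEMS.items()
    }
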