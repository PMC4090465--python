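"""Shared vocabulary: motif classes, nucleus names and alias normalization."""

from __future__ import annotations

#: Fixed class order used everywhere (discriminants, confusion matrices,
#: tie-breaking).  HH = alpha-loop-alpha, EH = beta-loop-alpha,
#: HE = alpha-loop-beta, EE = beta-loop-beta.
CLASSES: tuple[str, ...] = ("HH", "EH", "HE", "EE")

#: Canonical nucleus order: carbonyl carbon, alpha carbon, beta carbon,
#: amide proton, alpha proton, amide nitrogen.
NUCLEI: tuple[str, ...] = ("C", "CA", "CB", "H", "HA", "N")

#: Standard amino acids in alphabetical one-letter order (AAC feature order).
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_GREEK = str.maketrans({"α": "A", "Α": "A", "β": "B", "Β": "B"})


def normalize_nucleus(name: str) -> str:
    """Map a nucleus name or alias onto the canonical token.

    Accepts case-insensitive spellings and the Greek-letter aliases
    (Calpha/Cbeta/Halpha written with alpha/beta characters).  Raises
    ``ValueError`` for anything outside the six supported atoms.
    Idempotent on canonical tokens.
    """
    token = name.strip().translate(_GREEK).upper()
    if token not in NUCLEI:
        raise ValueError(f"unknown nucleus {name!r}; expected one of {NUCLEI}")
    return token


def validate_class(label: str) -> str:
    lab = label.strip().upper()
    if lab not in CLASSES:
        raise ValueError(f"unknown motif class {label!r}; expected one of {CLASSES}")
    return lab
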