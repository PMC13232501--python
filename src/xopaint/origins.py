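"""Shared integer codes for parental origin and per-site labels.

A male *Drosophila* X is hemizygous, so every genotype call is a direct
haplotype observation.  Origins describe which parental line a stretch of
chromosome descends from; site labels additionally record calls that carry
no origin information (missing, or matching neither parental allele).
"""

from __future__ import annotations

import numpy as np

# Tract / site origins.
UNKNOWN: int = 0
HI: int = 1
LO: int = 2

# Extra per-site label states (never appear in tracts).
UNIQUE: int = 3
MISSING: int = -1

ORIGIN_NAMES = {UNKNOWN: "Unknown", HI: "Hi", LO: "Lo"}
LABEL_NAMES = {**ORIGIN_NAMES, UNIQUE: "Unique", MISSING: "Missing"}
NAME_TO_ORIGIN = {v: k for k, v in ORIGIN_NAMES.items()}


def other_origin(origin: int) -> int:
    """Swap Hi <-> Lo."""
    if origin == HI:
        return LO
    if origin == LO:
        return HI
    raise ValueError(f"no opposite for origin code {origin}")


def is_informative(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of labels that carry parental-origin information."""
    return (labels == HI) | (labels == LO)
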