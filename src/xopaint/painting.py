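"""Parental-origin assignment (haplotype painting) of recombinant X's.

Given informative SNPs — sites homozygous within each parental line and
divergent between them — each male's hemizygous genotype calls are labelled
Hi/Lo per site, unlabelled base pairs inherit the origin of the nearest
labelled site, and short discordant runs can be smoothed away as likely
genotyping noise before crossovers are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .origins import HI, LO, MISSING, UNIQUE, UNKNOWN, is_informative

__all__ = [
    "InformativeSiteSet",
    "PaintedChromosome",
    "select_informative_sites",
    "assign_site_origins",
    "interpolate_origins",
    "smooth_tracts",
    "paint_fly",
]


@dataclass
class InformativeSiteSet:
    """Sites usable for origin assignment, plus the QC that produced them."""

    positions: np.ndarray  # int64, strictly increasing
    hi_allele: np.ndarray  # int8
    lo_allele: np.ndarray  # int8
    chrom_len: int
    #: QC summary: fraction of candidate sites dropped as heterozygous /
    #: non-unanimous within each parental line, and resulting parental
    #: homozygosity percentages
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) == 0:
            raise ValueError("zero informative sites retained")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.hi_allele == self.lo_allele):
            raise ValueError("informative sites must differ between lines")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def select_informative_sites(
    positions: np.ndarray,
    parental_calls: np.ndarray,
    n_hi: int,
    chrom_len: int,
) -> InformativeSiteSet:
    """Apply informative-site QC to diploid parental genotypes.

    ``parental_calls`` is (samples x sites x 2) with Hi samples first
    (``n_hi`` of them) and -1 for missing alleles.  A site is retained only
    if every Hi sample is homozygous for one common allele, every Lo sample
    is homozygous for one common allele, and the two alleles differ —
    origin assignment is only unambiguous at such fixed, divergent sites.
    """
    n_samples = parental_calls.shape[0]
    if n_hi < 1 or n_samples - n_hi < 1:
        raise ValueError("need at least one Hi and one Lo parental sample")
    hi_calls = parental_calls[:n_hi]
    lo_calls = parental_calls[n_hi:]

    def line_consensus(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # fixed within the line: every sample homozygous, all samples equal
        hom = (calls[..., 0] == calls[..., 1]) & (calls[..., 0] >= 0)
        allele = calls[:, :, 0]
        unanimous = np.all(allele == allele[0], axis=0)
        return np.all(hom, axis=0) & unanimous, allele[0]

    hi_fixed, hi_allele = line_consensus(hi_calls)
    lo_fixed, lo_allele = line_consensus(lo_calls)
    informative = hi_fixed & lo_fixed & (hi_allele != lo_allele)
    n_total = len(positions)
    if not informative.any():
        raise ValueError("zero informative sites after QC")
    qc = {
        "n_candidate_sites": int(n_total),
        "n_informative": int(informative.sum()),
        "frac_dropped_het_hi": float((~hi_fixed).sum() / n_total),
        "frac_dropped_het_lo": float((~lo_fixed).sum() / n_total),
        "pct_homozygous_hi": float(100.0 * hi_fixed.sum() / n_total),
        "pct_homozygous_lo": float(100.0 * lo_fixed.sum() / n_total),
    }
    return InformativeSiteSet(
        positions[informative].astype(np.int64),
        hi_allele[informative].astype(np.int8),
        lo_allele[informative].astype(np.int8),
        chrom_len,
        qc,
    )


@dataclass
class PaintedChromosome:
    """Per-fly parentage tracts over the X plus the raw per-site labels.

    Tracts tile [0, chrom_len); origins are Hi/Lo, or a single Unknown
    tract when no site could be labelled.
    """

    fly_id: str
    tract_starts: np.ndarray  # int64, tract_starts[0] == 0
    tract_origins: np.ndarray  # int8
    chrom_len: int
    site_positions: np.ndarray  # int64, all sites (labelled or not)
    site_labels: np.ndarray  # int8 in {HI, LO, UNIQUE, MISSING}

    def tracts(self) -> list[tuple[int, int, int]]:
        """As (origin, start, end) triples tiling [0, chrom_len)."""
        ends = np.append(self.tract_starts[1:], self.chrom_len)
        return [
            (int(o), int(s), int(e))
            for o, s, e in zip(self.tract_origins, self.tract_starts, ends)
        ]

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.tract_starts, positions, side="right") - 1
        return self.tract_origins[idx]

    @property
    def n_switches(self) -> int:
        """Number of Hi<->Lo origin switches along the chromosome."""
        inf = self.tract_origins[is_informative(self.tract_origins)]
        return int(np.sum(inf[1:] != inf[:-1]))

    def switch_intervals(self) -> list[tuple[int, int]]:
        """Flanking-informative-site interval (left_pos, right_pos) of each
        Hi<->Lo switch, in chromosome order."""
        mask = is_informative(self.site_labels)
        pos = self.site_positions[mask]
        lab = self.site_labels[mask]
        change = np.nonzero(lab[1:] != lab[:-1])[0]
        return [(int(pos[i]), int(pos[i + 1])) for i in change]


def assign_site_origins(
    calls: np.ndarray, sites: InformativeSiteSet
) -> np.ndarray:
    """Label one male's haploid calls at each informative site.

    Hi/Lo on an allele match, Missing for no call (-1), Unique when the
    call matches neither parental allele (e.g. a third allele).
    """
    calls = np.asarray(calls)
    if calls.shape != sites.positions.shape:
        raise ValueError(
            f"calls shape {calls.shape} does not match site set "
            f"({sites.positions.shape})"
        )
    labels = np.full(calls.shape, UNIQUE, dtype=np.int8)
    labels[calls == sites.hi_allele] = HI
    labels[calls == sites.lo_allele] = LO
    labels[calls < 0] = MISSING
    return labels


def interpolate_origins(
    labels: np.ndarray,
    positions: np.ndarray,
    chrom_len: int,
    fly_id: str = "",
) -> PaintedChromosome:
    """Nearest-site interpolation of origin over every base pair.

    Base pairs without an informative call inherit the origin of the
    nearest Hi/Lo-labelled site by bp distance; Unique and Missing sites
    are transparent; chromosome ends inherit the nearest label inward.
    Exact midpoints between two differing labels go to the lower-coordinate
    site.  With zero usable labels the whole chromosome is Unknown.
    """
    labels = np.asarray(labels, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    mask = is_informative(labels)
    if not mask.any():
        return PaintedChromosome(
            fly_id,
            np.zeros(1, np.int64),
            np.array([UNKNOWN], np.int8),
            chrom_len,
            positions,
            labels,
        )
    pos = positions[mask]
    lab = labels[mask]
    change = np.nonzero(lab[1:] != lab[:-1])[0]
    # boundary b between differing neighbours p_l < p_r: bp < b go left;
    # b = midpoint + 1 sends the exact midpoint to the lower coordinate
    starts = [0]
    origins = [int(lab[0])]
    for i in change:
        b = int((pos[i] + pos[i + 1]) // 2 + 1)
        starts.append(b)
        origins.append(int(lab[i + 1]))
    return PaintedChromosome(
        fly_id,
        np.array(starts, np.int64),
        np.array(origins, np.int8),
        chrom_len,
        positions,
        labels,
    )


def smooth_tracts(painting: PaintedChromosome, k: int) -> PaintedChromosome:
    """Reassign short discordant runs to their flanking origin.

    A run of fewer than ``k`` consecutive opposite-origin informative sites
    flanked on both sides by the same origin is relabelled to the flanking
    origin; applied to convergence.  ``k = 1`` is the identity.  The
    painting is rebuilt from the smoothed labels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = painting.site_labels.copy()
    if k == 1:
        return interpolate_origins(
            labels, painting.site_positions, painting.chrom_len, painting.fly_id
        )
    mask = is_informative(labels)
    lab = labels[mask]
    changed = True
    while changed:
        changed = False
        runs = _runs(lab)
        for r, (value, start, length) in enumerate(runs):
            if r == 0 or r == len(runs) - 1 or length >= k:
                continue
            left = runs[r - 1][0]
            right = runs[r + 1][0]
            if left == right and left != value:
                lab[start : start + length] = left
                changed = True
        if changed:
            lab = lab.copy()  # re-run on merged runs
    labels[mask] = lab
    return interpolate_origins(
        labels, painting.site_positions, painting.chrom_len, painting.fly_id
    )


def _runs(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of x as (value, start_index, length)."""
    if len(x) == 0:
        return []
    change = np.nonzero(x[1:] != x[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(x)]))
    return [(int(x[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def paint_fly(
    calls: np.ndarray,
    sites: InformativeSiteSet,
    fly_id: str = "",
    smooth_k: int = 1,
) -> PaintedChromosome:
    """Label, interpolate and (optionally) smooth one fly in a single call."""
    labels = assign_site_origins(calls, sites)
    painting = interpolate_origins(labels, sites.positions, sites.chrom_len, fly_id)
    if smooth_k > 1:
        painting = smooth_tracts(painting, smooth_k)
    return painting
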