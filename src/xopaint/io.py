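"""Readers and writers for the package's standard formats.

Genotypes travel as VCF 4.2 (diploid GT for parental female samples,
haploid GT for recombinant males — a male X is hemizygous); sample roles
travel in a two-column sample sheet TSV since VCF has no standard slot for
them; tracts and regions as BED (0-based half-open); phenotypes as TSV.
Internally all coordinates are 0-based half-open; VCF POS is 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .origins import LABEL_NAMES, ORIGIN_NAMES
from .xo_rates import Region, RegionSet

__all__ = [
    "VcfParseError",
    "GenotypeData",
    "write_vcf",
    "read_vcf",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_tracts_bed",
    "write_regions_bed",
    "read_regions_bed",
    "write_phenotypes",
    "read_phenotypes",
    "write_label_matrix",
]

ROLES = ("hi_parent", "lo_parent", "recombinant")
_REF, _ALT = "A", "T"  # synthetic bases for 0/1 allele codes


class VcfParseError(ValueError):
    pass


@dataclass
class GenotypeData:
    """In-memory genotype bundle for one chromosome.

    ``parental_calls`` is (samples x sites x 2) diploid allele codes with
    -1 for missing; ``calls`` is (flies x sites) haploid codes with -1 for
    missing.  Hi parental samples come first (``n_hi`` of them).
    """

    chrom: str
    chrom_len: int
    positions: np.ndarray  # int64, 0-based
    parental_samples: list[str]
    n_hi: int
    parental_calls: np.ndarray
    fly_ids: list[str]
    calls: np.ndarray


def write_vcf(path, data: GenotypeData) -> None:
    """Write the bundle as an uncompressed VCF 4.2 text file."""
    samples = data.parental_samples + data.fly_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xopaint\n")
        fh.write(f"##contig=<ID={data.chrom},length={data.chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, pos in enumerate(data.positions):
            fields = [
                data.chrom, str(int(pos) + 1), ".", _REF, _ALT, ".", "PASS",
                ".", "GT",
            ]
            for s in range(len(data.parental_samples)):
                a, b = data.parental_calls[s, j]
                fields.append(f"{_gt(a)}/{_gt(b)}")
            for f in range(len(data.fly_ids)):
                fields.append(_gt(data.calls[f, j]))
            fh.write("\t".join(fields) + "\n")


def _gt(code: int) -> str:
    return "." if code < 0 else str(int(code))


def read_vcf(path, roles: dict[str, str]) -> GenotypeData:
    """Read a VCF 4.2 into the genotype bundle.

    ``roles`` maps sample name to one of 'hi_parent', 'lo_parent',
    'recombinant' (see the sample sheet).  Parental genotypes must be
    diploid and recombinant genotypes haploid; a diploid call for a
    recombinant male is an error, since a male X carries one haplotype.
    """
    for sample, role in roles.items():
        if role not in ROLES:
            raise VcfParseError(f"unknown role {role!r} for sample {sample!r}")
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        header_lines = str(vcf.header).count("\n")
        samples = list(vcf.header.samples)
        missing = set(roles) - set(samples)
        if missing:
            raise VcfParseError(f"samples {sorted(missing)} not in VCF {path}")
        hi = [s for s in samples if roles.get(s) == "hi_parent"]
        lo = [s for s in samples if roles.get(s) == "lo_parent"]
        flies = [s for s in samples if roles.get(s) == "recombinant"]
        if not hi or not lo:
            raise VcfParseError("need at least one Hi and one Lo parental sample")
        parental = hi + lo
        chrom = None
        chrom_len = 0
        positions: list[int] = []
        par_rows: list[list[tuple[int, int]]] = []
        fly_rows: list[list[int]] = []
        for i, rec in enumerate(vcf):
            line_no = header_lines + i + 1
            if chrom is None:
                chrom = rec.chrom
                contig = vcf.header.contigs.get(rec.chrom)
                chrom_len = contig.length if contig and contig.length else 0
            elif rec.chrom != chrom:
                raise VcfParseError(
                    f"line {line_no}: multiple contigs ({chrom!r}, {rec.chrom!r})"
                )
            positions.append(rec.pos - 1)  # to 0-based
            prow = []
            for s in parental:
                gt = rec.samples[s]["GT"]
                if gt is None or len(gt) != 2:
                    raise VcfParseError(
                        f"line {line_no}: parental sample {s!r} must be diploid"
                    )
                prow.append(tuple(-1 if a is None else int(a) for a in gt))
            par_rows.append(prow)
            frow = []
            for s in flies:
                gt = rec.samples[s]["GT"]
                if gt is not None and len(gt) == 2 and gt.count(None) == 0:
                    raise VcfParseError(
                        f"line {line_no}: diploid call for recombinant male "
                        f"{s!r}; recombinant X genotypes must be haploid "
                        "(sample-ploidy 1)"
                    )
                allele = gt[0] if gt else None
                frow.append(-1 if allele is None else int(allele))
            fly_rows.append(frow)
    if not positions:
        raise VcfParseError(f"no records in {path}")
    positions_arr = np.array(positions, dtype=np.int64)
    if chrom_len == 0:
        chrom_len = int(positions_arr[-1]) + 1
    parental_calls = np.array(par_rows, dtype=np.int8).transpose(1, 0, 2)
    calls = (
        np.array(fly_rows, dtype=np.int8).T
        if flies
        else np.empty((0, len(positions)), np.int8)
    )
    return GenotypeData(
        chrom=chrom,
        chrom_len=chrom_len,
        positions=positions_arr,
        parental_samples=parental,
        n_hi=len(hi),
        parental_calls=parental_calls,
        fly_ids=flies,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# sample sheet, BED, TSV


def write_sample_sheet(path, roles: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample": list(roles), "role": list(roles.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "role"} <= set(df.columns):
        raise ValueError(f"sample sheet {path} needs 'sample' and 'role' columns")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)} in {path}")
    return dict(zip(df["sample"], df["role"]))


def write_tracts_bed(path, paintings, chrom: str = "X", header: str = "") -> None:
    """Painted (or truth) tracts as BED: chrom, start, end, origin, fly_id."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for p in paintings:
            fly = getattr(p, "fly_id", "")
            for origin, start, end in p.tracts():
                name = ORIGIN_NAMES.get(origin, str(origin))
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{fly}\n")


def write_regions_bed(path, regions: RegionSet, chrom: str = "X") -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.kind}\n")


def read_regions_bed(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"region BED needs 5 columns, got: {line!r}")
            _, start, end, label, kind = fields[:5]
            regions.append(Region(label, int(start), int(end), kind))
    return RegionSet(regions)


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    cols = [c for c in ("fly_id", "activity", "pool") if c in phenotypes.columns]
    phenotypes[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "fly_id" not in df.columns or "activity" not in df.columns:
        raise ValueError(f"phenotype TSV {path} needs fly_id and activity columns")
    return df


def write_label_matrix(path, paintings, order: list[str] | None = None) -> None:
    """Per-fly-by-site raw label matrix TSV (rows ordered by ``order``,
    typically descending activity — the cohort overview matrix)."""
    by_id = {p.fly_id: p for p in paintings}
    ids = order if order is not None else [p.fly_id for p in paintings]
    first = by_id[ids[0]]
    with open(path, "w") as fh:
        fh.write("fly_id\t" + "\t".join(str(p) for p in first.site_positions) + "\n")
        for fly in ids:
            p = by_id[fly]
            fh.write(
                fly
                + "\t"
                + "\t".join(LABEL_NAMES[int(l)] for l in p.site_labels)
                + "\n"
            )
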