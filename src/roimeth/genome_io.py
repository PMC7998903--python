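"""Reference/region/call I/O and reference CpG-site enumeration.

Coordinate conventions
----------------------
Internally everything is 0-based half-open (BED-style).  The Bismark coverage
dialect is 1-based with ``start == end`` at the cytosine position; the
conversion happens here, at the I/O boundary, and nowhere else.

A *CpG site* is one CG dinucleotide of the reference, anchored at the
forward-strand C (``pos`` is the 1-based coordinate of that C).  Calls landing
on the reverse-strand cytosine (the G position) are collapsed onto the anchor
by summing counts, which is the usual site-level RRBS convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FormatError, RegionError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in reference sequences.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True, order=True)
class CpGSite:
    """A CG dinucleotide, anchored at the 1-based position of its forward C."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class GenomicRegion:
    """A named genomic range of interest (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RegionError(
                f"region {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not self.name:
            raise RegionError("region name must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass(frozen=True)
class SiteCall:
    """Methylated/unmethylated read counts observed at one CpG site."""

    site: CpGSite
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self):
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise FormatError(f"negative read count at {self.site}")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated


@dataclass
class SampleCalls:
    """All calls of one sample, strand-collapsed onto reference CpG sites.

    ``non_cpg`` retains records whose position is not part of any reference CG
    dinucleotide; they are flagged and never enter region statistics.
    """

    calls: dict[CpGSite, SiteCall] = field(default_factory=dict)
    non_cpg: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def n_non_cpg(self) -> int:
        return len(self.non_cpg)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered ``{name: sequence}`` map.

    Sequences are uppercased; record order is preserved.  Raises
    :class:`FormatError` on an empty file, duplicate record names or
    non-IUPAC characters.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA record {record.id!r}", path=path)
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"record {record.id!r} contains non-IUPAC characters {sorted(bad)}",
                path=path,
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError("no FASTA records found", path=path)
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width (default 60)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CpG enumeration — the denominator of the region statistic
# ---------------------------------------------------------------------------

def enumerate_cpg_sites(sequence: str, region: GenomicRegion) -> list[CpGSite]:
    """Enumerate all possible CpG sites whose anchor C lies inside ``region``.

    A CG whose C is the last base of the region but whose G falls just outside
    still counts: membership is decided by the anchor base.  Sites are returned
    sorted by position.  Raises :class:`RegionError` if the region exceeds the
    sequence bounds.
    """
    if region.end > len(sequence):
        raise RegionError(
            f"region {region.name!r} [{region.start}, {region.end}) exceeds "
            f"sequence length {len(sequence)}"
        )
    sites = []
    # scan one base past the region end: the G partner may lie just outside
    window_end = min(region.end + 1, len(sequence))
    i = sequence.find("CG", region.start, window_end)
    while i != -1 and i < region.end:
        sites.append(CpGSite(chrom=region.chrom, pos=i + 1))
        i = sequence.find("CG", i + 1, window_end)
    return sites


def enumerate_reference_cpg_sites(sequences: Mapping[str, str]) -> list[CpGSite]:
    """Enumerate every CpG site of a whole reference, chromosome by chromosome."""
    sites = []
    for chrom, seq in sequences.items():
        if len(seq) < 2:
            continue
        region = GenomicRegion(chrom=chrom, start=0, end=len(seq), name=f"{chrom}:whole")
        sites.extend(enumerate_cpg_sites(seq, region))
    return sites


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def read_regions(path) -> list[GenomicRegion]:
    """Read BED3+name (tab-separated, 0-based half-open) regions.

    Names are required (they label the markers) and must be unique; order is
    preserved.  Malformed lines raise :class:`FormatError` with the line
    number.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    "BED line needs 4 columns (chrom, start, end, name)",
                    path=path, line=lineno,
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer BED coordinates", path=path, line=lineno)
            if start < 0 or start >= end:
                raise FormatError(
                    f"invalid interval [{start}, {end})", path=path, line=lineno
                )
            if not name:
                raise FormatError("empty region name", path=path, line=lineno)
            if name in seen:
                raise FormatError(f"duplicate region name {name!r}", path=path, line=lineno)
            seen.add(name)
            regions.append(GenomicRegion(chrom=chrom, start=start, end=end, name=name))
    if not regions:
        raise FormatError("no regions found", path=path)
    return regions


def write_regions(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Bismark coverage dialect
# ---------------------------------------------------------------------------

def read_methylation_calls(path, reference: Mapping[str, str]) -> SampleCalls:
    """Read a Bismark-coverage-dialect file and collapse strands.

    Dialect: ``chrom <TAB> start <TAB> end <TAB> %meth <TAB> n_meth <TAB>
    n_unmeth`` with 1-based inclusive ``start == end`` at the cytosine.

    Records at a position where the reference reads ``CG`` forward are mapped
    to that site; records at the G of a reference ``CG`` (reverse-strand
    cytosine) are merged into the forward anchor by summing counts; records at
    any other position are retained in ``non_cpg`` and logged.
    """
    path = Path(path)
    result = SampleCalls()
    merged: dict[CpGSite, list[int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError("coverage line needs 6 columns", path=path, line=lineno)
            chrom = fields[0]
            try:
                pos = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError:
                raise FormatError("non-numeric coverage fields", path=path, line=lineno)
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError("negative read counts", path=path, line=lineno)
            if chrom not in reference:
                raise FormatError(f"unknown chromosome {chrom!r}", path=path, line=lineno)
            seq = reference[chrom]
            if not (1 <= pos <= len(seq)):
                raise FormatError(
                    f"position {pos} outside {chrom} (length {len(seq)})",
                    path=path, line=lineno,
                )
            i = pos - 1  # 0-based index of the called base
            if seq[i] == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
                anchor = CpGSite(chrom=chrom, pos=pos)
            elif seq[i] == "G" and i >= 1 and seq[i - 1] == "C":
                anchor = CpGSite(chrom=chrom, pos=pos - 1)
            else:
                result.non_cpg.append((chrom, pos, n_meth, n_unmeth))
                continue
            counts = merged.setdefault(anchor, [0, 0])
            counts[0] += n_meth
            counts[1] += n_unmeth
    for site in sorted(merged):
        m, u = merged[site]
        result.calls[site] = SiteCall(site=site, count_methylated=m, count_unmethylated=u)
    if result.non_cpg:
        logger.warning(
            "%s: %d call(s) at non-CpG reference positions (excluded from region statistics)",
            path.name, len(result.non_cpg),
        )
    return result


def write_methylation_calls(calls: Iterable[SiteCall], path) -> None:
    """Write site calls in the Bismark coverage dialect (forward anchors only)."""
    with open(path, "w") as fh:
        for call in sorted(calls, key=lambda c: c.site):
            cov = call.coverage
            pct = 100.0 * call.count_methylated / cov if cov else 0.0
            fh.write(
                f"{call.site.chrom}\t{call.site.pos}\t{call.site.pos}\t"
                f"{pct:.6g}\t{call.count_methylated}\t{call.count_unmethylated}\n"
            )
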