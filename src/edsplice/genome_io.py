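"""Reference-format ingestion and coordinate normalisation.

All internal coordinates are 0-based half-open genome coordinates
(BED-style).  GTF (1-based closed) and VCF (1-based) are converted once,
at the parsing boundary, and never again.

Splice-site anchor convention used throughout the package:

==========  ========  ==========================================
kind        strand    boundary (the anchored base)
==========  ========  ==========================================
donor       \\+        intron start (first intronic base)
acceptor    \\+        intron end - 1 (last intronic base)
donor       \\-        intron end - 1 (first intronic base 5'->3')
acceptor    \\-        intron start (last intronic base 5'->3')
==========  ========  ==========================================

i.e. the boundary is always the first (donor) or last (acceptor)
intronic base *in transcript orientation*; all signed distances to
editing sites are measured from this base.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pyfaidx

__all__ = [
    "TranscriptModel",
    "SpliceSite",
    "SnpSet",
    "SiteDef",
    "Region",
    "GtfParseError",
    "VcfParseError",
    "revcomp",
    "load_gene_models",
    "write_gene_models",
    "derive_splice_sites",
    "load_known_snps",
    "fetch_sense_sequence",
    "read_sites_bed",
    "write_sites_bed",
    "read_regions_bed",
    "write_regions_bed",
    "open_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    pass


class VcfParseError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/intron structure of one transcript.

    Exons are ``(start, end)`` tuples in 0-based half-open genome
    coordinates, sorted by start and strictly non-overlapping.  Introns
    are derived as exactly the gaps between consecutive exons.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping or abutting exons at {s}"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class SpliceSite:
    """One donor (5'ss) or acceptor (3'ss), anchored per the module convention."""

    chrom: str
    strand: str
    kind: str  # "donor" | "acceptor"
    boundary: int
    intron_start: int
    intron_end: int
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"bad splice-site kind {self.kind!r}")
        expected = {
            ("donor", "+"): self.intron_start,
            ("acceptor", "+"): self.intron_end - 1,
            ("donor", "-"): self.intron_end - 1,
            ("acceptor", "-"): self.intron_start,
        }[(self.kind, self.strand)]
        if self.boundary != expected:
            raise ValueError(
                f"{self.kind}/{self.strand} boundary {self.boundary} does not "
                f"match intron ({self.intron_start},{self.intron_end})"
            )

    @property
    def intron(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)


@dataclass(frozen=True)
class SiteDef:
    """A candidate editing site: a stranded adenosine position."""

    chrom: str
    pos: int  # 0-based
    strand: str
    name: str = ""


@dataclass(frozen=True)
class Region:
    """A differentially spliced interval (external caller output or simulated)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name!r}: end must exceed start")


class SnpSet:
    """Exact-membership set of known SNP positions, 0-based, strand-agnostic."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()) -> None:
        self._positions = frozenset((str(c), int(p)) for c, p in positions)

    def __contains__(self, item: tuple[str, int]) -> bool:
        return (str(item[0]), int(item[1])) in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._positions))

    def __repr__(self) -> str:
        return f"SnpSet({len(self)} positions)"


def _as_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:
        yield from source


_TRANSCRIPT_ID_RE = re.compile(r'transcript_id\s+"([^"]+)"')
_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def load_gene_models(gtf) -> list[TranscriptModel]:
    """Parse exon features from GTF text into :class:`TranscriptModel` s.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Accepts a path, an open handle, or an iterable of lines.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(_as_lines(gtf), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"GTF line {lineno}: non-integer coordinate") from exc
        if strand not in ("+", "-"):
            raise GtfParseError(f"GTF line {lineno}: bad strand {strand!r}")
        m = _TRANSCRIPT_ID_RE.search(attrs)
        if not m:
            raise GtfParseError(f"GTF line {lineno}: exon without transcript_id")
        tx = m.group(1)
        rec = per_tx.setdefault(tx, {"chrom": chrom, "strand": strand, "exons": []})
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise GtfParseError(
                f"GTF line {lineno}: transcript {tx} spans chrom/strand combinations"
            )
        rec["exons"].append((start1 - 1, end1))
        if tx not in order:
            order.append(tx)
    models = []
    for tx in order:
        rec = per_tx[tx]
        models.append(
            TranscriptModel(
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
            )
        )
    return models


def write_gene_models(models: Sequence[TranscriptModel], path) -> None:
    """Write transcripts back to GTF (exon features only, 1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            gene = m.transcript_id.rsplit(".", 1)[0]
            for s, e in m.exons:
                attrs = f'gene_id "{gene}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tedsplice\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def derive_splice_sites(model: TranscriptModel) -> list[SpliceSite]:
    """One donor and one acceptor per intron, kinds assigned strand-aware.

    The donor is the 5' end of the intron in transcript orientation, so on
    the minus strand it sits at the genomic right edge of the intron.
    """
    sites: list[SpliceSite] = []
    for is_, ie in model.introns:
        if model.strand == "+":
            donor_b, acceptor_b = is_, ie - 1
        else:
            donor_b, acceptor_b = ie - 1, is_
        sites.append(
            SpliceSite(model.chrom, model.strand, "donor", donor_b, is_, ie,
                       model.transcript_id)
        )
        sites.append(
            SpliceSite(model.chrom, model.strand, "acceptor", acceptor_b, is_, ie,
                       model.transcript_id)
        )
    return sites


def load_known_snps(vcf) -> SnpSet:
    """Read CHROM/POS from VCF text into a :class:`SnpSet` (positions 0-based)."""
    positions: set[tuple[str, int]] = set()
    saw_header = False
    for lineno, raw in enumerate(_as_lines(vcf), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            saw_header = True
            continue
        if line.startswith("#CHROM"):
            saw_header = True
            continue
        if not saw_header:
            raise VcfParseError("VCF is missing its ## header lines")
        fields = line.split("\t")
        if len(fields) < 2:
            raise VcfParseError(f"VCF line {lineno}: fewer than 2 columns")
        try:
            pos1 = int(fields[1])
        except ValueError as exc:
            raise VcfParseError(f"VCF line {lineno}: non-integer POS") from exc
        positions.add((fields[0], pos1 - 1))
    if not saw_header:
        raise VcfParseError("VCF is missing its ## header lines")
    return SnpSet(positions)


def open_fasta(genome) -> pyfaidx.Fasta:
    if isinstance(genome, pyfaidx.Fasta):
        return genome
    return pyfaidx.Fasta(str(genome))


def fetch_sense_sequence(genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Uppercase sense-strand sequence of ``[start, end)``; revcomp on '-'."""
    fasta = open_fasta(genome)
    contig = fasta[chrom]
    if start < 0 or end > len(contig):
        raise ValueError(
            f"interval ({start},{end}) outside contig {chrom} of length {len(contig)}"
        )
    seq = str(contig[start:end]).upper()
    return revcomp(seq) if strand == "-" else seq


def read_sites_bed(path) -> list[SiteDef]:
    """BED6 editing sites; strand column required."""
    sites = []
    for lineno, raw in enumerate(_as_lines(path), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"sites BED line {lineno}: need 6 columns (strand required)")
        chrom, start, _end, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ValueError(f"sites BED line {lineno}: bad strand {strand!r}")
        sites.append(SiteDef(chrom, int(start), strand, name))
    return sites


def write_sites_bed(sites: Sequence[SiteDef], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.name}\t0\t{s.strand}\n")


def read_regions_bed(path) -> list[Region]:
    regions = []
    for lineno, raw in enumerate(_as_lines(path), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"regions BED line {lineno}: need >= 3 columns")
        chrom, start, end = fields[:3]
        name = fields[3] if len(fields) > 3 else f"region{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
        regions.append(Region(chrom, int(start), int(end), strand, name))
    return regions


def write_regions_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
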