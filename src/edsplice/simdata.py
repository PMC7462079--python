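"""Synthetic genome, gene models, and aligned reads with known truth.

The generator emulates the study conditions the downstream statistics are
built for: two genotype groups (WT / KO) in biological triplicate, per-site
editing levels that change between genotypes, junction-spanning reads whose
spliced/unspliced status is coupled to per-read edited status with a
controllable odds ratio, a flat per-base sequencing error rate, known-SNP
positions, and genes on both strands.

The read-level coupling uses the Plackett construction: given the splicing
margin psi, the editing margin epsilon, and a cross-product (odds) ratio
theta, the joint 2x2 cell probabilities are the unique table with those
margins and that ratio.  This is exactly the quantity the downstream Fisher
test estimates.

Every read over a locus is "informative" by construction (it spans the
focal exon/intron boundary with generous anchors), so ``coverage`` is the
number of informative fragments per junction per sample.

An intronic site poses an observability problem: a read drawn in a
"spliced & edited" joint class carries no copy of the edited base (the
intron is excised).  Such reads are emitted as plain spliced reads while
the truth table records the latent joint class — mirroring exactly the
ambiguity the co-occurrence analysis must handle.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .genome_io import Region, SiteDef, revcomp, write_regions_bed, write_sites_bed

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSpec",
    "SiteSpec",
    "SimDesign",
    "SimLayout",
    "GeneLayout",
    "SiteLayout",
    "build_joint",
    "coupled_site_spec",
    "simulate_genome",
    "simulate_reads",
    "simulate_all",
    "load_design",
    "default_fixture_design",
    "differential_editing_design",
    "cooccurrence_pair_design",
    "cooccurrence_null_design",
    "sample_names",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GeneSpec:
    """Exon/intron architecture of one simulated gene."""

    name: str
    strand: str = "+"
    exon_lengths: tuple[int, ...] = (150, 150)
    intron_lengths: tuple[int, ...] = (120,)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: bad strand")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(f"{self.name}: need one intron fewer than exons")
        if any(l < 20 for l in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"{self.name}: exon/intron lengths must be >= 20 nt")


@dataclass(frozen=True)
class SiteSpec:
    """One editing site tied to one exon/intron boundary of its host gene.

    ``offset`` is the signed distance from the boundary base in transcript
    orientation, + = upstream (exon side for a donor).  offset 0 is the
    boundary base itself (intronic).  ``psi``/``eps`` are the per-genotype
    splicing and editing levels; ``theta`` the read-level odds ratio
    coupling the two.
    """

    name: str
    gene: str
    intron_index: int = 0
    side: str = "donor"  # which boundary of the intron the site sits near
    offset: int = 2
    eps_wt: float = 0.5
    eps_ko: float = 0.0
    psi_wt: float = 0.7
    psi_ko: float = 0.7
    theta: float = 1.0
    is_snp: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"{self.name}: bad side {self.side!r}")
        for v in (self.eps_wt, self.eps_ko, self.psi_wt, self.psi_ko):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: psi/eps must lie in [0,1]")
        if self.theta <= 0:
            raise ValueError(f"{self.name}: theta must be positive")
        if abs(self.offset) > 80:
            raise ValueError(f"{self.name}: |offset| > 80 nt not supported")


def coupled_site_spec(
    name: str,
    gene: str,
    *,
    theta: float,
    eps_wt: float,
    eps_ko: float,
    spliced_prob_unedited: float = 0.7,
    **kwargs,
) -> SiteSpec:
    """Site spec whose splicing margins follow mechanistically from theta.

    Models a molecule-level mechanism: an unedited pre-mRNA is spliced with
    probability ``spliced_prob_unedited``; editing multiplies the splicing
    odds by ``theta``.  The genotype splicing level is then the mixture
    psi_g = eps_g * p_e + (1 - eps_g) * p_u, so a genotype that loses
    editing shifts its splicing level in the direction implied by theta.
    """
    p_u = spliced_prob_unedited
    odds_e = theta * p_u / (1.0 - p_u)
    p_e = odds_e / (1.0 + odds_e)
    psi_wt = eps_wt * p_e + (1.0 - eps_wt) * p_u
    psi_ko = eps_ko * p_e + (1.0 - eps_ko) * p_u
    return SiteSpec(
        name=name, gene=gene, theta=theta,
        eps_wt=eps_wt, eps_ko=eps_ko, psi_wt=psi_wt, psi_ko=psi_ko, **kwargs,
    )


def build_joint(psi: float, eps: float, theta: float) -> np.ndarray:
    """2x2 joint probability table over (spliced/unspliced x edited/unedited).

    Returns ``[[p_se, p_su], [p_ue, p_uu]]`` — the unique table with row
    margin (psi, 1-psi), column margin (eps, 1-eps) and cross-product ratio
    theta (Plackett construction; the standard quadratic in p_se).
    """
    if not (0.0 <= psi <= 1.0 and 0.0 <= eps <= 1.0):
        raise ValueError("psi and eps must lie in [0,1]")
    if theta <= 0 or not math.isfinite(theta):
        raise ValueError("theta must be positive and finite")
    if theta == 1.0:
        p_se = psi * eps
    else:
        s = 1.0 + (psi + eps) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * psi * eps
        if disc < 0:
            raise ValueError("no admissible joint table for these margins and theta")
        p_se = (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    cells = np.array(
        [[p_se, psi - p_se], [eps - p_se, 1.0 - psi - eps + p_se]], dtype=float
    )
    if (cells < -1e-9).any():
        raise ValueError("no admissible joint table for these margins and theta")
    cells = np.clip(cells, 0.0, 1.0)
    return cells / cells.sum()


@dataclass(frozen=True)
class GeneLayout:
    spec: GeneSpec
    start: int
    exons: tuple[tuple[int, int], ...]  # genome coordinates, left to right
    introns: tuple[tuple[int, int], ...]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class SiteLayout:
    spec: SiteSpec
    chrom: str
    pos: int  # genomic, 0-based
    strand: str
    boundary: int  # anchored boundary base (genome_io convention)
    junction: int  # the exon/intron transition the unspliced reads cross
    intron: tuple[int, int]
    context: str  # "exonic" | "intronic"

    @property
    def name(self) -> str:
        return self.spec.name

    def as_sitedef(self) -> SiteDef:
        return SiteDef(self.chrom, self.pos, self.strand, self.spec.name)


@dataclass
class SimLayout:
    chrom: str
    genome: str
    genes: dict[str, GeneLayout]
    sites: list[SiteLayout]
    snp_positions: list[int]


@dataclass(frozen=True)
class SimDesign:
    """Full specification of one simulated experiment."""

    seed: int = 0
    n_wt: int = 3
    n_ko: int = 3
    genes: tuple[GeneSpec, ...] = ()
    sites: tuple[SiteSpec, ...] = ()
    coverage: int = 50
    read_length: int = 100
    error_rate: float = 0.001
    n_random_snps: int = 0
    spacer: int = 150
    chrom: str = "simchr"
    base_quality: int = 40

    def __post_init__(self) -> None:
        if self.n_wt < 1 or self.n_ko < 1:
            raise ValueError("both genotype groups need at least one replicate")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.read_length < 40:
            raise ValueError("read_length must be >= 40 nt")
        gene_names = {g.name for g in self.genes}
        if len(gene_names) != len(self.genes):
            raise ValueError("duplicate gene names")
        site_names = {s.name for s in self.sites}
        if len(site_names) != len(self.sites):
            raise ValueError("duplicate site names")
        for s in self.sites:
            if s.gene not in gene_names:
                raise ValueError(f"site {s.name}: unknown gene {s.gene}")
            # feasibility of the joint tables, both genotypes
            build_joint(s.psi_wt, s.eps_wt, s.theta)
            build_joint(s.psi_ko, s.eps_ko, s.theta)


def sample_names(design: SimDesign) -> dict[str, str]:
    """Mapping sample name -> genotype ('WT' or 'KO')."""
    names = {f"WT{i + 1}": "WT" for i in range(design.n_wt)}
    names.update({f"KO{i + 1}": "KO" for i in range(design.n_ko)})
    return names


def _rngs(design: SimDesign) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(design.seed)
    g, r = ss.spawn(2)
    return np.random.default_rng(g), np.random.default_rng(r)


def _site_geometry(gene: GeneLayout, spec: SiteSpec) -> SiteLayout:
    strand = gene.spec.strand
    # intron_index is in transcript orientation
    introns_tx = gene.introns if strand == "+" else tuple(reversed(gene.introns))
    try:
        is_, ie = introns_tx[spec.intron_index]
    except IndexError:
        raise ValueError(f"site {spec.name}: gene {spec.gene} has no intron "
                         f"{spec.intron_index}") from None
    # boundary per genome_io convention; junction = the transition unspliced
    # reads must cross (donor side vs acceptor side of the intron)
    if spec.side == "donor":
        boundary = is_ if strand == "+" else ie - 1
        junction = is_ if strand == "+" else ie
    else:
        boundary = ie - 1 if strand == "+" else is_
        junction = ie if strand == "+" else is_
    pos = boundary - spec.offset if strand == "+" else boundary + spec.offset
    context = "intronic" if is_ <= pos < ie else "exonic"
    if not (gene.start <= pos < gene.end):
        raise ValueError(f"site {spec.name}: offset {spec.offset} leaves the gene body")
    return SiteLayout(
        spec=spec, chrom="", pos=pos, strand=strand, boundary=boundary,
        junction=junction, intron=(is_, ie), context=context,
    )


def simulate_genome(design: SimDesign, outdir) -> SimLayout:
    """Generate genome.fa(+.fai), models.gtf, snps.vcf, sites.bed, regions.bed.

    Deterministic given ``design.seed``.  Intron ends are canonical GT..AG
    in transcript orientation; every editing-site position carries an A on
    the sense strand (forced; a conflict with a canonical dinucleotide is
    an error).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_genome, _ = _rngs(design)

    # lay genes left to right along one contig
    genes: dict[str, GeneLayout] = {}
    total = design.spacer
    for gspec in design.genes:
        # genome-space exon lengths: transcript order reversed for '-' genes
        ex = list(gspec.exon_lengths)
        intr = list(gspec.intron_lengths)
        if gspec.strand == "-":
            ex, intr = ex[::-1], intr[::-1]
        exons = []
        introns = []
        pos = total
        gstart = pos
        for i, el in enumerate(ex):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intr):
                introns.append((pos, pos + intr[i]))
                pos += intr[i]
        genes[gspec.name] = GeneLayout(
            spec=gspec, start=gstart, exons=tuple(exons), introns=tuple(introns)
        )
        total = pos + design.spacer
    genome_len = total

    seq = rng_genome.choice(_BASES, size=genome_len)

    forced: dict[int, bytes] = {}

    def force(p: int, base: str, what: str) -> None:
        b = base.encode()
        if p in forced and forced[p] != b:
            raise ValueError(
                f"{what}: position {p} conflicts with an earlier forced base"
            )
        forced[p] = b
        seq[p] = b

    for g in genes.values():
        for is_, ie in g.introns:
            if g.spec.strand == "+":
                force(is_, "G", g.spec.name); force(is_ + 1, "T", g.spec.name)
                force(ie - 2, "A", g.spec.name); force(ie - 1, "G", g.spec.name)
            else:
                # sense GT..AG maps to genome AC at right edge, CT at left edge
                force(ie - 1, "C", g.spec.name); force(ie - 2, "A", g.spec.name)
                force(is_, "C", g.spec.name); force(is_ + 1, "T", g.spec.name)

    sites: list[SiteLayout] = []
    for sspec in design.sites:
        gl = genes[sspec.gene]
        layout = _site_geometry(gl, sspec)
        layout = replace(layout, chrom=design.chrom)
        sense_a = "A" if layout.strand == "+" else "T"
        force(layout.pos, sense_a, f"site {sspec.name}")
        sites.append(layout)

    genome = seq.tobytes().decode()

    # genome.fa + index
    fa_path = outdir / "genome.fa"
    with open(fa_path, "w") as fh:
        fh.write(f">{design.chrom}\n")
        for i in range(0, genome_len, 70):
            fh.write(genome[i : i + 70] + "\n")
    fai = Path(str(fa_path) + ".fai")
    if fai.exists():
        fai.unlink()
    pysam.faidx(str(fa_path))

    # models.gtf
    with open(outdir / "models.gtf", "w") as fh:
        for g in genes.values():
            tx = f"{g.spec.name}.t1"
            for s, e in g.exons:
                attrs = f'gene_id "{g.spec.name}"; transcript_id "{tx}";'
                fh.write(
                    f"{design.chrom}\tedsplice-sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.spec.strand}\t.\t{attrs}\n"
                )

    # snps.vcf — sites flagged is_snp plus random intergenic positions
    snp_positions = sorted(
        {s.pos for s in sites if s.spec.is_snp}
        | set(
            int(p)
            for p in rng_genome.integers(0, design.spacer, size=design.n_random_snps)
        )
    )
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
    with open(outdir / "snps.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={design.chrom},length={genome_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for p in snp_positions:
            ref = genome[p]
            fh.write(f"{design.chrom}\t{p + 1}\t.\t{ref}\t{alt[ref]}\t.\tPASS\t.\n")

    write_sites_bed([s.as_sitedef() for s in sites], outdir / "sites.bed")

    # regions.bed — the focal introns of genes whose splicing level changes
    regions = []
    for s in sites:
        if s.spec.psi_wt != s.spec.psi_ko:
            regions.append(
                Region(design.chrom, s.intron[0], s.intron[1], s.strand, s.spec.gene)
            )
    write_regions_bed(regions, outdir / "regions.bed")

    return SimLayout(
        chrom=design.chrom, genome=genome, genes=genes, sites=sites,
        snp_positions=snp_positions,
    )


_CLASSES = ("se", "su", "ue", "uu")  # spliced/unspliced x edited/unedited

# simulation anchors exceed the default classification anchor (6 nt) so that
# every emitted read is informative downstream
_SIM_ANCHOR = 8


def _emit_reads_for_site(
    rng: np.random.Generator,
    design: SimDesign,
    layout: SimLayout,
    site: SiteLayout,
    genotype: str,
) -> tuple[list[tuple], dict[str, int]]:
    """Reads (start, cigartuples, seq bytes) and latent class counts for one
    site/sample."""
    spec = site.spec
    psi = spec.psi_wt if genotype == "WT" else spec.psi_ko
    eps = spec.eps_wt if genotype == "WT" else spec.eps_ko
    probs = build_joint(psi, eps, spec.theta).ravel()
    counts = rng.multinomial(design.coverage, probs)
    n_by_class = dict(zip(_CLASSES, (int(c) for c in counts)))

    L = design.read_length
    A = _SIM_ANCHOR
    is_, ie = site.intron
    jn = site.junction
    pos = site.pos
    genome = layout.genome
    edited_base = b"G" if site.strand == "+" else b"C"

    # spliced-read start range: j = is_ - start exonic-left bases, anchors both sides
    jlo, jhi = A, L - A
    if site.context == "exonic":
        if pos < is_:
            jlo = max(jlo, is_ - pos)
        elif pos >= ie:
            jhi = min(jhi, L - (pos - ie) - 1)
    if jlo > jhi:
        raise ValueError(f"site {spec.name}: spliced reads cannot cover the site")

    # unspliced-read start range: cover [jn-A, jn+A) and the site position
    ulo = max(jn + A - L, pos - L + 1, 0)
    uhi = min(jn - A, pos)
    if ulo > uhi:
        raise ValueError(f"site {spec.name}: unspliced reads cannot cover the site")

    reads: list[tuple] = []
    n_intron = ie - is_
    for cls, n in n_by_class.items():
        if n == 0:
            continue
        spliced = cls[0] == "s"
        edited = cls[1] == "e"
        if spliced:
            js = rng.integers(jlo, jhi + 1, size=n)
            for j in js:
                j = int(j)
                start = is_ - j
                s = genome[start:is_] + genome[ie : ie + (L - j)]
                arr = np.frombuffer(s.encode(), dtype="S1").copy()
                if edited and site.context == "exonic":
                    idx = pos - start if pos < is_ else j + (pos - ie)
                    arr[idx] = edited_base
                # intronic edited base is excised: latent class only
                cig = ((0, j), (3, n_intron), (0, L - j))
                reads.append((start, cig, arr))
        else:
            starts = rng.integers(ulo, uhi + 1, size=n)
            for start in starts:
                start = int(start)
                s = genome[start : start + L]
                arr = np.frombuffer(s.encode(), dtype="S1").copy()
                if edited:
                    arr[pos - start] = edited_base
                cig = ((0, L),)
                reads.append((start, cig, arr))

    # sequencing errors, applied after the editing substitution
    if design.error_rate > 0 and reads:
        n_reads = len(reads)
        err = rng.random((n_reads, L)) < design.error_rate
        for i, (start, cig, arr) in enumerate(reads):
            hits = np.nonzero(err[i])[0]
            for h in hits:
                cur = arr[h]
                choices = _BASES[_BASES != cur]
                arr[h] = choices[rng.integers(0, len(choices))]
    return reads, n_by_class


def simulate_reads(design: SimDesign, layout: SimLayout, outdir) -> pd.DataFrame:
    """Per-sample sorted+indexed BAMs plus the truth table.

    Returns the truth DataFrame (one row per site x sample) and writes it
    to ``truth.tsv``.  Truth records the latent joint class counts and the
    realized editing/splicing levels before sequencing error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, rng_reads = _rngs(design)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": layout.chrom, "LN": len(layout.genome)}],
    }
    qual = pysam.qualitystring_to_array(chr(design.base_quality + 33) * design.read_length)

    truth_rows = []
    for sample, genotype in sample_names(design).items():
        all_reads: list[tuple] = []
        for site in layout.sites:
            reads, n_by_class = _emit_reads_for_site(
                rng_reads, design, layout, site, genotype
            )
            n_tot = sum(n_by_class.values())
            if n_tot == 0:
                warnings.warn(
                    f"sample {sample}, site {site.name}: zero informative reads",
                    stacklevel=2,
                )
            for i, r in enumerate(reads):
                all_reads.append((r[0], f"{site.name}:{sample}:{i}", r[1], r[2],
                                  site.strand))
            truth_rows.append(
                {
                    "sample": sample,
                    "genotype": genotype,
                    "pair_id": site.name,
                    "n_se": n_by_class["se"],
                    "n_su": n_by_class["su"],
                    "n_ue": n_by_class["ue"],
                    "n_uu": n_by_class["uu"],
                    "realized_eps": (n_by_class["se"] + n_by_class["ue"]) / n_tot
                    if n_tot else float("nan"),
                    "realized_psi": (n_by_class["se"] + n_by_class["su"]) / n_tot
                    if n_tot else float("nan"),
                }
            )
        all_reads.sort(key=lambda r: (r[0], r[1]))
        tmp = outdir / f".{sample}.unsorted.bam"
        bam_path = outdir / f"{sample}.bam"
        with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
            for start, qname, cig, arr, strand in all_reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = qname
                a.query_sequence = arr.tobytes().decode()
                a.flag = 16 if strand == "-" else 0
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = list(cig)
                a.query_qualities = qual
                bam.write(a)
        # --no-PG keeps BAMs byte-identical across runs (no path-bearing @PG)
        pysam.sort("--no-PG", "-o", str(bam_path), str(tmp))
        tmp.unlink()
        pysam.index(str(bam_path))

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth


def simulate_all(design: SimDesign, outdir) -> tuple[SimLayout, pd.DataFrame]:
    """Genome + reads in one call; the usual entry point."""
    layout = simulate_genome(design, outdir)
    truth = simulate_reads(design, layout, outdir)
    return layout, truth


def load_design(path) -> SimDesign:
    """Read a SimDesign from a YAML file (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("design YAML must be a mapping")
    genes = tuple(
        GeneSpec(
            name=g["name"],
            strand=g.get("strand", "+"),
            exon_lengths=tuple(g.get("exon_lengths", (150, 150))),
            intron_lengths=tuple(g.get("intron_lengths", (120,))),
        )
        for g in raw.pop("genes", [])
    )
    sites = tuple(
        SiteSpec(
            name=s["name"],
            gene=s["gene"],
            intron_index=s.get("intron_index", 0),
            side=s.get("side", "donor"),
            offset=s.get("offset", 2),
            eps_wt=s.get("eps_wt", 0.5),
            eps_ko=s.get("eps_ko", 0.0),
            psi_wt=s.get("psi_wt", 0.7),
            psi_ko=s.get("psi_ko", 0.7),
            theta=s.get("theta", 1.0),
            is_snp=s.get("is_snp", False),
        )
        for s in raw.pop("sites", [])
    )
    known = {f.name for f in SimDesign.__dataclass_fields__.values()}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"unknown design keys: {sorted(extra)}")
    return SimDesign(genes=genes, sites=sites, **raw)


def differential_editing_design(
    seed: int = 0,
    n_true: int = 100,
    n_null: int = 200,
    coverage: int = 50,
    eps_true_wt: float = 0.5,
    eps_null: float = 0.3,
) -> SimDesign:
    """Benchmark design for differential-editing recovery and calibration.

    3 vs 3 replicates; ``n_true`` exonic sites whose editing level drops
    from ``eps_true_wt`` to 0 in the KO, and ``n_null`` sites edited at
    ``eps_null`` in both genotypes.  Splicing is flat so the editing call
    is the only signal.
    """
    genes = []
    sites = []
    for i in range(n_true + n_null):
        strand = "+" if i % 2 == 0 else "-"
        name = f"t{i}" if i < n_true else f"n{i - n_true}"
        genes.append(GeneSpec(f"g_{name}", strand, (150, 150), (120,)))
        if i < n_true:
            eps_wt, eps_ko = eps_true_wt, 0.0
        else:
            eps_wt = eps_ko = eps_null
        sites.append(
            SiteSpec(name, f"g_{name}", side="donor", offset=2,
                     eps_wt=eps_wt, eps_ko=eps_ko, psi_wt=0.7, psi_ko=0.7)
        )
    return SimDesign(seed=seed, genes=tuple(genes), sites=tuple(sites),
                     coverage=coverage)


def cooccurrence_pair_design(
    seed: int,
    theta: float,
    coverage: int = 50,
    eps_wt: float = 0.6,
    eps_ko: float = 0.05,
) -> SimDesign:
    """One exonic pair with read-level coupling theta; 3 vs 3 replicates at
    ``coverage`` informative fragments each (300 pooled at the default)."""
    return SimDesign(
        seed=seed, coverage=coverage,
        genes=(GeneSpec("g", "+", (150, 150), (120,)),),
        sites=(coupled_site_spec("pair", "g", theta=theta,
                                 eps_wt=eps_wt, eps_ko=eps_ko,
                                 side="donor", offset=2),),
    )


def cooccurrence_null_design(
    seed: int = 0, n_pairs: int = 200, coverage: int = 50
) -> SimDesign:
    """``n_pairs`` exonic pairs with theta = 1 (no read-level association)."""
    genes = tuple(
        GeneSpec(f"g{i}", "+" if i % 2 == 0 else "-", (150, 150), (120,))
        for i in range(n_pairs)
    )
    sites = tuple(
        SiteSpec(f"p{i}", f"g{i}", side="donor", offset=2, theta=1.0,
                 eps_wt=0.3, eps_ko=0.3, psi_wt=0.6, psi_ko=0.6)
        for i in range(n_pairs)
    )
    return SimDesign(seed=seed, genes=genes, sites=sites, coverage=coverage)


def default_fixture_design(seed: int = 0) -> SimDesign:
    """A small mixed-strand fixture exercising every downstream stage."""
    genes = (
        GeneSpec("geneA", "+", (150, 150), (120,)),
        GeneSpec("geneB", "-", (150, 150), (120,)),
        GeneSpec("geneC", "+", (150, 150, 150), (120, 120)),
        GeneSpec("geneD", "-", (150, 150), (120,)),
        GeneSpec("geneE", "+", (150, 150), (120,)),
        GeneSpec("geneF", "+", (150, 150), (120,)),
    )
    sites = (
        # exonic R/G-type site 2 nt upstream of a donor; editing lost in KO,
        # read-level coupling theta=6 and a matching genotype splicing shift
        coupled_site_spec("siteA", "geneA", side="donor", offset=2,
                          theta=6.0, eps_wt=0.6, eps_ko=0.05),
        # minus-strand exonic site, coupling theta<1 (editing suppresses splicing)
        coupled_site_spec("siteB", "geneB", side="donor", offset=2,
                          theta=0.25, eps_wt=0.6, eps_ko=0.05),
        # intronic site near an acceptor of the second intron; steady editing
        SiteSpec("siteC", "geneC", intron_index=1, side="acceptor", offset=-5,
                 eps_wt=0.3, eps_ko=0.3, psi_wt=0.6, psi_ko=0.6),
        # the editable A of the acceptor AG (offset +1 from the boundary base)
        SiteSpec("siteD", "geneD", side="acceptor", offset=1,
                 eps_wt=0.4, eps_ko=0.0, psi_wt=0.7, psi_ko=0.7),
        # known SNP masquerading as an editing site: excluded downstream
        SiteSpec("siteE", "geneE", side="donor", offset=10,
                 eps_wt=0.5, eps_ko=0.5, psi_wt=0.8, psi_ko=0.8, is_snp=True),
        # null site: nothing changes
        SiteSpec("siteF", "geneF", side="donor", offset=-20,
                 eps_wt=0.2, eps_ko=0.2, psi_wt=0.5, psi_ko=0.5),
    )
    return SimDesign(seed=seed, genes=genes, sites=sites, coverage=60,
                     n_random_snps=3)
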