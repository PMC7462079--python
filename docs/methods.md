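# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open (BED-style); GTF (1-based
closed) and VCF (1-based) are converted once at the parsing boundary.
Splice sites are anchored on an intronic base: the donor boundary is the
first intronic base and the acceptor boundary the last intronic base, both
in transcript orientation. All signed distances between editing sites and
splice sites are measured from these bases, with **+ = upstream** in
transcript orientation (so a + strand donor at intron start 100 with an
exonic site at 98 has offset +2). This makes every distance rule symmetric
across strands; the strand-flip property (mirror the genome, reflect
coordinates, flip strands — derived kinds and sense-window sequences are
unchanged) is asserted in the test suite.

Editing sites on minus-strand genes are stored at their genomic position
with strand `-`; the edited base observed in genome space is then T→C,
because inosine reads as G on the sense strand.

## Editing quantification and differential calling

The counting unit is the fragment: overlapping mates vote once, and mates
that disagree at the site are tallied as `other`. Fragments failing
MAPQ ≥ 20, base quality ≥ 20, or flagged duplicate/secondary/supplementary
are excluded. These quality defaults are standard editing-pileup practice
and configurable; they are a design choice of this package, not a
reconstruction of any particular published filter chain.

The editing level is `edited / (edited + unedited)`, i.e. non-A/G calls are
excluded from the denominator so the level is a proper A→G proportion.
(The alternative — counting every spanning read in the denominator — is a
one-line change; at realistic error rates the two differ by well under a
percentage point.)

Differential calling applies, in order: known-SNP removal; the coverage
filter (≥ `min_cov` = 5 informative fragments in ≥ `min_samples` = 2
replicates of *each* group); Welch's unequal-variance *t*-test on
per-sample editing levels, two-sided, with the Welch–Satterthwaite degrees
of freedom. Degenerate inputs follow explicit contracts: both group
variances zero with equal means gives p = 1; with different means p = 0
and a degeneracy flag; a group with fewer than two usable levels skips the
site with a recorded reason. Sites with p ≤ α (default 0.1) are classed
`increase`/`decrease` by the sign of mean(KO) − mean(WT).

Welch on 3-vs-3 binomial proportions is an approximation; its empirical
type-I error at α = 0.1 and coverage 50 sits near 0.06–0.08 in the
calibration benchmark (the acceptance band [0.05, 0.16] reflects this
known mild conservatism/anti-conservatism envelope).

## Read-level co-occurrence

Pairs are every (splice site, editing site) on the same strand and contig
with |offset| ≤ 50 nt. Per fragment:

- **spliced** — an N gap in the CIGAR matches the annotated intron exactly
  at both ends, with ≥ 6 nt aligned on each flank;
- **unspliced** — contiguous alignment across the boundary with ≥ 6 nt on
  each side;
- otherwise excluded with a reason (novel junction, short anchor, no
  boundary overlap). The 6-nt anchor rejects 1–2 nt spurious overhangs;
  it is a package decision.

Edit status is the aligned sense base at the site (G = edited,
A = unedited, anything else excluded). An intronic site is invisible in a
spliced fragment; the default `absence_as_unedited` mode counts such
fragments as spliced-unedited (without this, intron-retention-linked pairs
with intronic sites could never be tested), while `strict` mode excludes
them. Neither choice is claimed to match any external implementation; both
are exposed. Note that in `absence_as_unedited` mode an intronic pair can
reach significance from observability alone even when θ = 1 — the
calibration benchmarks therefore use exonic sites, and intronic verdicts
should be read together with the per-sample levels.

Fisher's exact test (two-sided, sum of all margin-fixed tables no more
probable than the observed one) runs on counts pooled across all samples
of both genotypes; per-sample tables are kept for the regression.
Per-replicate testing would be an easy variant but pooling maximises
per-read pairing information. A zero row or column margin makes a pair
untestable (p undefined, reason reported) — never silently p = 1. Odds
ratios use the Haldane–Anscombe +0.5 correction when any cell is zero.
Benjamini–Hochberg is the multiple-testing correction (the field default),
applied across all testable pairs, with significance at q ≤ 0.1.

Editing level (se+ue)/n and splicing level (se+su)/n are computed from the
same classified fragments per sample, and splicing level is regressed on
editing level by OLS across all samples, genotype labels retained. Zero
variance in editing levels flags the fit undefined rather than erroring.

## Proximity binning and gene overlap

Each differential site is assigned to its nearest region edge: `overlap`
when inside the half-open interval, `upstream`/`downstream` when the edge
distance is in (0, window] (window default 5000 nt), `outside` otherwise.
Distance is `start − pos` left of a region and `pos − end` right of it;
with this end-exclusive convention the single base right-adjacent to a
region has distance 0 and falls outside the window bins — a documented
edge artefact. Ties between regions break toward the smaller distance,
then the earlier region in coordinate order; an `all_pairs` flag reports
every qualifying region instead of the nearest only. Orientation default
is `stranded` (upstream = 5′ of the region in transcript orientation);
`genomic` maps left to upstream unconditionally.

Gene-list overlap uses the upper-tail hypergeometric probability
P(X ≥ k) with the expressed gene universe as background, expected overlap
|A||B|/N, and a Haldane–Anscombe-corrected sample odds ratio.

## Splice-site windows and deltas

Windows follow the MaxEntScan geometry — 9 nt at the 5′ss (3 exonic +
6 intronic) and 23 nt at the 3′ss (20 intronic + 3 exonic), sense strand,
transcript orientation. The in-silico edit is a single A→G; applying it at
a non-A position is an error (it signals a site/window mismatch).

Effect classes: `creation` iff the edit is at intron position +1 with T at
+2 (A→G at +1 is the only A→G mechanism that can establish the canonical
GT donor dinucleotide); `disruption` iff the acceptor AG at −2/−1 becomes
GG (edit at the −2 A); `modulation` otherwise.

The built-in scorer is a per-position log-odds matrix,
`weight(pos, base) = log2(((count + pc)/(n + 4·pc)) / 0.25)` with
pseudocount 1, trained on annotated splice sites; a sequence scores as the
sum of its column weights, so an edit's delta depends only on the edited
column (asserted column-wise in tests). This is deliberately *not* a
maximum-entropy model: the delta analysis needs sign and magnitude of a
strength change, and a PWM trained on the supplied annotation provides
that without external model files. Where fidelity to MaxEntScan matters, a
k-mer → score table in its format can be supplied (`TableScorer` /
`--score-table-5ss/-3ss`) and is used verbatim.

## Synthetic data generator

One contig carries the specified genes left to right with 150-nt spacers.
Intron ends are canonical (GT..AG in transcript orientation) and every
editing-site position is forced to a sense-strand A; a site spec whose
position collides with a forced dinucleotide base of a different identity
is rejected. Known SNPs are emitted as a VCF (flagged sites plus random
intergenic positions), and the focal introns of genes whose splicing level
differs between genotypes are emitted as a regions BED, standing in for an
external differential-splicing caller's output.

Reads are single-end, default 100 nt, MAPQ 60, one base quality value
(Phred 40), with a flat per-base substitution error (default 0.001)
applied after the editing substitution. Every read spans its focal
boundary with ≥ 8 nt anchors — comfortably above the 6-nt classification
anchor — so `coverage` is the informative fragment count per junction and
sample. Paired-end fragments, indels, quality-profile realism and
between-gene expression variation are deliberately out of scope: the
generator exists to give the statistics a truth table, not to imitate a
sequencer. Consequently, passing benchmarks demonstrate correctness and
calibration of the inference given ideal alignments; they do not probe
alignment artefacts, coverage heterogeneity, or library-preparation biases
of real data.

Per read, the joint (spliced/unspliced × edited/unedited) class is drawn
from the Plackett table for the genotype's (ψ, ε) margins and the pair's
odds ratio θ — exactly the quantity the downstream Fisher test estimates.
For "coupled" pairs the generator derives the genotype splicing margins
from a molecule-level mechanism (unedited molecules spliced with
probability p_u, editing multiplying the splicing odds by θ), so a
genotype that loses editing shifts its splicing level in the direction
implied by θ; this is what makes the cross-sample regression slope sign
recover sign(log θ). A read drawn spliced-and-edited over an *intronic*
site is emitted as a plain spliced read (the edited base is excised) while
the truth table records the latent class — reproducing the observability
problem the co-occurrence analysis faces.

Determinism: one integer seed drives two spawned generator streams
(genome, reads); identical designs and seeds give byte-identical FASTA,
GTF, VCF, truth tables and BAMs (BAM sorting runs with `--no-PG` so no
path-bearing header line leaks in).

## Benchmark problem sizes

The standing benchmark designs, used by both the test suite and
`scripts/acceptance.py`, are: differential recovery — 3 vs 3 replicates,
coverage 50, 100 sites with ε 0.5→0 plus 200 null sites at ε 0.3;
co-occurrence power — 50 replicates of one exonic pair with θ = 6 and 300
pooled informative reads; size — 200 exonic θ = 1 pairs; slope-sign — the
50 θ = 6 replicates plus 50 at θ = 0.25; splice-site deltas — PWMs trained
on 50 simulated canonical sites per kind. These sizes give binomial
standard errors of a few percent on every reported rate while keeping a
full run in the tens of seconds on one CPU.

## Known limitations

- Welch's test on 3-vs-3 proportions is approximate; p-values near the
  α = 0.1 boundary should not be over-read.
- `absence_as_unedited` inflates association for intronic sites whose
  editing is coupled to retention — by construction. Use `strict` mode and
  the per-sample levels to interrogate such pairs.
- The PWM scorer is additive and position-independent; it cannot reproduce
  the pairwise dependencies a maximum-entropy model captures. Deltas from
  the two scorers agree in sign for canonical-dinucleotide events but not
  necessarily in magnitude.
- Overlapping transcripts: a site inside several gene models is paired
  with every same-strand splice site within the window; gene assignment
  for the overlap test takes the first containing model.
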