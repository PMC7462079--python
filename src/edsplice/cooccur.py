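"""Read-level co-occurrence of editing and splicing near splice sites.

For every (splice site, editing site) pair at most ``window`` nt apart,
each fragment spanning the locus is classified into one of four joint
classes — spliced-edited, spliced-unedited, unspliced-edited,
unspliced-unedited — or excluded with a reason.  The pooled 2x2 table is
tested with Fisher's exact test, p-values are corrected across pairs with
Benjamini-Hochberg, and per-sample (editing level, splicing level) points
are fit by ordinary least squares.

Sign convention for the editing-site offset (matches the figure
convention): + = upstream of the splice-site boundary base in transcript
orientation, - = downstream.  A + strand donor at intron start 100 with an
exonic site at 98 has es_offset = +2.

Splice status of a fragment:
  spliced    — an N gap matching the annotated intron exactly (both ends),
               with >= anchor nt aligned on each flank;
  unspliced  — contiguous alignment across the boundary with >= anchor on
               each side;
  excluded   — otherwise (novel junction, short anchor, no overlap).

An intronic editing site cannot be observed in a spliced fragment (the
base is excised).  In ``strict`` mode such fragments are excluded, which
can leave the pair untestable; in ``absence_as_unedited`` mode (default)
they count as spliced-unedited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import SiteDef, SpliceSite, TranscriptModel
from .editing_quant import _fragment_base, _passes_read_filters

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrencePair",
    "JointCounts",
    "FisherResult",
    "RegressionResult",
    "enumerate_pairs",
    "classify_fragment",
    "fisher_exact",
    "bh_adjust",
    "levels_and_regression",
    "run_cooccurrence",
]

JOINT_CLASSES = (
    "spliced_edited",
    "spliced_unedited",
    "unspliced_edited",
    "unspliced_unedited",
)


@dataclass(frozen=True)
class CooccurrencePair:
    """One (splice site, editing site <= window nt apart) testing unit."""

    splice_site: SpliceSite
    editing_site: SiteDef
    es_offset: int
    site_context: str  # "exonic" | "intronic"

    @property
    def pair_id(self) -> str:
        return (
            f"{self.editing_site.name or self.editing_site.pos}"
            f"@{self.splice_site.kind}:{self.splice_site.boundary}"
        )


@dataclass
class JointCounts:
    n_se: int = 0  # spliced-edited
    n_su: int = 0  # spliced-unedited
    n_ue: int = 0  # unspliced-edited
    n_uu: int = 0  # unspliced-unedited
    n_excluded: int = 0
    exclusions: dict = field(default_factory=dict)

    @property
    def informative(self) -> int:
        return self.n_se + self.n_su + self.n_ue + self.n_uu

    def add(self, label: str) -> None:
        if label == "spliced_edited":
            self.n_se += 1
        elif label == "spliced_unedited":
            self.n_su += 1
        elif label == "unspliced_edited":
            self.n_ue += 1
        elif label == "unspliced_unedited":
            self.n_uu += 1
        else:
            raise ValueError(label)

    def exclude(self, reason: str) -> None:
        self.n_excluded += 1
        self.exclusions[reason] = self.exclusions.get(reason, 0) + 1

    def table(self) -> np.ndarray:
        return np.array([[self.n_se, self.n_su], [self.n_ue, self.n_uu]], dtype=int)

    def __iadd__(self, other: "JointCounts") -> "JointCounts":
        self.n_se += other.n_se
        self.n_su += other.n_su
        self.n_ue += other.n_ue
        self.n_uu += other.n_uu
        self.n_excluded += other.n_excluded
        for k, v in other.exclusions.items():
            self.exclusions[k] = self.exclusions.get(k, 0) + v
        return self


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float
    testable: bool
    reason: str = ""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n_points: int
    defined: bool
    points: tuple = ()  # (sample, genotype, editing_level, splicing_level)


def _site_context(site_pos: int, intron: tuple[int, int]) -> str:
    return "intronic" if intron[0] <= site_pos < intron[1] else "exonic"


def enumerate_pairs(
    splice_sites: Sequence[SpliceSite],
    editing_sites: Sequence[SiteDef],
    window: int = 50,
) -> list[CooccurrencePair]:
    """All (splice site, editing site) pairs with |es_offset| <= window.

    Editing sites on a strand conflicting with the host transcript are
    skipped with a warning.
    """
    pairs = []
    for ss in splice_sites:
        for es in editing_sites:
            if es.chrom != ss.chrom:
                continue
            if abs(ss.boundary - es.pos) > window:
                continue
            if es.strand != ss.strand:
                logger.warning(
                    "editing site %s strand %s conflicts with transcript %s (%s); "
                    "pair skipped", es.name or es.pos, es.strand,
                    ss.transcript_id, ss.strand,
                )
                continue
            offset = (ss.boundary - es.pos) if ss.strand == "+" else (es.pos - ss.boundary)
            pairs.append(
                CooccurrencePair(
                    splice_site=ss,
                    editing_site=es,
                    es_offset=offset,
                    site_context=_site_context(es.pos, ss.intron),
                )
            )
    return pairs


def _junction_point(ss: SpliceSite) -> int:
    """Genome coordinate of the exon/intron transition an unspliced read
    must cross (a between-bases point)."""
    if ss.kind == "donor":
        return ss.intron_start if ss.strand == "+" else ss.intron_end
    return ss.intron_end if ss.strand == "+" else ss.intron_start


def _walk_cigar(read: pysam.AlignedSegment):
    """Aligned reference segments and N gaps: ([(s,e),...], [(s,e),...])."""
    segments: list[list[int]] = []
    gaps: list[tuple[int, int]] = []
    ref = read.reference_start
    open_seg = None
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M/=/X/D: contiguous on reference
            if open_seg is None:
                open_seg = [ref, ref + ln]
            else:
                open_seg[1] = ref + ln
            ref += ln
        elif op == 3:  # N: junction
            if open_seg is not None:
                segments.append(open_seg)
                open_seg = None
            gaps.append((ref, ref + ln))
            ref += ln
        # I/S consume no reference
    if open_seg is not None:
        segments.append(open_seg)
    return [tuple(s) for s in segments], gaps


_SENSE = {"+": {"G": "edited", "A": "unedited"}, "-": {"C": "edited", "T": "unedited"}}


def classify_fragment(
    reads: Sequence[pysam.AlignedSegment],
    pair: CooccurrencePair,
    mode: str = "absence_as_unedited",
    *,
    anchor: int = 6,
    min_baseq: int = 20,
    annotated_introns: frozenset = frozenset(),
) -> tuple[str | None, str]:
    """Joint class of one fragment, or (None, reason) when excluded.

    ``reads`` are the alignments of one fragment (one read for single-end
    data).  Returns ``(label, "")`` with label one of JOINT_CLASSES, or
    ``(None, reason)``.
    """
    if mode not in ("strict", "absence_as_unedited"):
        raise ValueError(f"unknown mode {mode!r}")
    ss = pair.splice_site
    intron = ss.intron
    jn = _junction_point(ss)
    pos = pair.editing_site.pos

    splice_status = None
    saw_novel = False
    base_calls: set[str] = set()
    for read in reads:
        segments, gaps = _walk_cigar(read)
        for g_s, g_e in gaps:
            if (g_s, g_e) == intron:
                left = next((s for s in segments if s[1] == g_s), None)
                right = next((s for s in segments if s[0] == g_e), None)
                if (
                    left and right
                    and left[1] - left[0] >= anchor
                    and right[1] - right[0] >= anchor
                ):
                    splice_status = "spliced"
            elif (g_s, g_e) not in annotated_introns:
                saw_novel = True
        if splice_status is None:
            for s_s, s_e in segments:
                if s_s <= jn - anchor and s_e >= jn + anchor:
                    splice_status = "unspliced"
                    break
        base = _fragment_base(read, pos, min_baseq)
        if base is not None:
            base_calls.add(base.upper())

    if splice_status is None:
        return (None, "novel_junction" if saw_novel else "uninformative_splice")

    if len(base_calls) > 1:
        return (None, "mate_conflict")
    if base_calls:
        status = _SENSE[pair.editing_site.strand].get(next(iter(base_calls)))
        if status is None:
            return (None, "ambiguous_base")
        edit_status = status
    else:
        if pair.site_context == "intronic" and splice_status == "spliced":
            if mode == "strict":
                return (None, "intronic_unobservable")
            edit_status = "unedited"
        else:
            return (None, "site_not_covered")

    return (f"{splice_status}_{edit_status}", "")


def fisher_exact(counts: JointCounts) -> FisherResult:
    """Two-sided Fisher's exact test on the pooled 2x2 joint table.

    p is the sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one.
    The odds ratio uses the Haldane-Anscombe +0.5 correction when any cell
    is zero.  A zero row or column margin makes the pair untestable
    (p undefined), never silently p = 1.
    """
    t = counts.table()
    if counts.informative < 1:
        return FisherResult(math.nan, math.nan, False, "no informative fragments")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) > 0:
        odds = (a * d) / (b * c)
    else:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if a + b == 0 or c + d == 0:
        return FisherResult(math.nan, odds, False, "zero splice-status margin")
    if a + c == 0 or b + d == 0:
        return FisherResult(math.nan, odds, False, "zero edit-status margin")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return FisherResult(p, odds, True)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def levels_and_regression(
    per_sample: Mapping[str, JointCounts],
    genotypes: Mapping[str, str],
) -> RegressionResult:
    """OLS of splicing level on editing level across samples.

    Editing level = (se+ue)/informative, splicing level = (se+su)/informative,
    computed from the same classified fragments; both genotypes are fit
    together (labels retained in the points).  Requires >= 2 samples with
    defined levels; zero variance in editing levels leaves the fit
    undefined (flagged), not an error.
    """
    points = []
    for sample, jc in per_sample.items():
        n = jc.informative
        if n < 1:
            continue
        eps = (jc.n_se + jc.n_ue) / n
        psi = (jc.n_se + jc.n_su) / n
        points.append((sample, genotypes.get(sample, "?"), eps, psi))
    if len(points) < 2:
        raise ValueError("regression needs >= 2 samples with defined levels")
    x = np.array([p[2] for p in points])
    y = np.array([p[3] for p in points])
    if np.allclose(x, x[0]):
        return RegressionResult(math.nan, math.nan, math.nan, len(points), False,
                                tuple(points))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2), n_points=len(points), defined=True,
        points=tuple(points),
    )


def _pack_per_sample(per_sample: Mapping[str, JointCounts]) -> str:
    return ";".join(
        f"{s}:{jc.n_se},{jc.n_su},{jc.n_ue},{jc.n_uu}"
        for s, jc in per_sample.items()
    )


def run_cooccurrence(
    bams: Mapping[str, str],
    pairs: Sequence[CooccurrencePair],
    genotypes: Mapping[str, str],
    *,
    alpha: float = 0.1,
    mode: str = "absence_as_unedited",
    anchor: int = 6,
    min_mapq: int = 20,
    min_baseq: int = 20,
    models: Sequence[TranscriptModel] = (),
) -> pd.DataFrame:
    """Classify, test, correct, and regress every pair.

    Fisher runs on counts pooled across all samples of both genotypes;
    per-sample tables feed the regression.  BH correction is applied
    across all testable pairs; significance is called at q <= alpha.
    Untestable pairs are retained in the output with their reason.
    """
    annotated = frozenset(i for m in models for i in m.introns)
    results = []
    for pair in pairs:
        ss = pair.splice_site
        lo = min(ss.intron_start, pair.editing_site.pos) - 400
        hi = max(ss.intron_end, pair.editing_site.pos) + 400
        pooled = JointCounts()
        per_sample: dict[str, JointCounts] = {}
        for sample, path in bams.items():
            jc = JointCounts()
            with pysam.AlignmentFile(str(path)) as bam:
                fragments: dict[str, list] = {}
                for read in bam.fetch(ss.chrom, max(lo, 0), hi):
                    if not _passes_read_filters(read, min_mapq):
                        continue
                    fragments.setdefault(read.query_name, []).append(read)
                for reads in fragments.values():
                    label, reason = classify_fragment(
                        reads, pair, mode, anchor=anchor, min_baseq=min_baseq,
                        annotated_introns=annotated,
                    )
                    if label is None:
                        jc.exclude(reason)
                    else:
                        jc.add(label)
            per_sample[sample] = jc
            pooled += jc
        fres = fisher_exact(pooled)
        try:
            reg = levels_and_regression(per_sample, genotypes)
        except ValueError:
            reg = RegressionResult(math.nan, math.nan, math.nan, 0, False)
        results.append(
            {
                "pair_id": pair.pair_id,
                "chrom": ss.chrom, "strand": ss.strand,
                "splice_kind": ss.kind, "boundary": ss.boundary,
                "intron_start": ss.intron_start, "intron_end": ss.intron_end,
                "site_name": pair.editing_site.name, "site_pos": pair.editing_site.pos,
                "es_offset": pair.es_offset, "site_context": pair.site_context,
                "n_se": pooled.n_se, "n_su": pooled.n_su,
                "n_ue": pooled.n_ue, "n_uu": pooled.n_uu,
                "n_excluded": pooled.n_excluded,
                "per_sample": _pack_per_sample(per_sample),
                "fisher_p": fres.p, "odds_ratio": fres.odds_ratio,
                "testable": fres.testable,
                "untestable_reason": fres.reason,
                "slope": reg.slope, "intercept": reg.intercept, "r2": reg.r2,
            }
        )
    out = pd.DataFrame(results)
    if len(out):
        out["q"] = np.nan
        testable = out["testable"].to_numpy(dtype=bool)
        if testable.any():
            out.loc[testable, "q"] = bh_adjust(out.loc[testable, "fisher_p"].to_numpy())
        out["significant"] = (out["q"] <= alpha).fillna(False)
    return out
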