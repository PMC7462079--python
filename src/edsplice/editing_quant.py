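"""Per-site A-to-I editing quantification and differential calling.

The editing level of a site is the fraction of informative fragments whose
sense-strand base at the site is G (inosine reads as guanosine):
``edited / (edited + unedited)``.  Fragments whose base is neither the
sense A nor the sense G are tallied as ``other`` and excluded from the
denominator, so the level is a proper A->G proportion.

Differential calling follows the study design the filters were written
for: a site must be covered by at least ``min_cov`` informative fragments
in at least ``min_samples_per_group`` replicates of *each* genotype group,
known SNPs are removed, and per-sample editing levels are compared between
groups with Welch's t-test; sites with p <= alpha (default 0.1) are
classified as increase/decrease by the sign of mean(KO) - mean(WT),
everything else is steady.

Counting unit is the fragment: overlapping mates vote once and disagreeing
mates count as ``other``.  Quality defaults (MAPQ >= 20, base quality
>= 20, duplicates/secondary/supplementary excluded) are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genome_io import SiteDef, SnpSet, fetch_sense_sequence, open_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "WelchResult",
    "quantify_editing",
    "editing_level_matrix",
    "filter_sites",
    "remove_snps",
    "welch_test",
    "call_differential",
]

_SENSE_CALL = {
    "+": {"G": "edited", "A": "unedited"},
    "-": {"C": "edited", "T": "unedited"},
}


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def _fragment_base(read: pysam.AlignedSegment, pos: int, min_baseq: int):
    """Aligned base and quality at a reference position, or None."""
    ref = read.reference_start
    q = 0
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):  # M/=/X consume both
            if ref <= pos < ref + ln:
                qi = q + (pos - ref)
                if read.query_qualities is not None and read.query_qualities[qi] < min_baseq:
                    return None
                return read.query_sequence[qi]
            ref += ln
            q += ln
        elif op in (2, 3):  # D/N consume reference
            if ref <= pos < ref + ln:
                return None
            ref += ln
        elif op in (1, 4):  # I/S consume query
            q += ln
    return None


def _passes_read_filters(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def quantify_editing(
    bams: Mapping[str, str],
    sites: Sequence[SiteDef],
    genome=None,
    *,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> pd.DataFrame:
    """Count edited/unedited/other fragments at every site in every sample.

    Parameters
    ----------
    bams
        Mapping of sample name to coordinate-sorted, indexed BAM path.
    sites
        Stranded candidate sites (sense-strand reference base must be A).
    genome
        Optional FASTA (path or pyfaidx.Fasta).  When given, every site's
        sense reference base is checked and non-A sites are rejected with a
        message that distinguishes a configuration error from a SNP.

    Returns
    -------
    Tidy DataFrame with one row per site x sample and columns
    ``name chrom pos strand sample edited unedited other``.
    """
    if genome is not None:
        fasta = open_fasta(genome)
        bad = [
            s for s in sites
            if fetch_sense_sequence(fasta, s.chrom, s.pos, s.pos + 1, s.strand) != "A"
        ]
        if bad:
            names = ", ".join(f"{s.name or s.chrom}:{s.pos}({s.strand})" for s in bad)
            raise ValueError(
                "sites whose sense-strand reference base is not A (check strand "
                f"annotation, or the position is a SNP, not an editing site): {names}"
            )

    rows = []
    for sample, path in bams.items():
        with pysam.AlignmentFile(str(path)) as bam:
            for site in sites:
                calls = _SENSE_CALL[site.strand]
                votes: dict[str, set[str]] = {}
                for read in bam.fetch(site.chrom, site.pos, site.pos + 1):
                    if not _passes_read_filters(read, min_mapq):
                        continue
                    base = _fragment_base(read, site.pos, min_baseq)
                    if base is None:
                        continue
                    votes.setdefault(read.query_name, set()).add(base.upper())
                edited = unedited = other = 0
                for bases in votes.values():
                    if len(bases) > 1:  # disagreeing mates
                        other += 1
                        continue
                    status = calls.get(next(iter(bases)), "other")
                    if status == "edited":
                        edited += 1
                    elif status == "unedited":
                        unedited += 1
                    else:
                        other += 1
                rows.append(
                    {
                        "name": site.name, "chrom": site.chrom, "pos": site.pos,
                        "strand": site.strand, "sample": sample,
                        "edited": edited, "unedited": unedited, "other": other,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["name", "chrom", "pos", "strand", "sample",
                 "edited", "unedited", "other"],
    )


def editing_level_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Site x sample matrix of editing levels (NaN when coverage is zero)."""
    df = counts.copy()
    cov = df["edited"] + df["unedited"]
    df["level"] = np.where(cov > 0, df["edited"] / cov.replace(0, np.nan), np.nan)
    return df.pivot_table(index="name", columns="sample", values="level",
                          dropna=False)


def filter_sites(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_cov: int = 5,
    min_samples_per_group: int = 2,
) -> pd.DataFrame:
    """Keep sites covered by >= min_cov fragments in >= min_samples_per_group
    samples of EACH group.

    Coverage is edited + unedited (informative fragments only).
    """
    for gname, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {gname!r} has zero samples")
    df = counts.copy()
    df["cov"] = df["edited"] + df["unedited"]
    keep = []
    for name, sub in df.groupby("name", sort=False):
        ok = True
        for members in groups.values():
            n_ok = (sub.loc[sub["sample"].isin(members), "cov"] >= min_cov).sum()
            if n_ok < min_samples_per_group:
                ok = False
                break
        if ok:
            keep.append(name)
    out = counts[counts["name"].isin(keep)].copy()
    logger.info("coverage filter: %d of %d sites kept",
                len(keep), counts["name"].nunique())
    return out


def remove_snps(counts: pd.DataFrame, snps: SnpSet) -> pd.DataFrame:
    """Drop sites at known SNP positions (strand-agnostic position match)."""
    mask = counts.apply(lambda r: (r["chrom"], r["pos"]) in snps, axis=1)
    n_removed = counts.loc[mask, "name"].nunique() if len(counts) else 0
    logger.info("SNP removal: %d sites dropped", n_removed)
    return counts[~mask].copy()


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny), df by Welch-Satterthwaite.
    Degenerate contracts: both variances zero and equal means -> p := 1;
    both zero and different means -> p := 0 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test needs at least 2 values per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0, degenerate=True)
        t = math.inf if mx > my else -math.inf
        return WelchResult(t=t, df=float(nx + ny - 2), p=0.0, degenerate=True)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def call_differential(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Welch's t-test per site on per-sample editing levels, WT vs KO.

    ``groups`` must contain keys "WT" and "KO".  Sites where either group
    has fewer than 2 samples with a defined editing level are reported with
    status ``skipped:<reason>`` and no test.  Output is sorted by p
    (tested sites first).

    Classes: increase iff p <= alpha and delta > 0; decrease iff p <= alpha
    and delta < 0; steady otherwise, with delta = mean_ko - mean_wt.
    """
    if "WT" not in groups or "KO" not in groups:
        raise ValueError('groups must contain "WT" and "KO"')
    wt, ko = list(groups["WT"]), list(groups["KO"])
    rows = []
    for name, sub in counts.groupby("name", sort=False):
        meta = sub.iloc[0]
        levels = {}
        for _, r in sub.iterrows():
            cov = r["edited"] + r["unedited"]
            if cov > 0:
                levels[r["sample"]] = r["edited"] / cov
        x = [levels[s] for s in wt if s in levels]
        y = [levels[s] for s in ko if s in levels]
        row = {
            "name": name, "chrom": meta["chrom"], "pos": meta["pos"],
            "strand": meta["strand"], "n_wt_used": len(x), "n_ko_used": len(y),
        }
        if len(x) < 2 or len(y) < 2:
            short = "WT" if len(x) < 2 else "KO"
            row.update(
                mean_wt=np.mean(x) if x else np.nan,
                mean_ko=np.mean(y) if y else np.nan,
                delta=np.nan, t=np.nan, df=np.nan, p=np.nan,
                cls="untested", status=f"skipped:<2 usable {short} samples",
            )
        else:
            res = welch_test(x, y)
            mean_wt, mean_ko = float(np.mean(x)), float(np.mean(y))
            delta = mean_ko - mean_wt
            if res.p <= alpha and delta > 0:
                cls = "increase"
            elif res.p <= alpha and delta < 0:
                cls = "decrease"
            else:
                cls = "steady"
            status = "tested" if not res.degenerate else "tested:degenerate-variance"
            row.update(
                mean_wt=mean_wt, mean_ko=mean_ko, delta=delta,
                t=res.t, df=res.df, p=res.p, cls=cls, status=status,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p", na_position="last", kind="mergesort")
        out = out.reset_index(drop=True)
    return out
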