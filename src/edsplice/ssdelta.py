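"""Splice-site strength deltas under in-silico A->G editing.

The scored windows follow the MaxEntScan geometry: 9 bases at the 5'
splice site (3 exonic + 6 intronic) and 23 bases at the 3' splice site
(20 intronic + 3 exonic), always read on the sense strand in transcript
orientation.  Each window containing an editing site is scored unedited
and with the single A->G substitution applied, and the delta classifies
the edit:

creation
    the edit establishes the canonical intron-initial GT (A->G at intron
    position +1 with T at +2) — the only A->G mechanism that can create
    a canonical 5' splice site;
disruption
    the acceptor AG at intron positions -2/-1 becomes GG (edit at the -2 A);
modulation
    any other in-window edit.

The built-in scorer is a position-specific log-odds matrix (PWM) trained
from annotated splice sites; an externally supplied k-mer -> score table
(MaxEntScan-compatible) can be plugged in instead via :class:`TableScorer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (SiteDef, SpliceSite, TranscriptModel,
                        derive_splice_sites, fetch_sense_sequence, open_fasta)

__all__ = [
    "SpliceSiteWindow",
    "PwmScorer",
    "TableScorer",
    "WINDOW_GEOMETRY",
    "extract_window",
    "window_offset_of",
    "train_pwm",
    "apply_edit",
    "delta_and_classify",
    "analyze_sites",
    "collect_true_site_sequences",
]

# kind -> (exonic nt, intronic nt, window length); donor window is
# exon|intron, acceptor window is intron|exon, in transcript orientation
WINDOW_GEOMETRY = {"donor": (3, 6, 9), "acceptor": (20, 3, 23)}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SpliceSiteWindow:
    """Sense-strand scoring window around one splice site."""

    splice_site: SpliceSite
    kind: str
    sequence: str
    edit_offset: int | None = None  # 0-based from the window's 5' end
    edited_sequence: str | None = None
    score_unedited: float = math.nan
    score_edited: float = math.nan
    effect_class: str = ""

    @property
    def delta(self) -> float:
        return self.score_edited - self.score_unedited


class PwmScorer:
    """Per-position log-odds weights; score = sum of column weights."""

    mode = "pwm"

    def __init__(self, weights: np.ndarray, kind: str):
        self.weights = np.asarray(weights, dtype=float)
        self.kind = kind
        if self.weights.shape[1] != 4:
            raise ValueError("weights must be positions x 4 bases (ACGT)")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def score(self, seq: str) -> float:
        if len(seq) != self.length:
            raise ValueError(
                f"sequence length {len(seq)} != scorer length {self.length}"
            )
        return float(
            sum(self.weights[i, _BASE_INDEX[b]] for i, b in enumerate(seq.upper()))
        )


class TableScorer:
    """Exact-length k-mer -> score lookup (MaxEntScan-compatible tables)."""

    mode = "table"

    def __init__(self, table: Mapping[str, float], kind: str):
        lengths = {len(k) for k in table}
        if len(lengths) != 1:
            raise ValueError("all k-mers in a score table must have one length")
        self._table = {k.upper(): float(v) for k, v in table.items()}
        self.length = lengths.pop()
        self.kind = kind

    @classmethod
    def from_tsv(cls, path, kind: str) -> "TableScorer":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kmer, score = line.split("\t")[:2]
                table[kmer] = float(score)
        return cls(table, kind)

    def score(self, seq: str) -> float:
        try:
            return self._table[seq.upper()]
        except KeyError:
            raise KeyError(f"k-mer {seq!r} not in score table") from None


def extract_window(genome, splice_site: SpliceSite) -> SpliceSiteWindow:
    """Sense-strand 9-nt (donor) or 23-nt (acceptor) window, unscored."""
    kind = splice_site.kind
    n_first, n_second, total = WINDOW_GEOMETRY[kind]
    is_, ie = splice_site.intron
    strand = splice_site.strand
    if kind == "donor":
        # 3 exonic + 6 intronic around the exon|intron transition
        if strand == "+":
            start, end = is_ - 3, is_ + 6
        else:
            start, end = ie - 6, ie + 3
    else:
        # 20 intronic + 3 exonic around the intron|exon transition
        if strand == "+":
            start, end = ie - 20, ie + 3
        else:
            start, end = is_ - 3, is_ + 20
    seq = fetch_sense_sequence(genome, splice_site.chrom, start, end, strand)
    assert len(seq) == total
    return SpliceSiteWindow(splice_site=splice_site, kind=kind, sequence=seq)


def window_offset_of(window: SpliceSiteWindow, site_pos: int) -> int | None:
    """0-based offset of a genomic position within the window's sense
    sequence, or None when outside."""
    ss = window.splice_site
    is_, ie = ss.intron
    kind, strand = window.kind, ss.strand
    if kind == "donor":
        start, end = (is_ - 3, is_ + 6) if strand == "+" else (ie - 6, ie + 3)
    else:
        start, end = (ie - 20, ie + 3) if strand == "+" else (is_ - 3, is_ + 20)
    if not start <= site_pos < end:
        return None
    return site_pos - start if strand == "+" else end - 1 - site_pos


def train_pwm(
    sequences: Sequence[str],
    kind: str,
    pseudocount: float = 1.0,
    background: float = 0.25,
) -> PwmScorer:
    """Log-odds PWM from true splice-site sequences.

    weight(pos, base) = log2(((count + pc) / (n + 4 pc)) / background).
    """
    if not sequences:
        raise ValueError("cannot train a PWM from zero sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("training sequences must share one length")
    length = lengths.pop()
    counts = np.zeros((length, 4), dtype=float)
    for s in sequences:
        for i, b in enumerate(s.upper()):
            counts[i, _BASE_INDEX[b]] += 1
    n = len(sequences)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PwmScorer(np.log2(freqs / background), kind)


def apply_edit(sequence: str, offset: int) -> str:
    """A->G at ``offset`` only; the base there must be A."""
    if not 0 <= offset < len(sequence):
        raise ValueError(f"offset {offset} outside window of length {len(sequence)}")
    if sequence[offset].upper() != "A":
        raise ValueError(
            f"window base at offset {offset} is {sequence[offset]!r}, not A "
            "(site/window mismatch)"
        )
    return sequence[:offset] + "G" + sequence[offset + 1 :]


def _effect_class(window: SpliceSiteWindow, offset: int) -> str:
    seq = window.sequence
    if window.kind == "donor":
        # window = 3 exonic | 6 intronic; intron +1 is index 3
        if offset == 3 and len(seq) > 4 and seq[4].upper() == "T":
            return "creation"
    else:
        # window = 20 intronic | 3 exonic; acceptor AG is indices 18,19
        if offset == 18 and seq[19].upper() == "G":
            return "disruption"
    return "modulation"


def delta_and_classify(
    window: SpliceSiteWindow, offset: int, scorer
) -> SpliceSiteWindow:
    """Score both variants of the window and classify the edit's effect."""
    if getattr(scorer, "kind", window.kind) != window.kind:
        raise ValueError(
            f"scorer trained for {scorer.kind!r} cannot score a {window.kind} window"
        )
    edited = apply_edit(window.sequence, offset)
    return replace(
        window,
        edit_offset=offset,
        edited_sequence=edited,
        score_unedited=scorer.score(window.sequence),
        score_edited=scorer.score(edited),
        effect_class=_effect_class(window, offset),
    )


def collect_true_site_sequences(
    genome, models: Sequence[TranscriptModel]
) -> dict[str, list[str]]:
    """Annotated donor/acceptor window sequences, for PWM training."""
    out: dict[str, list[str]] = {"donor": [], "acceptor": []}
    fasta = open_fasta(genome)
    for m in models:
        for ss in derive_splice_sites(m):
            out[ss.kind].append(extract_window(fasta, ss).sequence)
    return out


def analyze_sites(
    genome,
    models: Sequence[TranscriptModel],
    sites: Sequence[SiteDef],
    donor_scorer=None,
    acceptor_scorer=None,
) -> pd.DataFrame:
    """Scored deltas for every editing site that falls inside a splice-site
    window of its host strand.

    Scorers default to PWMs trained on the annotated splice sites of the
    supplied gene models.
    """
    fasta = open_fasta(genome)
    if donor_scorer is None or acceptor_scorer is None:
        training = collect_true_site_sequences(fasta, models)
        if donor_scorer is None:
            donor_scorer = train_pwm(training["donor"], "donor")
        if acceptor_scorer is None:
            acceptor_scorer = train_pwm(training["acceptor"], "acceptor")
    scorers = {"donor": donor_scorer, "acceptor": acceptor_scorer}

    rows = []
    for m in models:
        for ss in derive_splice_sites(m):
            window = extract_window(fasta, ss)
            for site in sites:
                if site.chrom != ss.chrom or site.strand != ss.strand:
                    continue
                offset = window_offset_of(window, site.pos)
                if offset is None:
                    continue
                scored = delta_and_classify(window, offset, scorers[ss.kind])
                rows.append(
                    {
                        "site_name": site.name, "site_pos": site.pos,
                        "strand": ss.strand, "kind": ss.kind,
                        "boundary": ss.boundary,
                        "window": scored.sequence,
                        "edited_window": scored.edited_sequence,
                        "edit_offset": offset,
                        "score_unedited": scored.score_unedited,
                        "score_edited": scored.score_edited,
                        "delta": scored.delta,
                        "effect_class": scored.effect_class,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["site_name", "site_pos", "strand", "kind", "boundary", "window",
                 "edited_window", "edit_offset", "score_unedited", "score_edited",
                 "delta", "effect_class"],
    )
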