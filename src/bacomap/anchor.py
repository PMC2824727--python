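"""Mate-pair anchoring of BAC-end sequences against a reference.

Reads BLAST tabular alignments, classifies each end read by
mappability (0 / 1 / >1 loci), rescues multi-mapped ends via a uniquely
mapped mate, and calls each clone concordant or discordant with the
violation category (indel / inversion / translocation).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "BesAlignment",
    "ReadAnchor",
    "Thresholds",
    "CloneAnchorCall",
    "Locus",
    "parse_blast_tab",
    "classify_mappability",
    "rescue_multi",
    "classify_pair",
    "anchor_clone",
    "call_clones",
    "summarize_anchors",
]

END_LABELS = ("T7", "SP6")

KLASSES = (
    "no_anchor",
    "single_end",
    "concordant",
    "discordant_indel_assignable",
    "discordant_large_or_complex",
    "discordant_inversion",
    "discordant_translocation",
)

_READ_ID_RE = re.compile(r"^(?P<clone>.+)_(?P<end>T7|SP6)$")


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("locus start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class BesAlignment:
    read_id: str
    clone_id: str
    end_label: str
    target_chrom: str
    start: int
    end: int
    strand: str
    bit_score: float
    e_value: float
    identity: float

    @property
    def locus(self) -> Locus:
        return Locus(self.target_chrom, self.start, self.end, self.strand)


@dataclass
class ReadAnchor:
    read_id: str
    status: str  # unmapped | unique | multi | rescued
    chosen_locus: Optional[Locus] = None
    n_candidates: int = 0
    candidates: List[Locus] = field(default_factory=list)

    def __post_init__(self):
        has_locus = self.chosen_locus is not None
        if has_locus != (self.status in ("unique", "rescued")):
            raise ValueError(
                f"status {self.status} inconsistent with chosen_locus"
            )


@dataclass(frozen=True)
class Thresholds:
    concordant_min: int = 90_000
    concordant_max: int = 200_000
    large_indel: int = 2_000_000

    def __post_init__(self):
        if not (0 < self.concordant_min < self.concordant_max < self.large_indel):
            raise ValueError(
                "need 0 < concordant_min < concordant_max < large_indel"
            )


@dataclass
class CloneAnchorCall:
    clone_id: str
    klass: str
    span: Optional[int] = None
    assigned_interval: Optional[Tuple[str, int, int]] = None
    locus_a: Optional[Locus] = None
    locus_b: Optional[Locus] = None

    def __post_init__(self):
        if self.klass not in KLASSES:
            raise ValueError(f"unknown klass {self.klass!r}")


class BlastParseError(ValueError):
    pass


def parse_blast_tab(path) -> List[BesAlignment]:
    """Parse 12-column BLAST tabular text (outfmt 6).

    Subject coordinates are 1-based inclusive with strand encoded by
    sstart > send; they are converted to 0-based half-open plus an
    explicit strand.  Read ids must look like {clone}_{T7|SP6}.
    Malformed rows raise BlastParseError naming the line.
    """
    out: List[BesAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise BlastParseError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            m = _READ_ID_RE.match(qid)
            if not m:
                raise BlastParseError(
                    f"line {lineno}: read id {qid!r} does not match "
                    "{clone}_{T7|SP6}"
                )
            try:
                pident = float(fields[2])
                sstart = int(fields[8])
                send = int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise BlastParseError(f"line {lineno}: {exc}") from None
            if sstart <= send:
                start, end, strand = sstart - 1, send, "+"
            else:
                start, end, strand = send - 1, sstart, "-"
            out.append(BesAlignment(
                read_id=qid,
                clone_id=m.group("clone"),
                end_label=m.group("end"),
                target_chrom=sid,
                start=start,
                end=end,
                strand=strand,
                bit_score=bitscore,
                e_value=evalue,
                identity=pident,
            ))
    return out


def classify_mappability(hits: Sequence[BesAlignment],
                         best_margin: float = 0.0) -> ReadAnchor:
    """0 hits -> unmapped; 1 -> unique; >=2 -> multi (candidates kept).

    With ``best_margin`` > 0, a read whose best bit score beats the
    runner-up by more than the margin is treated as unique (off by
    default: uniqueness is count-based).
    """
    if not hits:
        return ReadAnchor(read_id="", status="unmapped")
    read_id = hits[0].read_id
    if len(hits) == 1:
        return ReadAnchor(read_id=read_id, status="unique",
                          chosen_locus=hits[0].locus, n_candidates=1)
    ranked = sorted(hits, key=lambda h: -h.bit_score)
    if best_margin > 0 and ranked[0].bit_score - ranked[1].bit_score > best_margin:
        return ReadAnchor(read_id=read_id, status="unique",
                          chosen_locus=ranked[0].locus,
                          n_candidates=len(hits),
                          candidates=[h.locus for h in ranked])
    return ReadAnchor(read_id=read_id, status="multi",
                      n_candidates=len(hits),
                      candidates=[h.locus for h in ranked])


def _pair_geometry(a: Locus, b: Locus, t: Thresholds) -> str:
    if a.chrom != b.chrom:
        return "discordant_translocation"
    if a.strand == b.strand:
        return "discordant_inversion"
    # strand participates in the tie-break so coincident loci sort stably
    left, right = sorted((a, b), key=lambda l: (l.start, l.end, l.strand))
    if not (left.strand == "+" and right.strand == "-"):
        return "discordant_inversion"  # opposite strands but facing outward
    span = max(a.end, b.end) - min(a.start, b.start)
    if t.concordant_min <= span <= t.concordant_max:
        return "concordant"
    if span > t.large_indel:
        return "discordant_large_or_complex"
    return "discordant_indel_assignable"


def classify_pair(a: Locus, b: Locus, t: Thresholds,
                  clone_id: str = "") -> CloneAnchorCall:
    """Concordance call for a clone with two resolved end loci.

    Span is the outer distance (leftmost start to rightmost end); the
    concordant window is closed.  Different chromosomes -> translocation;
    same strand or outward-facing -> inversion; in-window span ->
    concordant; otherwise indel (assignable) or, beyond the large-indel
    cutoff, large/complex.
    """
    if a is None or b is None:
        raise ValueError("classify_pair requires two resolved loci")
    klass = _pair_geometry(a, b, t)
    span = None
    interval = None
    if a.chrom == b.chrom:
        span = max(a.end, b.end) - min(a.start, b.start)
        if klass in ("concordant", "discordant_indel_assignable"):
            interval = (a.chrom, min(a.start, b.start), max(a.end, b.end))
    return CloneAnchorCall(clone_id=clone_id, klass=klass, span=span,
                           assigned_interval=interval, locus_a=a, locus_b=b)


def rescue_multi(read: ReadAnchor, mate_locus: Locus,
                 t: Thresholds) -> ReadAnchor:
    """Use a uniquely mapped mate to pick among a multi-read's candidate
    loci: keep the candidate that would form a concordant pair.  Exactly
    one qualifying candidate -> rescued; zero or several -> still multi.
    """
    if read.status != "multi":
        return read
    qualifying = [
        c for c in read.candidates
        if _pair_geometry(c, mate_locus, t) == "concordant"
    ]
    if len(qualifying) == 1:
        return ReadAnchor(read_id=read.read_id, status="rescued",
                          chosen_locus=qualifying[0],
                          n_candidates=read.n_candidates,
                          candidates=list(read.candidates))
    return read


def anchor_clone(clone_id: str, anchors: Sequence[ReadAnchor],
                 t: Thresholds) -> CloneAnchorCall:
    """Combine up to two end anchors into a per-clone call."""
    if len(anchors) > 2:
        raise ValueError(f"clone {clone_id}: more than 2 end reads")
    resolved = [a.chosen_locus for a in anchors if a.chosen_locus is not None]
    if len(resolved) == 2:
        return classify_pair(resolved[0], resolved[1], t, clone_id=clone_id)
    if len(resolved) == 1:
        loc = resolved[0]
        return CloneAnchorCall(
            clone_id=clone_id, klass="single_end",
            assigned_interval=(loc.chrom, loc.start, loc.end), locus_a=loc,
        )
    return CloneAnchorCall(clone_id=clone_id, klass="no_anchor")


def call_clones(alignments: Iterable[BesAlignment],
                t: Thresholds) -> Tuple[Dict[str, CloneAnchorCall],
                                        Dict[str, ReadAnchor]]:
    """Full anchoring pass: mappability, one round of mate rescue, then
    per-clone classification.  Returns (calls by clone, anchors by read).
    """
    by_read: Dict[str, List[BesAlignment]] = defaultdict(list)
    clone_reads: Dict[str, Dict[str, str]] = defaultdict(dict)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
        clone_reads[aln.clone_id][aln.end_label] = aln.read_id
    anchors: Dict[str, ReadAnchor] = {}
    for read_id, hits in by_read.items():
        anc = classify_mappability(hits)
        anc.read_id = read_id
        anchors[read_id] = anc
    # one round of mate rescue from unique mates only
    for clone_id, ends in clone_reads.items():
        labels = list(ends)
        for lab in labels:
            mate_labels = [l for l in labels if l != lab]
            if not mate_labels:
                continue
            me = anchors[ends[lab]]
            mate = anchors[ends[mate_labels[0]]]
            if me.status == "multi" and mate.status == "unique":
                anchors[ends[lab]] = rescue_multi(me, mate.chosen_locus, t)
    calls = {}
    for clone_id, ends in clone_reads.items():
        calls[clone_id] = anchor_clone(
            clone_id, [anchors[r] for r in ends.values()], t,
        )
    return calls, anchors


def summarize_anchors(calls: Iterable[CloneAnchorCall]) -> pd.DataFrame:
    """Fixed-order counts per klass plus one-end/both-end totals."""
    counts = {k: 0 for k in KLASSES}
    for c in calls:
        counts[c.klass] += 1
    both = sum(v for k, v in counts.items()
               if k not in ("no_anchor", "single_end"))
    rows = [(k, counts[k]) for k in KLASSES]
    rows.append(("anchored_single_end", counts["single_end"]))
    rows.append(("anchored_both_ends", both))
    rows.append(("total_clones", sum(counts.values())))
    return pd.DataFrame(rows, columns=["category", "count"])


def calls_to_frame(calls: Dict[str, CloneAnchorCall]) -> pd.DataFrame:
    rows = []
    for cid in sorted(calls):
        c = calls[cid]
        def loc_cols(l):
            if l is None:
                return ("", "", "", "")
            return (l.chrom, l.start, l.end, l.strand)
        rows.append((cid, c.klass, *loc_cols(c.locus_a), *loc_cols(c.locus_b),
                     c.span if c.span is not None else ""))
    return pd.DataFrame(rows, columns=[
        "clone_id", "klass",
        "chrom_a", "start_a", "end_a", "strand_a",
        "chrom_b", "start_b", "end_b", "strand_b", "span",
    ])
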