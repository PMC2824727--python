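"""Comparative-map construction from a FISH marker table.

Markers carry a cytogenetic query position (chromosome + integer rank,
no orientation) and a physical target position (chromosome + bp).  This
module calls conserved-synteny blocks, tabulates chromosome
correspondence, condenses markers into signed segments for the
rearrangement engine, and (de)serializes the classic GRIMM genome text
dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .rearrange import SignedGenome

__all__ = [
    "Marker",
    "SyntenyBlock",
    "SegmentedGenomes",
    "load_marker_table",
    "call_blocks",
    "chromosome_correspondence",
    "condense",
    "write_grimm",
    "read_grimm",
]

REQUIRED_COLUMNS = ("clone_id", "query_chrom", "query_rank",
                    "target_chrom", "target_pos")


@dataclass(frozen=True)
class Marker:
    clone_id: str
    query_chrom: str
    query_rank: int
    target_chrom: str
    target_pos: int

    def __post_init__(self):
        if self.query_rank < 1:
            raise ValueError("query_rank must be >= 1")


@dataclass
class SyntenyBlock:
    query_chrom: str
    members: List[Marker]
    target_chrom: str

    @property
    def n_markers(self) -> int:
        return len(self.members)

    @property
    def target_span(self) -> int:
        pos = [m.target_pos for m in self.members]
        return max(pos) - min(pos)

    @property
    def orientation(self) -> str:
        if len(self.members) == 1:
            return "singleton"
        pos = [m.target_pos for m in self.members]
        if all(a < b for a, b in zip(pos, pos[1:])):
            return "+"
        if all(a > b for a, b in zip(pos, pos[1:])):
            return "-"
        return "mixed"


@dataclass
class SegmentedGenomes:
    """Signed-segment condensation of a marker table.

    ``genome_query`` carries inferred signs; ``genome_target`` is the
    identity ordering (segments sorted by target position, all '+').
    Singleton segments have no inferable sign and are listed in
    ``ambiguous_segments`` with a provisional '+'.
    """

    genome_query: SignedGenome
    genome_target: SignedGenome
    ambiguous_segments: Tuple[int, ...]
    segment_markers: Dict[int, List[str]] = field(default_factory=dict)
    query_chrom_names: Tuple[str, ...] = ()
    target_chrom_names: Tuple[str, ...] = ()

    @property
    def n_segments(self) -> int:
        return self.genome_query.n_segments

    def target_chrom_of(self, segment_id: int) -> str:
        for name, chrom in zip(self.target_chrom_names,
                               self.genome_target.chromosomes):
            if segment_id in chrom:
                return name
        raise KeyError(segment_id)


def _natural_key(label: str):
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def load_marker_table(path_or_df) -> List[Marker]:
    """Load and validate the 5-column marker TSV.

    Markers come back sorted by (query_chrom, query_rank); tied ranks
    (unresolved FISH pairs) are allowed and kept.  Duplicate clone ids
    are rejected by name.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing column(s): {missing}")
    dup = df["clone_id"][df["clone_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate clone id(s): {sorted(set(dup))}")
    try:
        ranks = df["query_rank"].astype(int)
        pos = df["target_pos"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric rank/position: {exc}") from None
    markers = [
        Marker(str(r.clone_id), str(r.query_chrom), int(rank),
               str(r.target_chrom), int(tp))
        for r, rank, tp in zip(df.itertuples(), ranks, pos)
    ]
    markers.sort(key=lambda m: (_natural_key(m.query_chrom), m.query_rank,
                                _natural_key(m.target_chrom), m.target_pos))
    return markers


def _by_query_chrom(markers: Sequence[Marker]) -> Dict[str, List[Marker]]:
    out: Dict[str, List[Marker]] = {}
    for m in markers:
        out.setdefault(m.query_chrom, []).append(m)
    for chrom in out.values():
        chrom.sort(key=lambda m: (m.query_rank, _natural_key(m.target_chrom),
                                  m.target_pos))
    return out


def call_blocks(markers: Sequence[Marker]) -> List[SyntenyBlock]:
    """Maximal runs of consecutive markers (per query chromosome) that
    share a target chromosome."""
    blocks: List[SyntenyBlock] = []
    for qc in sorted(_by_query_chrom(markers), key=_natural_key):
        run: List[Marker] = []
        for m in _by_query_chrom(markers)[qc]:
            if run and m.target_chrom != run[-1].target_chrom:
                blocks.append(SyntenyBlock(qc, run, run[-1].target_chrom))
                run = []
            run.append(m)
        if run:
            blocks.append(SyntenyBlock(qc, run, run[-1].target_chrom))
    return blocks


def chromosome_correspondence(blocks: Sequence[SyntenyBlock]) -> Tuple[
        Dict[str, List[str]], Dict[str, List[str]]]:
    """Many-to-many chromosome correspondence from the block list:
    (target -> query chromosomes, query -> target chromosomes)."""
    t2q: Dict[str, set] = {}
    q2t: Dict[str, set] = {}
    for b in blocks:
        t2q.setdefault(b.target_chrom, set()).add(b.query_chrom)
        q2t.setdefault(b.query_chrom, set()).add(b.target_chrom)
    return (
        {k: sorted(v, key=_natural_key) for k, v in sorted(
            t2q.items(), key=lambda kv: _natural_key(kv[0]))},
        {k: sorted(v, key=_natural_key) for k, v in sorted(
            q2t.items(), key=lambda kv: _natural_key(kv[0]))},
    )


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        pos = [m.target_pos for m in b.members]
        rows.append((b.target_chrom, min(pos), max(pos), b.query_chrom,
                     b.orientation, b.n_markers))
    return pd.DataFrame(rows, columns=[
        "target_chrom", "start", "end", "query_chrom", "orientation",
        "n_markers",
    ])


def condense(markers: Sequence[Marker]) -> SegmentedGenomes:
    """Collapse maximal strips into signed segments.

    Markers are indexed 1..n by (target_chrom, target_pos); a strip is a
    run of markers adjacent in query order whose target indices step by
    exactly +1 (sign '+') or -1 (sign '-') on one target chromosome.
    Each strip becomes one segment; segments are renumbered 1..m in
    target order, so the target genome is the all-positive identity.
    Singleton strips are sign-ambiguous and flagged (provisional '+').
    """
    if not markers:
        raise ValueError("no markers to condense")
    t_sorted = sorted(
        markers, key=lambda m: (_natural_key(m.target_chrom), m.target_pos))
    t_index = {m.clone_id: i + 1 for i, m in enumerate(t_sorted)}
    t_chrom = {m.clone_id: m.target_chrom for m in markers}

    # strips along each query chromosome
    strips: List[List[Marker]] = []
    query_strips: List[List[int]] = []  # strip indices per query chromosome
    q_names = sorted(_by_query_chrom(markers), key=_natural_key)
    grouped = _by_query_chrom(markers)
    for qc in q_names:
        idxs: List[int] = []
        run: List[Marker] = [grouped[qc][0]]
        direction = 0
        for m in grouped[qc][1:]:
            prev = run[-1]
            step = t_index[m.clone_id] - t_index[prev.clone_id]
            same_chrom = t_chrom[m.clone_id] == t_chrom[prev.clone_id]
            if same_chrom and step in (1, -1) and direction in (0, step):
                run.append(m)
                direction = step
            else:
                idxs.append(len(strips))
                strips.append(run)
                run, direction = [m], 0
        idxs.append(len(strips))
        strips.append(run)
        query_strips.append(idxs)

    # number segments in target order (by the strip's minimum target index)
    order = sorted(range(len(strips)),
                   key=lambda si: min(t_index[m.clone_id] for m in strips[si]))
    seg_id = {si: k + 1 for k, si in enumerate(order)}
    seg_sign: Dict[int, int] = {}
    ambiguous: List[int] = []
    seg_markers: Dict[int, List[str]] = {}
    for si, run in enumerate(strips):
        sid = seg_id[si]
        seg_markers[sid] = [m.clone_id for m in run]
        if len(run) == 1:
            seg_sign[si] = 1
            ambiguous.append(sid)
        else:
            asc = t_index[run[1].clone_id] > t_index[run[0].clone_id]
            seg_sign[si] = 1 if asc else -1

    genome_query = SignedGenome([
        [seg_sign[si] * seg_id[si] for si in idxs] for idxs in query_strips
    ])
    # target genome: segments grouped by target chromosome, identity order
    t_chrom_names = []
    target_chroms: List[List[int]] = []
    for si in order:
        tc = strips[si][0].target_chrom
        if not t_chrom_names or t_chrom_names[-1] != tc:
            t_chrom_names.append(tc)
            target_chroms.append([])
        target_chroms[-1].append(seg_id[si])
    genome_target = SignedGenome(target_chroms)
    return SegmentedGenomes(
        genome_query=genome_query,
        genome_target=genome_target,
        ambiguous_segments=tuple(sorted(ambiguous)),
        segment_markers=seg_markers,
        query_chrom_names=tuple(q_names),
        target_chrom_names=tuple(t_chrom_names),
    )


# ---------------------------------------------------------------------------
# GRIMM genome text dialect
# ---------------------------------------------------------------------------

def write_grimm(genomes: Dict[str, SignedGenome], path) -> None:
    """Write genomes as '>name' headers followed by one '$'-terminated
    line of signed integers per chromosome."""
    with open(path, "w") as fh:
        for name, g in genomes.items():
            fh.write(f">{name}\n")
            for chrom in g.chromosomes:
                fh.write(" ".join(str(x) for x in chrom) + " $\n")


def read_grimm(path) -> Dict[str, SignedGenome]:
    """Parse the GRIMM text dialect; duplicate or missing segment ids in
    a genome raise a validation error listing them."""
    genomes: Dict[str, List[List[int]]] = {}
    name = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                if name in genomes:
                    raise ValueError(f"duplicate genome name {name!r}")
                genomes[name] = []
                continue
            if name is None:
                raise ValueError(f"line {lineno}: data before any '>' header")
            toks = line.split()
            if toks and toks[-1] == "$":
                toks = toks[:-1]
            try:
                chrom = [int(t) for t in toks]
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-integer segment id"
                ) from None
            if chrom:
                genomes[name].append(chrom)
    out = {}
    for gname, chroms in genomes.items():
        ids = sorted(abs(x) for c in chroms for x in c)
        n = len(ids)
        dups = sorted({i for i in ids if ids.count(i) > 1})
        missing = sorted(set(range(1, n + 1)) - set(ids))
        if dups or missing:
            raise ValueError(
                f"genome {gname!r}: duplicate ids {dups}, missing ids {missing}"
            )
        out[gname] = SignedGenome(chroms)
    return out
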