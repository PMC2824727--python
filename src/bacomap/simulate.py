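"""Synthetic data generator: ancestor/derived genome pairs with known
rearrangement history, BAC clone sampling, mate-pair alignment emission,
end-read FASTA, probe-screening tables and marker tables.

The derived genome is represented as oriented intervals ("blocks") of
the ancestor, so every emitted coordinate can be lifted back to the
ancestor exactly and every clone carries clean truth labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rearrange import SignedGenome

__all__ = [
    "SimConfig",
    "AncestralGenome",
    "RearrangementEvent",
    "EventLog",
    "DerivedGenome",
    "Clone",
    "make_ancestor",
    "apply_events",
    "sample_clones",
    "emit_alignments",
    "emit_bes_fasta",
    "simulate_screening",
    "emit_marker_table",
]

EVENT_KINDS = ("inversion", "translocation", "fusion", "fission")

# named child streams off the root seed; appending new emitters does not
# perturb existing ones
_STREAMS = ("ancestor", "events", "clones", "alignments", "fasta",
            "screening", "markers")


@dataclass
class SimConfig:
    n_chromosomes: int = 3
    chrom_lengths: Tuple[int, ...] = (240_000_000, 240_000_000, 240_000_000)
    n_markers: Optional[int] = None
    n_clones: int = 200
    insert_mean: int = 139_000
    insert_min: int = 100_000
    insert_max: int = 200_000
    insert_sd: int = 25_000
    read_len_mean: int = 728
    read_len_sd: int = 60
    gc: float = 0.418
    p_unmapped: float = 0.0
    p_multimap: float = 0.0
    marker_spacing: int = 30_000_000
    seed: int = 0

    def __post_init__(self):
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have n_chromosomes entries")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if not (0 < self.insert_min <= self.insert_mean <= self.insert_max):
            raise ValueError("need insert_min <= insert_mean <= insert_max, all > 0")
        if self.read_len_mean <= 0 or self.marker_spacing <= 0:
            raise ValueError("lengths must be > 0")
        for name in ("gc", "p_unmapped", "p_multimap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def stream(self, name: str) -> np.random.Generator:
        """Deterministic child generator for one emitter."""
        idx = _STREAMS.index(name)
        ss = np.random.SeedSequence(self.seed)
        return np.random.default_rng(ss.spawn(len(_STREAMS))[idx])


@dataclass
class AncestralGenome:
    """Marker grid standing in for the reference genome.

    ``chromosomes[i]`` is an ordered list of (marker_id, position) with
    strictly increasing positions; marker ids are unique genome-wide.
    """

    chromosomes: List[List[Tuple[str, int]]]
    chrom_lengths: Tuple[int, ...]

    def __post_init__(self):
        seen = set()
        for chrom, L in zip(self.chromosomes, self.chrom_lengths):
            prev = -1
            for mid, pos in chrom:
                if mid in seen:
                    raise ValueError(f"duplicate marker id {mid}")
                seen.add(mid)
                if not (prev < pos < L):
                    raise ValueError(f"marker {mid} position {pos} out of order/range")
                prev = pos

    @property
    def n_markers(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"


@dataclass(frozen=True)
class Block:
    """Oriented ancestor interval [start, end), strand +1/-1."""
    anc_chrom: int
    start: int
    end: int
    strand: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RearrangementEvent:
    kind: str
    chroms: Tuple[int, ...]        # chromosome indices at application time
    positions: Tuple[int, ...]     # derived-bp cut sites at application time
    orient: Tuple[int, ...] = ()   # orientation flags (fusion/translocation)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventLog:
    events: List[RearrangementEvent] = field(default_factory=list)
    clone_truth: Dict[str, tuple] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"events": [e.to_dict() for e in self.events],
             "clone_truth": self.clone_truth},
            indent=2, sort_keys=True,
        )


class DerivedGenome:
    """The rearranged genome: per chromosome, a list of ancestor blocks."""

    def __init__(self, ancestor: AncestralGenome,
                 chromosomes: Optional[List[List[Block]]] = None):
        self.ancestor = ancestor
        if chromosomes is None:
            chromosomes = [
                [Block(i, 0, L, 1)]
                for i, L in enumerate(ancestor.chrom_lengths)
            ]
        self.chromosomes = chromosomes

    def copy(self) -> "DerivedGenome":
        return DerivedGenome(self.ancestor, [list(c) for c in self.chromosomes])

    def chrom_length(self, i: int) -> int:
        return sum(b.length for b in self.chromosomes[i])

    def __eq__(self, other) -> bool:
        return (isinstance(other, DerivedGenome)
                and self.chromosomes == other.chromosomes)

    # -- coordinate lifting ------------------------------------------------

    def markers_on(self, i: int) -> List[Tuple[str, int, int]]:
        """Markers on derived chromosome i as (id, derived_pos, orient)."""
        out = []
        offset = 0
        for b in self.chromosomes[i]:
            anc = self.ancestor.chromosomes[b.anc_chrom]
            inside = [(m, p) for m, p in anc if b.start <= p < b.end]
            if b.strand == 1:
                out.extend((m, offset + (p - b.start), 1) for m, p in inside)
            else:
                out.extend(
                    (m, offset + (b.end - 1 - p), -1) for m, p in reversed(inside)
                )
            offset += b.length
        return out

    def junctions(self, i: int) -> List[int]:
        """Derived offsets of block junctions (novel adjacencies)."""
        offs = []
        acc = 0
        for b in self.chromosomes[i][:-1]:
            acc += b.length
            offs.append(acc)
        return offs

    def lift_to_ancestor(self, i: int, pos: int) -> Tuple[int, int, int]:
        """Map derived (chrom i, pos) -> (anc_chrom, anc_pos, strand)."""
        offset = 0
        for b in self.chromosomes[i]:
            if offset <= pos < offset + b.length:
                delta = pos - offset
                if b.strand == 1:
                    return b.anc_chrom, b.start + delta, 1
                return b.anc_chrom, b.end - 1 - delta, -1
            offset += b.length
        raise IndexError(f"position {pos} beyond chromosome {i}")

    def block_bounds(self, i: int, pos: int) -> Tuple[int, int]:
        """Derived [start, end) of the block containing pos."""
        offset = 0
        for b in self.chromosomes[i]:
            if offset <= pos < offset + b.length:
                return offset, offset + b.length
            offset += b.length
        raise IndexError(f"position {pos} beyond chromosome {i}")

    def to_signed_genome(self) -> Tuple[SignedGenome, SignedGenome, Dict[int, str]]:
        """(derived, ancestor-identity) signed marker permutations.

        Markers are numbered 1..n in ancestor order; the ancestor genome
        is then the all-positive identity grouped by ancestor chromosome.
        """
        number: Dict[str, int] = {}
        k = 0
        anc_chroms = []
        for chrom in self.ancestor.chromosomes:
            ids = []
            for mid, _ in chrom:
                k += 1
                number[mid] = k
                ids.append(k)
            if ids:
                anc_chroms.append(tuple(ids))
        der_chroms = []
        for i in range(len(self.chromosomes)):
            seq = [o * number[m] for m, _, o in self.markers_on(i)]
            if seq:
                der_chroms.append(tuple(seq))
        names = {v: k for k, v in number.items()}
        return (SignedGenome(der_chroms), SignedGenome(anc_chroms), names)


@dataclass
class Clone:
    clone_id: str
    chrom: int          # derived chromosome index
    start: int          # derived bp, 0-based half-open
    end: int
    spans_breakpoint: bool

    @property
    def insert_length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def make_ancestor(config: SimConfig) -> AncestralGenome:
    """Place markers on a regular grid of ``marker_spacing`` with jitter."""
    rng = config.stream("ancestor")
    if config.n_markers is None:
        counts = [L // config.marker_spacing for L in config.chrom_lengths]
    else:
        total = int(config.n_markers)
        if total == 0:
            return AncestralGenome([[] for _ in config.chrom_lengths],
                                   config.chrom_lengths)
        if total > sum(config.chrom_lengths):
            raise ValueError(
                f"cannot place {total} markers in "
                f"{sum(config.chrom_lengths)} bp of genome"
            )
        glen = sum(config.chrom_lengths)
        raw = [total * L / glen for L in config.chrom_lengths]
        counts = [int(x) for x in raw]
        # largest-remainder top-up
        order = np.argsort([c - r for c, r in zip(counts, raw)])
        for idx in order:
            if sum(counts) == total:
                break
            counts[idx] += 1
        if any(c > L for c, L in zip(counts, config.chrom_lengths)):
            raise ValueError("marker count incompatible with chromosome lengths")
    chroms = []
    mid = 0
    for ci, (m, L) in enumerate(zip(counts, config.chrom_lengths)):
        row = []
        if m > 0:
            step = L / m
            jitter = rng.uniform(-0.2, 0.2, size=m) * step
            pos = np.clip(((np.arange(m) + 0.5) * step + jitter).astype(np.int64),
                          0, L - 1)
            pos = np.sort(pos)
            # enforce strict increase after clipping
            for k in range(1, m):
                if pos[k] <= pos[k - 1]:
                    pos[k] = pos[k - 1] + 1
            if pos[-1] >= L:
                raise ValueError("marker count incompatible with chromosome lengths")
            for p in pos:
                mid += 1
                row.append((f"M{mid:05d}", int(p)))
        chroms.append(row)
    return AncestralGenome(chroms, config.chrom_lengths)


# ---------------------------------------------------------------------------
# Rearrangement events on the derived genome
# ---------------------------------------------------------------------------

def _cut(blocks: List[Block], x: int) -> Tuple[List[Block], List[Block]]:
    """Split a block list at derived offset x."""
    left: List[Block] = []
    right: List[Block] = []
    acc = 0
    for b in blocks:
        if acc + b.length <= x:
            left.append(b)
        elif acc >= x:
            right.append(b)
        else:
            d = x - acc
            if b.strand == 1:
                left.append(Block(b.anc_chrom, b.start, b.start + d, 1))
                right.append(Block(b.anc_chrom, b.start + d, b.end, 1))
            else:
                left.append(Block(b.anc_chrom, b.end - d, b.end, -1))
                right.append(Block(b.anc_chrom, b.start, b.end - d, -1))
        acc += b.length
    return left, right


def _flip_blocks(blocks: List[Block]) -> List[Block]:
    return [Block(b.anc_chrom, b.start, b.end, -b.strand)
            for b in reversed(blocks)]


def _merge(blocks: List[Block]) -> List[Block]:
    """Merge ancestor-contiguous equally-oriented neighbours so block
    junctions correspond to genuine breakpoints."""
    out: List[Block] = []
    for b in blocks:
        if out:
            p = out[-1]
            if p.anc_chrom == b.anc_chrom and p.strand == b.strand:
                if p.strand == 1 and p.end == b.start:
                    out[-1] = Block(p.anc_chrom, p.start, b.end, 1)
                    continue
                if p.strand == -1 and p.start == b.end:
                    out[-1] = Block(p.anc_chrom, b.start, p.end, -1)
                    continue
        out.append(b)
    return out


def _apply_one(genome: DerivedGenome, ev: RearrangementEvent) -> DerivedGenome:
    g = genome.copy()
    cs = g.chromosomes
    if ev.kind == "inversion":
        (ci,) = ev.chroms
        b1, b2 = sorted(ev.positions)
        left, rest = _cut(cs[ci], b1)
        mid, right = _cut(rest, b2 - b1)
        cs[ci] = _merge(left + _flip_blocks(mid) + right)
    elif ev.kind == "translocation":
        ci, cj = ev.chroms
        x, y = ev.positions
        (mode,) = ev.orient
        xi, xr = _cut(cs[ci], x)
        yi, yr = _cut(cs[cj], y)
        if mode == 0:  # prefix-prefix exchange
            cs[ci] = _merge(xi + yr)
            cs[cj] = _merge(yi + xr)
        else:          # prefix exchanged with flipped prefix
            cs[ci] = _merge(xi + _flip_blocks(yi))
            cs[cj] = _merge(_flip_blocks(xr) + yr)
    elif ev.kind == "fusion":
        ci, cj = ev.chroms
        fi, fj = ev.orient
        x = _flip_blocks(cs[ci]) if fi else cs[ci]
        y = _flip_blocks(cs[cj]) if fj else cs[cj]
        merged = _merge(x + y)
        keep = [c for k, c in enumerate(cs) if k not in (ci, cj)]
        keep.insert(min(ci, cj), merged)
        g.chromosomes = keep
    elif ev.kind == "fission":
        (ci,) = ev.chroms
        (x,) = ev.positions
        left, right = _cut(cs[ci], x)
        cs[ci:ci + 1] = [left, right]
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    return g


def _legal_cut_sites(genome: DerivedGenome, i: int,
                     include_ends: bool) -> List[int]:
    """Breakpoints fall between markers: midpoints of inter-marker gaps
    (optionally plus chromosome ends)."""
    marks = genome.markers_on(i)
    mids = [(marks[k][1] + marks[k + 1][1]) // 2 for k in range(len(marks) - 1)]
    # midpoint could coincide with a marker position only for adjacent bp
    if include_ends:
        return [0] + mids + [genome.chrom_length(i)]
    return mids


def _sample_event(genome: DerivedGenome, rng: np.random.Generator,
                  kind: str) -> Optional[RearrangementEvent]:
    nch = len(genome.chromosomes)
    if kind == "inversion":
        cands = [i for i in range(nch) if len(genome.markers_on(i)) >= 1]
        rng.shuffle(cands)
        for ci in cands:
            sites = _legal_cut_sites(genome, ci, include_ends=True)
            L = genome.chrom_length(ci)
            pairs = []
            marks = [p for _, p, _ in genome.markers_on(ci)]
            for a in range(len(sites)):
                for b in range(a + 1, len(sites)):
                    if sites[a] == 0 and sites[b] == L:
                        continue  # whole-chromosome flip is a no-op
                    if any(sites[a] < p < sites[b] for p in marks):
                        pairs.append((sites[a], sites[b]))
            if pairs:
                b1, b2 = pairs[rng.integers(len(pairs))]
                return RearrangementEvent("inversion", (ci,), (b1, b2))
        return None
    if kind == "fission":
        cands = [i for i in range(nch) if len(genome.markers_on(i)) >= 2]
        if not cands:
            return None
        ci = int(rng.choice(cands))
        sites = _legal_cut_sites(genome, ci, include_ends=False)
        x = int(sites[rng.integers(len(sites))])
        return RearrangementEvent("fission", (ci,), (x,))
    if kind == "fusion":
        if nch < 2:
            return None
        ci, cj = sorted(rng.choice(nch, size=2, replace=False).tolist())
        fi, fj = int(rng.integers(2)), int(rng.integers(2))
        return RearrangementEvent("fusion", (ci, cj), (), (fi, fj))
    if kind == "translocation":
        cands = [i for i in range(nch) if len(genome.markers_on(i)) >= 2]
        if len(cands) < 2:
            return None
        ci, cj = sorted(rng.choice(len(cands), size=2, replace=False).tolist())
        ci, cj = cands[ci], cands[cj]
        si = _legal_cut_sites(genome, ci, include_ends=False)
        sj = _legal_cut_sites(genome, cj, include_ends=False)
        x = int(si[rng.integers(len(si))])
        y = int(sj[rng.integers(len(sj))])
        mode = int(rng.integers(2))
        return RearrangementEvent("translocation", (ci, cj), (x, y), (mode,))
    raise ValueError(kind)


def apply_events(
    ancestor: AncestralGenome,
    k: Optional[int] = None,
    events: Optional[Sequence[RearrangementEvent]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    kind_weights: Optional[Dict[str, float]] = None,
    retry_cap: int = 100,
) -> Tuple[DerivedGenome, EventLog]:
    """Apply ``k`` random events (or replay an explicit event list).

    Random events draw the kind from ``kind_weights`` (default uniform)
    and breakpoints uniformly over legal inter-marker sites; illegal
    draws are resampled up to ``retry_cap`` times.
    """
    genome = DerivedGenome(ancestor)
    log = EventLog()
    if events is not None:
        for ev in events:
            genome = _apply_one(genome, ev)
            log.events.append(ev)
        return genome, log
    if k is None:
        raise ValueError("provide either k or events")
    if k < 0:
        raise ValueError("k must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    kinds = list(EVENT_KINDS)
    if kind_weights is None:
        weights = np.ones(len(kinds))
    else:
        weights = np.array([kind_weights.get(kd, 0.0) for kd in kinds], float)
        if weights.sum() <= 0:
            raise ValueError("kind_weights sums to zero")
    weights = weights / weights.sum()
    for _ in range(int(k)):
        ev = None
        for _try in range(retry_cap):
            kind = kinds[int(rng.choice(len(kinds), p=weights))]
            ev = _sample_event(genome, rng, kind)
            if ev is not None:
                break
        if ev is None:
            raise RuntimeError(
                f"no legal event found after {retry_cap} retries"
            )
        genome = _apply_one(genome, ev)
        log.events.append(ev)
    return genome, log


# ---------------------------------------------------------------------------
# Clone sampling
# ---------------------------------------------------------------------------

def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter so the truncated normal has the given mean."""
    if hi == lo:
        return lo

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return optimize.brentq(trunc_mean, lo - 10 * sd, hi + 10 * sd)


def sample_clones(genome: DerivedGenome, config: SimConfig,
                  rng: Optional[np.random.Generator] = None,
                  log: Optional[EventLog] = None) -> List[Clone]:
    """Draw clones with truncated-normal insert sizes and uniform starts;
    record per-clone truth including breakpoint straddling."""
    if rng is None:
        rng = config.stream("clones")
    nch = len(genome.chromosomes)
    lengths = np.array([genome.chrom_length(i) for i in range(nch)], float)
    if lengths.min() < config.insert_max:
        raise ValueError("every chromosome must be at least insert_max long")
    if config.insert_min == config.insert_max:
        inserts = np.full(config.n_clones, config.insert_min, dtype=np.int64)
    else:
        loc = _truncnorm_loc(config.insert_mean, config.insert_sd,
                             config.insert_min, config.insert_max)
        a = (config.insert_min - loc) / config.insert_sd
        b = (config.insert_max - loc) / config.insert_sd
        inserts = stats.truncnorm.rvs(
            a, b, loc=loc, scale=config.insert_sd,
            size=config.n_clones, random_state=rng,
        ).astype(np.int64)
    probs = lengths / lengths.sum()
    chroms = rng.choice(nch, size=config.n_clones, p=probs)
    clones = []
    junctions = {i: genome.junctions(i) for i in range(nch)}
    for k in range(config.n_clones):
        ci = int(chroms[k])
        ins = int(inserts[k])
        start = int(rng.integers(0, genome.chrom_length(ci) - ins + 1))
        end = start + ins
        spans = any(start < j < end for j in junctions[ci])
        cid = f"C{k + 1:06d}"
        clones.append(Clone(cid, ci, start, end, spans))
        if log is not None:
            log.clone_truth[cid] = (ci, start, end, spans)
    return clones


# ---------------------------------------------------------------------------
# Emitters
# ---------------------------------------------------------------------------

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def _read_alignment(genome: DerivedGenome, clone: Clone, end_label: str,
                    read_len: int) -> Tuple[int, int, int, int]:
    """Ancestor placement of one clone end read (clipped to its block).

    Returns (anc_chrom, anc_start, anc_end, anc_strand), 0-based
    half-open on the ancestor.
    """
    if end_label == "T7":
        s = clone.start
        e = min(clone.start + read_len, clone.end)
        orient = 1
    else:
        s = max(clone.end - read_len, clone.start)
        e = clone.end
        orient = -1
    mid = (s + e) // 2
    bs, be = genome.block_bounds(clone.chrom, mid)
    s, e = max(s, bs), min(e, be)
    c1, p1, strand = genome.lift_to_ancestor(clone.chrom, s)
    _, p2, _ = genome.lift_to_ancestor(clone.chrom, e - 1)
    lo, hi = min(p1, p2), max(p1, p2) + 1
    return c1, lo, hi, strand * orient


def emit_alignments(
    clones: Sequence[Clone],
    genome: DerivedGenome,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """BLAST-tabular mate-pair alignments on the ancestor plus a truth
    table.  Ends drop out with p_unmapped and gain an equal-score decoy
    locus with p_multimap."""
    if rng is None:
        rng = config.stream("alignments")
    anc = genome.ancestor
    rows = []
    truth = []
    read_len = int(config.read_len_mean)
    for clone in clones:
        for end_label in ("T7", "SP6"):
            qid = f"{clone.clone_id}_{end_label}"
            unmapped = rng.random() < config.p_unmapped
            c, lo, hi, strand = _read_alignment(genome, clone, end_label, read_len)
            truth.append({
                "read_id": qid, "clone_id": clone.clone_id, "end": end_label,
                "true_chrom": anc.chrom_name(c), "true_start": lo,
                "true_end": hi, "true_strand": "+" if strand == 1 else "-",
                "emitted": not unmapped,
                "spans_breakpoint": clone.spans_breakpoint,
            })
            if unmapped:
                continue
            alen = hi - lo
            if strand == 1:
                sstart, send = lo + 1, hi
            else:
                sstart, send = hi, lo + 1
            bitscore = float(2 * alen)
            rows.append((qid, anc.chrom_name(c), 98.5, alen, 2, 0,
                         1, alen, sstart, send, 1e-80, bitscore))
            if rng.random() < config.p_multimap:
                dc = int(rng.integers(len(anc.chrom_lengths)))
                dl = anc.chrom_lengths[dc]
                dpos = int(rng.integers(0, max(dl - alen, 1)))
                dstrand = int(rng.integers(2))
                if dstrand:
                    ds, de = dpos + 1, dpos + alen
                else:
                    ds, de = dpos + alen, dpos + 1
                rows.append((qid, anc.chrom_name(dc), 98.5, alen, 2, 0,
                             1, alen, ds, de, 1e-80, bitscore))
    aln = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    return aln, pd.DataFrame(truth)


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.6g")


def emit_bes_fasta(clones: Sequence[Clone], config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   width: int = 60) -> str:
    """Two reads per clone ({clone}_T7 / {clone}_SP6), i.i.d. bases with
    the configured GC fraction, lengths ~ N(read_len_mean, read_len_sd)."""
    if rng is None:
        rng = config.stream("fasta")
    gc = config.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    out = []
    for clone in clones:
        for end_label in ("T7", "SP6"):
            n = max(int(round(rng.normal(config.read_len_mean,
                                         config.read_len_sd))), 50)
            seq = "".join(alphabet[rng.choice(4, size=n, p=p)])
            out.append(f">{clone.clone_id}_{end_label}")
            out.extend(seq[i:i + width] for i in range(0, n, width))
    return "\n".join(out) + "\n"


def simulate_screening(n_probes: int, depth: float,
                       rng: Optional[np.random.Generator] = None,
                       seed: Optional[int] = None) -> pd.DataFrame:
    """Probe-screening hit table: per probe, Poisson(depth) clone hits.

    Returns long format (probe_id, clone_id) so downstream exclusion of
    individual clones is possible.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if n_probes <= 0:
        raise ValueError("need at least one probe")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.poisson(depth, size=n_probes)
    rows = []
    k = 0
    for i, c in enumerate(counts):
        pid = f"P{i + 1:03d}"
        if c == 0:
            rows.append((pid, ""))  # probe present, zero hits
        for _ in range(int(c)):
            k += 1
            rows.append((pid, f"SC{k:06d}"))
    return pd.DataFrame(rows, columns=["probe_id", "clone_id"])


def emit_marker_table(genome: DerivedGenome, config: SimConfig,
                      rng: Optional[np.random.Generator] = None,
                      tie_fraction: float = 0.0) -> pd.DataFrame:
    """Cytogenetic-style marker table: query chromosome + integer rank
    (orientation-free) vs target chromosome + bp position.

    Markers are subsampled to ~1 per marker_spacing along each derived
    chromosome; at least one marker per non-empty chromosome survives.
    Optional rank ties emulate unresolved FISH pairs.
    """
    if rng is None:
        rng = config.stream("markers")
    anc = genome.ancestor
    anc_pos = {m: (ci, p) for ci, chrom in enumerate(anc.chromosomes)
               for m, p in chrom}
    rows = []
    for i in range(len(genome.chromosomes)):
        marks = genome.markers_on(i)
        kept = []
        last = None
        # half-spacing minimum gap: tolerates grid jitter while still
        # thinning marker sets denser than the configured spacing
        min_gap = config.marker_spacing // 2
        for m, pos, _ in marks:
            if last is None or pos - last >= min_gap:
                kept.append((m, pos))
                last = pos
        ranks = list(range(1, len(kept) + 1))
        if tie_fraction > 0:
            for k in range(len(ranks) - 1):
                if ranks[k + 1] == ranks[k] + 1 and rng.random() < tie_fraction:
                    ranks[k + 1] = ranks[k]
        for (m, _pos), r in zip(kept, ranks):
            tc, tp = anc_pos[m]
            rows.append((m, f"q{i + 1}", r, anc.chrom_name(tc), tp))
    return pd.DataFrame(
        rows, columns=["clone_id", "query_chrom", "query_rank",
                       "target_chrom", "target_pos"],
    )
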