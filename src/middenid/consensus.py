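"""Replicate-PCR consensus calling for degraded (ancient) DNA.

Each target fragment is amplified in several independent PCR replicates,
sequenced in forward or reverse direction.  Reverse reads are
reverse-complemented, all reads are merged into a site-by-replicate
matrix by progressive pairwise alignment against the longest read, and
each column is resolved by majority vote among the replicates that
cover it.  This mirrors the multi-observer chromatogram review used in
practice: replicates (and reviewers) collapse into one voting pool.

Column conventions: ``N`` cells carry no information (unread base or no
coverage) and are excluded from both the vote and the coverage count;
``-`` cells are interior absences and vote for a deletion.  Exact
base-versus-gap ties adjacent to a run of the tied base are resolved to
the gap — polymerase slippage inflates homopolymer runs more often than
it deflates them — while other gap ties yield N and base-versus-base
ties yield the IUPAC ambiguity code of the tied bases.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .config import PipelineConfig
from .seq import iupac_code, reverse_complement


class Direction(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


@dataclass(frozen=True)
class ReplicateRead:
    """One PCR replicate's read, stored exactly as read off the machine."""

    fragment_id: str
    replicate_id: str
    direction: Direction
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(
                f"replicate {self.replicate_id}: empty read"
            )


@dataclass
class ReplicateMatrix:
    """Aligned site-by-replicate matrix for one fragment."""

    fragment_id: str
    replicate_ids: list[str]
    rows: list[str]              # aligned strings over {A,C,G,T,N,-}
    n_forward: int
    n_reverse: int
    dropped: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class ConsensusSequence:
    fragment_id: str
    bases: str                   # gap-free consensus over {A,C,G,T,N,IUPAC}
    calls: str                   # per-column call including '-' (alignment length)
    support: list[float]         # per-column agreeing/covering fraction
    n_forward: int
    n_reverse: int


def trim_read(read: ReplicateRead) -> ReplicateRead:
    """Keep the longest contiguous N-free run (leftmost on ties)."""
    runs = [r for r in read.bases.split("N") if r]
    if not runs:
        raise ValueError(f"replicate {read.replicate_id}: read is entirely N")
    best = max(runs, key=len)
    return ReplicateRead(read.fragment_id, read.replicate_id, read.direction, best)


def merge_replicates(
    reads: list[ReplicateRead], cfg: PipelineConfig | None = None
) -> ReplicateMatrix:
    """Orient, anchor and progressively align replicates of one fragment.

    The longest read (ties: lexicographically smallest replicate_id) is
    the alignment anchor; every other read is Needleman-Wunsch-aligned
    to it and merged column-wise, reads being processed in replicate_id
    order so the result is independent of input order.  Reads that do
    not align to the anchor with positive score are dropped with a
    warning (possible contaminant).
    """
    from .compare import pairwise_align, star_align

    cfg = cfg or PipelineConfig()
    if not reads:
        raise ValueError("merge_replicates requires at least one read")
    frag_ids = {r.fragment_id for r in reads}
    if len(frag_ids) > 1:
        raise ValueError(f"mixed fragment ids: {sorted(frag_ids)}")
    ids = [r.replicate_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate replicate ids")

    oriented = []
    for r in sorted(reads, key=lambda r: r.replicate_id):
        seq = (
            reverse_complement(r.bases)
            if r.direction is Direction.REVERSE
            else r.bases
        )
        oriented.append((r.replicate_id, seq))

    scores = (cfg.match_score, cfg.mismatch_score, cfg.gap_score)
    anchor_id = min(oriented, key=lambda r: (-len(r[1]), r[0]))[0]
    anchor_seq = dict(oriented)[anchor_id]

    kept, dropped = [], []
    for rid, seq in oriented:
        if rid == anchor_id:
            kept.append((rid, seq))
            continue
        _, _, score = pairwise_align(anchor_seq, seq, *scores)
        if score <= 0:
            warnings.warn(
                f"replicate {rid} does not align to the anchor "
                f"(score {score}); dropped as a possible contaminant",
                stacklevel=2,
            )
            dropped.append(rid)
        else:
            kept.append((rid, seq))

    aligned = star_align(kept, scores=scores, anchor_ends_as_unknown=True)
    dirs = {r.replicate_id: r.direction for r in reads}
    kept_ids = [rid for rid, _ in aligned]
    return ReplicateMatrix(
        fragment_id=reads[0].fragment_id,
        replicate_ids=kept_ids,
        rows=[row for _, row in aligned],
        n_forward=sum(1 for rid in kept_ids if dirs[rid] is Direction.FORWARD),
        n_reverse=sum(1 for rid in kept_ids if dirs[rid] is Direction.REVERSE),
        dropped=dropped,
    )


def call_consensus(
    matrix: ReplicateMatrix, cfg: PipelineConfig | None = None
) -> ConsensusSequence:
    """Majority-resolve each alignment column into a consensus call.

    Per column, among non-N cells: a unique plurality symbol is called
    (a strict majority in the common case); exact ties between bases
    yield the IUPAC ambiguity code, ties involving a gap yield the gap
    when a neighboring column calls the tied base (homopolymer
    shortening) and N otherwise.  Columns covered by fewer than
    ``min_coverage`` replicates are called N.  Leading and trailing
    columns where no replicate has data are removed.
    """
    cfg = cfg or PipelineConfig()
    if not matrix.rows:
        raise ValueError("empty replicate matrix")
    nsites = matrix.n_sites
    columns = [[row[k] for row in matrix.rows] for k in range(nsites)]
    if all(all(c == "N" for c in col) for col in columns):
        raise ValueError("all-N replicate matrix: nothing to call")

    # first pass: per-column vote; ties deferred
    calls: list[str] = []
    support: list[float] = []
    ties: list[tuple[int, set[str], int, int]] = []  # (col, tied symbols, top, cov)
    for k, col in enumerate(columns):
        votes = Counter(c for c in col if c != "N")
        cov = sum(votes.values())
        if cov < cfg.min_coverage:
            calls.append("N")
            support.append(0.0)
            continue
        top = max(votes.values())
        winners = {s for s, v in votes.items() if v == top}
        if len(winners) == 1:
            calls.append(next(iter(winners)))
            support.append(top / cov)
        else:
            ties.append((k, winners, top, cov))
            calls.append("?")  # placeholder resolved below
            support.append(top / cov)

    # second pass: resolve ties with neighbor context available
    for k, winners, top, cov in ties:
        if "-" in winners:
            bases = winners - {"-"}
            neighbors = {calls[k - 1] if k > 0 else None,
                         calls[k + 1] if k + 1 < nsites else None}
            if len(bases) == 1 and bases & neighbors:
                calls[k] = "-"  # homopolymer-length conflict: shorter run
            else:
                calls[k] = "N"
                support[k] = 0.0
        else:
            calls[k] = iupac_code(frozenset(winners))

    # trim leading/trailing columns with no data at all
    has_data = [any(c != "N" for c in col) for col in columns]
    first = next((i for i, h in enumerate(has_data) if h), 0)
    last = next((i for i in range(nsites - 1, -1, -1) if has_data[i]), nsites - 1)
    calls = calls[first:last + 1]
    support = support[first:last + 1]

    return ConsensusSequence(
        fragment_id=matrix.fragment_id,
        bases="".join(c for c in calls if c != "-"),
        calls="".join(calls),
        support=support,
        n_forward=matrix.n_forward,
        n_reverse=matrix.n_reverse,
    )


def consensus_from_reads(
    reads: list[ReplicateRead], cfg: PipelineConfig | None = None
) -> ConsensusSequence:
    """Convenience: merge replicates and call the consensus in one step."""
    return call_consensus(merge_replicates(reads, cfg), cfg)
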