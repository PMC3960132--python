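"""Pairwise alignment and haplotype difference counting.

The ancient consensus fragments are short (~46-120 bp after primer
trimming), so comparison against reference haplotypes uses plain global
Needleman-Wunsch alignment with unit scores and a deterministic
traceback, followed by column-wise difference counting with explicit
rules for gaps, N and IUPAC ambiguity codes:

* both symbols determinate and different        -> substitution
* exactly one symbol is a gap                   -> one difference per column
* either symbol is N                            -> skipped (unknown base)
* overlapping ambiguity sets (e.g. R vs A)      -> compared, no difference
* disjoint ambiguity sets involving a code      -> skipped

Exact-match search restricts each comparison to the aligned extent of
the query, so a short ancient fragment can match a longer published
haplotype that is identical over the sequenced span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import base_set


@dataclass(frozen=True)
class ReferenceHaplotype:
    """A labeled, gapless published sequence."""

    accession: str
    taxon: str = ""
    bases: str = ""
    subspecies: str | None = None


@dataclass
class DifferenceReport:
    query_id: str
    ref_id: str
    aligned_length: int
    compared_sites: int
    substitutions: int
    gap_columns: int
    skipped_sites: int
    scores: tuple[float, float, float] = (1.0, -1.0, -2.0)

    @property
    def total_differences(self) -> int:
        return self.substitutions + self.gap_columns


def pairwise_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, str, float]:
    """Global Needleman-Wunsch alignment with a linear gap penalty.

    Symbols whose IUPAC base sets overlap score as a match (so N matches
    everything).  Traceback ties are broken deterministically preferring
    diagonal, then up (gap in ``b``), then left (gap in ``a``).

    Returns (aligned_a, aligned_b, score); the aligned strings have
    equal length.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires two non-empty sequences")
    n, m = len(a), len(b)
    a_sets = [base_set(c) for c in a]
    b_sets = [base_set(c) for c in b]

    # score matrix, then traceback with fixed move preference
    prev = [gap * j for j in range(m + 1)]
    rows = [prev]
    for i in range(1, n + 1):
        cur = [gap * i] + [0.0] * m
        sa = a_sets[i - 1]
        p = prev
        for j in range(1, m + 1):
            s = match if not sa.isdisjoint(b_sets[j - 1]) else mismatch
            cur[j] = max(p[j - 1] + s, p[j] + gap, cur[j - 1] + gap)
        rows.append(cur)
        prev = cur

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = rows[i][j]
        if i > 0 and j > 0:
            s = match if not a_sets[i - 1].isdisjoint(b_sets[j - 1]) else mismatch
            if here == rows[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and here == rows[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), rows[n][m]


def count_differences(
    aligned_a: str,
    aligned_b: str,
    query_id: str = "query",
    ref_id: str = "ref",
    scores: tuple[float, float, float] = (1.0, -1.0, -2.0),
) -> DifferenceReport:
    """Column-wise difference report for an aligned pair (see module doc)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = subs = gaps = skipped = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            skipped += 1
        elif ca == "-" or cb == "-":
            gaps += 1
        elif ca == "N" or cb == "N":
            skipped += 1
        else:
            sa, sb = base_set(ca), base_set(cb)
            if not sa.isdisjoint(sb):
                compared += 1
            elif len(sa) == 1 and len(sb) == 1:
                compared += 1
                subs += 1
            else:
                # disjoint sets but at least one ambiguity code: unresolvable
                skipped += 1
    return DifferenceReport(
        query_id=query_id,
        ref_id=ref_id,
        aligned_length=len(aligned_a),
        compared_sites=compared,
        substitutions=subs,
        gap_columns=gaps,
        skipped_sites=skipped,
        scores=scores,
    )


def _align_and_count(
    query: str,
    query_id: str,
    ref: ReferenceHaplotype,
    scores: tuple[float, float, float],
    restrict_to_query: bool,
) -> DifferenceReport:
    qa, ra, _ = pairwise_align(query, ref.bases, *scores)
    if restrict_to_query:
        idx = [i for i, c in enumerate(qa) if c != "-"]
        lo, hi = idx[0], idx[-1] + 1
        qa, ra = qa[lo:hi], ra[lo:hi]
    return count_differences(qa, ra, query_id, ref.accession, scores)


def difference_matrix(
    query: str,
    panel: list[ReferenceHaplotype],
    query_id: str = "query",
    scores: tuple[float, float, float] = (1.0, -1.0, -2.0),
) -> list[DifferenceReport]:
    """One difference report per panel member, in stable panel order."""
    if not panel:
        raise ValueError("difference_matrix requires a non-empty panel")
    return [
        _align_and_count(query, query_id, ref, scores, restrict_to_query=False)
        for ref in panel
    ]


def match_exact(
    query: str,
    panel: list[ReferenceHaplotype],
    scores: tuple[float, float, float] = (1.0, -1.0, -2.0),
) -> list[str]:
    """Accessions with zero differences over the query's aligned span.

    The comparison window is the aligned extent of the query, so
    references identical over the sequenced fragment match even when
    they differ outside it.
    """
    if not panel:
        raise ValueError("match_exact requires a non-empty panel")
    hits = []
    for ref in panel:
        rep = _align_and_count(query, "query", ref, scores, restrict_to_query=True)
        if rep.total_differences == 0:
            hits.append(ref.accession)
    return hits


def star_align(records: list[tuple[str, str]],
               scores: tuple[float, float, float] = (1.0, -1.0, -2.0),
               anchor_ends_as_unknown: bool = True) -> list[tuple[str, str]]:
    """Progressive star multiple alignment against the longest sequence.

    Every sequence is pairwise-aligned to the anchor (longest; ties by
    label); anchor-relative insertions open new columns for all rows.
    When ``anchor_ends_as_unknown`` is set, the unaligned leading and
    trailing overhang of each shorter sequence is encoded N (no data)
    rather than as gap characters, which matters when the alignment is
    scored with gaps as a real character state.

    Returns (label, aligned sequence) rows in the input order.
    """
    if not records:
        raise ValueError("star_align requires at least one sequence")
    labels = [r[0] for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in star_align input")
    anchor_label = min(records, key=lambda r: (-len(r[1]), r[0]))[0]
    anchor_seq = dict(records)[anchor_label]

    # master alignment: list of columns, each a dict row-label -> symbol
    cols: list[dict[str, str]] = [{anchor_label: c} for c in anchor_seq]
    colmap = list(range(len(anchor_seq)))  # anchor position -> column index
    span: dict[str, tuple[int, int]] = {anchor_label: (0, len(anchor_seq) - 1)}

    for label, seq in records:
        if label == anchor_label:
            continue
        a_aln, r_aln, _ = pairwise_align(anchor_seq, seq, *scores)
        i_anchor = 0
        last_col = -1
        placed: list[int] = []
        for ca, cr in zip(a_aln, r_aln):
            if ca != "-":
                col = colmap[i_anchor]
                if cr != "-":
                    cols[col][label] = cr
                    placed.append(col)
                else:
                    cols[col][label] = "-"
                last_col = col
                i_anchor += 1
            else:  # insertion relative to the anchor: open a new column
                k = last_col + 1
                cols.insert(k, {label: cr})
                colmap = [c + 1 if c >= k else c for c in colmap]
                placed = [c + 1 if c >= k else c for c in placed]
                span = {
                    lab: (lo + 1 if lo >= k else lo, hi + 1 if hi >= k else hi)
                    for lab, (lo, hi) in span.items()
                }
                placed.append(k)
                last_col = k
        if not placed:
            span[label] = (0, -1)
        else:
            span[label] = (min(placed), max(placed))

    out = []
    for label, _seq in records:
        lo, hi = span[label]
        row = []
        for k, col in enumerate(cols):
            if lo <= k <= hi:
                row.append(col.get(label, "-"))
            else:
                row.append("N" if anchor_ends_as_unknown else "-")
        out.append((label, "".join(row)))
    return out
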