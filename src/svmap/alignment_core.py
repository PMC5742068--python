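"""Whole-genome pairwise alignment primitives.

The pipeline mirrors the classic anchor-based design: maximal exact
matches (MEMs) between two assemblies are chained into collinear
clusters, clusters are filled to base-level alignments with an
affine-gap DP, and the resulting alignments are reduced to one-to-one
synteny blocks by weighted conflict resolution.

Internal coordinates are 0-based half-open. Reverse-strand query
coordinates are kept both on the given (reverse-complemented) strand,
for chaining arithmetic, and as forward-strand intervals for reporting.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._seq import INVALID, encode, kmer_codes, revcomp
from .io import SequenceRecord

# affine scoring used by fill_cluster_alignment (a gap of length g costs
# GAP_OPEN + GAP_EXT * g)
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -2.0
GAP_EXT = -0.5


@dataclass(frozen=True, order=True)
class Match:
    """A maximal exact match; qry_start is on the given strand."""

    ref_name: str
    ref_start: int
    qry_name: str
    qry_start: int
    length: int
    strand: str = "+"

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length

    def qry_fwd_interval(self, qry_len: int) -> tuple[int, int]:
        """Interval on the forward query strand."""
        if self.strand == "+":
            return self.qry_start, self.qry_end
        return qry_len - self.qry_end, qry_len - self.qry_start


def _as_records(obj) -> list[SequenceRecord]:
    if isinstance(obj, SequenceRecord):
        return [obj]
    return list(obj)


class _KmerIndex:
    """Sorted index of packed k-mer start positions for one sequence."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        vals, valid = kmer_codes(codes, k)
        pos = np.nonzero(valid)[0]
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.pos = pos[order].astype(np.int64)

    def lookup_many(self, qvals: np.ndarray, qpos: np.ndarray):
        """All (ref_pos, qry_pos) pairs sharing a k-mer value."""
        lo = np.searchsorted(self.vals, qvals, side="left")
        hi = np.searchsorted(self.vals, qvals, side="right")
        counts = hi - lo
        keep = counts > 0
        lo, counts, qpos = lo[keep], counts[keep], qpos[keep]
        if len(lo) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        idx = np.repeat(lo, counts) + _ragged_arange(counts)
        return self.pos[idx], np.repeat(qpos, counts)

    def positions_for(self, val: int) -> np.ndarray:
        lo = np.searchsorted(self.vals, val, side="left")
        hi = np.searchsorted(self.vals, val, side="right")
        return self.pos[lo:hi]


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = -counts[:-1] + 1
    return np.cumsum(out)


def _maximal_runs(rpos: np.ndarray, qpos: np.ndarray, k: int):
    """Merge seed hits into maximal exact matches (>= k bp).

    A maximal match of length L >= k appears as exactly the run of its
    L - k + 1 consecutive seed start positions on one diagonal, so runs
    of consecutive hits are in one-to-one correspondence with MEMs.
    """
    if len(rpos) == 0:
        return []
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    rpos, qpos, diag = rpos[order], qpos[order], diag[order]
    brk = np.nonzero((np.diff(diag) != 0) | (np.diff(qpos) != 1))[0] + 1
    starts = np.concatenate(([0], brk))
    ends = np.concatenate((brk, [len(qpos)]))
    return [
        (int(rpos[s]), int(qpos[s]), int(qpos[e - 1] - qpos[s]) + k)
        for s, e in zip(starts, ends)
    ]


def _is_unique_in_ref(ref_seq: str, index: _KmerIndex, r0: int, length: int) -> bool:
    sub = ref_seq[r0 : r0 + length]
    val, valid = kmer_codes(encode(sub[: index.k]), index.k)
    if len(val) == 0 or not valid[0]:
        return False
    for p in index.positions_for(int(val[0])):
        p = int(p)
        if p != r0 and ref_seq[p : p + length] == sub:
            return False
    return True


def find_mems(
    ref,
    qry,
    min_len: int = 20,
    unique_in_ref: bool = True,
    both_strands: bool = True,
) -> list[Match]:
    """Maximal exact matches of length >= ``min_len`` between two genomes.

    With ``unique_in_ref`` only matches whose reference substring occurs
    exactly once in the reference are kept (the ``mummer -mumreference``
    contract). N and masked bases never match anything.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ref_records, qry_records = _as_records(ref), _as_records(qry)
    k = min(min_len, 31)
    out: list[Match] = []
    for rrec in ref_records:
        rcodes = encode(rrec.seq, rrec.masked)
        index = _KmerIndex(rcodes, k)
        uniq_index = index  # uniqueness uses the same seed index
        for qrec in qry_records:
            strands = ["+", "-"] if both_strands else ["+"]
            for strand in strands:
                if strand == "+":
                    qseq = qrec.seq
                    qmask = qrec.masked
                else:
                    qseq = revcomp(qrec.seq)
                    qmask = None if qrec.masked is None else qrec.masked[::-1]
                qcodes = encode(qseq, qmask)
                qvals, qvalid = kmer_codes(qcodes, k)
                qpos_all = np.nonzero(qvalid)[0]
                rpos, qpos = index.lookup_many(qvals[qpos_all], qpos_all)
                for r0, q0, length in _maximal_runs(rpos, qpos, k):
                    if length < min_len:
                        continue
                    if unique_in_ref and not _is_unique_in_ref(
                        rrec.seq, uniq_index, r0, length
                    ):
                        continue
                    out.append(
                        Match(rrec.name, r0, qrec.name, q0, length, strand)
                    )
    out.sort()
    return out


@dataclass
class Cluster:
    """A collinear chain of same-strand matches between one sequence pair."""

    ref_name: str
    qry_name: str
    strand: str
    matches: list[Match]
    qry_len: int

    def __post_init__(self) -> None:
        self.matches = sorted(self.matches)

    @property
    def ref_start(self) -> int:
        return min(m.ref_start for m in self.matches)

    @property
    def ref_end(self) -> int:
        return max(m.ref_end for m in self.matches)

    # given-strand query interval (chaining space)
    @property
    def qs_start(self) -> int:
        return min(m.qry_start for m in self.matches)

    @property
    def qs_end(self) -> int:
        return max(m.qry_end for m in self.matches)

    # forward-strand query interval (reporting space)
    @property
    def qry_start(self) -> int:
        if self.strand == "+":
            return self.qs_start
        return self.qry_len - self.qs_end

    @property
    def qry_end(self) -> int:
        if self.strand == "+":
            return self.qs_end
        return self.qry_len - self.qs_start

    @property
    def total_match_len(self) -> int:
        return sum(m.length for m in self.matches)


def _chain_edges(ms: list[Match], s: int, f: float):
    """Adjacency for collinear chaining under separation/drift limits."""
    edges: list[list[int]] = [[] for _ in ms]  # predecessors of j
    for i, mi in enumerate(ms):
        for j in range(i + 1, len(ms)):
            mj = ms[j]
            if mj.ref_start - mi.ref_end > s:
                break
            if mj.ref_start <= mi.ref_start or mj.qry_start <= mi.qry_start:
                continue
            ref_gap = mj.ref_start - mi.ref_end
            qry_gap = mj.qry_start - mi.qry_end
            sep = max(ref_gap, qry_gap)
            drift = abs(ref_gap - qry_gap)
            if sep <= s and drift <= f * max(sep, 1):
                edges[j].append(i)
    return edges


def cluster_matches(
    matches: list[Match],
    qry_lengths: dict[str, int],
    s: int = 200,
    f: float = 0.12,
    l: int = 100,
) -> list[Cluster]:
    """Chain MEMs into clusters (the mgaps step).

    Consecutive chained matches must be separated by at most ``s`` bp on
    both genomes with diagonal drift at most ``f`` times the separation;
    chains carrying fewer than ``l`` matched bp are dropped. Matches are
    assigned to at most one cluster, best-total-length chains first.
    """
    clusters: list[Cluster] = []
    keyfn = lambda m: (m.ref_name, m.qry_name, m.strand)
    for key, group in itertools.groupby(sorted(matches, key=keyfn), key=keyfn):
        ms = sorted(group)
        alive = list(range(len(ms)))
        while alive:
            sub = [ms[i] for i in alive]
            edges = _chain_edges(sub, s, f)
            best = np.full(len(sub), 0.0)
            prev = np.full(len(sub), -1, dtype=int)
            for j in range(len(sub)):
                best[j] = sub[j].length
                for i in edges[j]:
                    cand = best[i] + sub[j].length
                    if cand > best[j]:
                        best[j], prev[j] = cand, i
            top = int(np.argmax(best))
            chain = []
            node = top
            while node != -1:
                chain.append(node)
                node = prev[node]
            chain.reverse()
            total = sum(sub[i].length for i in chain)
            if total < l:
                break
            clusters.append(
                Cluster(
                    key[0], key[1], key[2],
                    [sub[i] for i in chain],
                    qry_lengths[key[1]],
                )
            )
            removed = set(chain)
            alive = [a for idx, a in enumerate(alive) if idx not in removed]
    clusters.sort(key=lambda c: (c.ref_name, c.ref_start, c.qry_name, c.qry_start))
    return clusters


# ---------------------------------------------------------------------------
# affine-gap dynamic programming
# ---------------------------------------------------------------------------

NEG = np.float32(-1e7)


def affine_global_align(a: str | np.ndarray, b: str | np.ndarray):
    """Full affine-gap global alignment (Gotoh). Returns (score, ops).

    Ops are run-length encoded: '=' match, 'X' mismatch, 'D' consumes
    only ``a`` (gap in b), 'I' consumes only ``b`` (gap in a). N bases
    never match. Scores are exact multiples of 0.5, so the float
    comparisons in the traceback are exact.
    """
    ac = encode(a) if isinstance(a, str) else a
    bc = encode(b) if isinstance(b, str) else b
    n, m = len(ac), len(bc)
    H = np.empty((n + 1, m + 1), dtype=np.float32)
    E = np.empty_like(H)  # gap consuming b ('I')
    F = np.empty_like(H)  # gap consuming a ('D')
    j_arr = np.arange(m + 1, dtype=np.float32)
    H[0, :] = GAP_OPEN + GAP_EXT * j_arr
    H[0, 0] = 0.0
    E[0, :] = H[0, :]
    E[0, 0] = NEG
    F[0, :] = NEG
    ext_j = np.float32(GAP_EXT) * j_arr
    b_match = bc[None, :]  # (1, m)
    for i in range(1, n + 1):
        F[i, :] = np.maximum(F[i - 1, :] + np.float32(GAP_EXT),
                             H[i - 1, :] + np.float32(GAP_OPEN + GAP_EXT))
        sub = np.where(
            (ac[i - 1] == bc) & (ac[i - 1] != INVALID) & (bc != INVALID),
            np.float32(MATCH_SCORE),
            np.float32(MISMATCH_SCORE),
        )
        hrow = np.empty(m + 1, dtype=np.float32)
        hrow[0] = GAP_OPEN + GAP_EXT * i
        hrow[1:] = np.maximum(H[i - 1, :-1] + sub, F[i, 1:])
        # horizontal gaps: prefix-max trick (reopening is never better)
        g = hrow - ext_j
        pref = np.maximum.accumulate(g)
        E[i, 0] = NEG
        E[i, 1:] = np.float32(GAP_OPEN) + ext_j[1:] + pref[:-1]
        F[i, 0] = hrow[0]
        H[i, :] = np.maximum(hrow, E[i, :])
    score = float(H[n, m])
    # traceback
    ops: list[tuple[str, int]] = []

    def emit(op: str):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            if j > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                match = (
                    ac[i - 1] == bc[j - 1]
                    and ac[i - 1] != INVALID
                    and bc[j - 1] != INVALID
                )
                emit("=" if match else "X")
                i, j = i - 1, j - 1
        elif state == "E":
            emit("I")
            if j > 1 and E[i, j] == E[i, j - 1] + np.float32(GAP_EXT):
                pass
            else:
                state = "H"
            j -= 1
        else:  # F
            emit("D")
            if i > 1 and F[i, j] == F[i - 1, j] + np.float32(GAP_EXT):
                pass
            else:
                state = "H"
            i -= 1
    ops.reverse()
    return score, ops


def score_ops(ops: list[tuple[str, int]]) -> float:
    score = 0.0
    for op, ln in ops:
        if op == "=":
            score += MATCH_SCORE * ln
        elif op == "X":
            score += MISMATCH_SCORE * ln
        else:
            score += GAP_OPEN + GAP_EXT * ln
    return score


@dataclass
class BaseAlignment:
    """Base-level alignment of one cluster (or merged cluster chain)."""

    ref_name: str
    qry_name: str
    strand: str
    ref_start: int
    ref_end: int
    qry_start: int  # forward strand
    qry_end: int
    ops: list[tuple[str, int]]
    weight: float
    cluster: Cluster | None = None

    @property
    def score(self) -> float:
        return score_ops(self.ops)

    @property
    def identity(self) -> float:
        cols = sum(ln for _, ln in self.ops)
        eq = sum(ln for op, ln in self.ops if op == "=")
        return eq / cols if cols else 0.0

    def consumed(self) -> tuple[int, int]:
        r = sum(ln for op, ln in self.ops if op in "=XD")
        q = sum(ln for op, ln in self.ops if op in "=XI")
        return r, q


def _trimmed_anchors(cluster: Cluster):
    """Anchor list in cluster-local coordinates, overlaps trimmed away.

    Anchors are exact matches, so trimming a prefix keeps them exact.
    """
    anchors = []
    r_off, q_off = cluster.ref_start, cluster.qs_start
    last_r = last_q = 0
    for m in cluster.matches:
        r, q, ln = m.ref_start - r_off, m.qry_start - q_off, m.length
        cut = max(last_r - r, last_q - q, 0)
        r, q, ln = r + cut, q + cut, ln - cut
        if ln <= 0:
            continue
        if r < last_r or q < last_q:
            raise ValueError("anchors cross; cluster is not collinear")
        anchors.append((r, q, ln))
        last_r, last_q = r + ln, q + ln
    return anchors


def fill_cluster_alignment(
    cluster: Cluster,
    ref: SequenceRecord,
    qry: SequenceRecord,
    dp_limit: int = 1_000_000,
) -> BaseAlignment:
    """Resolve a cluster to a base-level alignment through its anchors.

    Small intervals get one unconstrained affine DP (so the result is a
    true optimum under the scoring scheme); larger intervals are solved
    piecewise, with exact-anchor columns fixed and full DP between
    consecutive anchors (gaps there are bounded by the chaining limits).
    """
    rseq = ref.seq[cluster.ref_start : cluster.ref_end]
    qfull = qry.seq if cluster.strand == "+" else revcomp(qry.seq)
    qseq = qfull[cluster.qs_start : cluster.qs_end]
    anchors = _trimmed_anchors(cluster)
    if len(rseq) * len(qseq) <= dp_limit:
        _, ops = affine_global_align(rseq, qseq)
    else:
        ops = []

        def extend(new_ops):
            for op, ln in new_ops:
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + ln)
                else:
                    ops.append((op, ln))

        pr = pq = 0
        for r, q, ln in anchors:
            gr, gq = rseq[pr:r], qseq[pq:q]
            if gr and gq:
                _, gap_ops = affine_global_align(gr, gq)
                extend(gap_ops)
            elif gr:
                extend([("D", len(gr))])
            elif gq:
                extend([("I", len(gq))])
            extend([("=", ln)])
            pr, pq = r + ln, q + ln
        if pr < len(rseq) or pq < len(qseq):
            gr, gq = rseq[pr:], qseq[pq:]
            if gr and gq:
                _, gap_ops = affine_global_align(gr, gq)
                extend(gap_ops)
            elif gr:
                extend([("D", len(gr))])
            elif gq:
                extend([("I", len(gq))])
    aln = BaseAlignment(
        ref_name=cluster.ref_name,
        qry_name=cluster.qry_name,
        strand=cluster.strand,
        ref_start=cluster.ref_start,
        ref_end=cluster.ref_end,
        qry_start=cluster.qry_start,
        qry_end=cluster.qry_end,
        ops=ops,
        weight=cluster.total_match_len,
        cluster=cluster,
    )
    r, q = aln.consumed()
    assert r == len(rseq) and q == len(qseq), "alignment does not cover cluster"
    return aln


@dataclass
class SyntenyBlock:
    """A BaseAlignment retained after one-to-one filtering."""

    aln: BaseAlignment

    def __getattr__(self, name):
        return getattr(self.aln, name)

    @property
    def weight(self) -> float:
        return self.aln.weight


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def _conflicts(a, b, mode: str, tol: int) -> bool:
    if (
        a.ref_name == b.ref_name
        and mode in ("one-to-one", "ref")
        and _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end) > tol
    ):
        return True
    if (
        a.qry_name == b.qry_name
        and mode in ("one-to-one", "query")
        and _overlap(a.qry_start, a.qry_end, b.qry_start, b.qry_end) > tol
    ):
        return True
    return False


def filter_mutual_best(
    alignments,
    mode: str = "one-to-one",
    tol: int = 50,
    exact_limit: int = 16,
) -> list:
    """Maximum-weight consistent subset of alignments.

    ``one-to-one`` forbids overlaps (beyond ``tol`` bp) on both the
    reference and query axes (delta-filter -r -q); ``query`` constrains
    only the query axis, reproducing the mutually-best behaviour used
    for scaffolding. Exact search up to ``exact_limit`` items, greedy
    by descending weight beyond that.
    """
    items = list(alignments)
    n = len(items)
    if n == 0:
        return []
    if n <= exact_limit:
        conflict_mask = [0] * n
        for i in range(n):
            for j in range(i + 1, n):
                if _conflicts(items[i], items[j], mode, tol):
                    conflict_mask[i] |= 1 << j
                    conflict_mask[j] |= 1 << i
        weights = [it.weight for it in items]
        best_mask, best_w = 0, -1.0
        for mask in range(1 << n):
            w = 0.0
            ok = True
            mm = mask
            while mm:
                i = (mm & -mm).bit_length() - 1
                if conflict_mask[i] & mask:
                    ok = False
                    break
                w += weights[i]
                mm &= mm - 1
            if ok and w > best_w:
                best_mask, best_w = mask, w
        kept = [items[i] for i in range(n) if best_mask >> i & 1]
    else:
        order = sorted(
            range(n),
            key=lambda i: (-items[i].weight, items[i].ref_name, items[i].ref_start),
        )
        kept = []
        for i in order:
            if not any(_conflicts(items[i], k, mode, tol) for k in kept):
                kept.append(items[i])
    kept.sort(key=lambda a: (a.ref_name, a.ref_start, a.qry_name, a.qry_start))
    if all(isinstance(k, BaseAlignment) for k in kept):
        return [SyntenyBlock(k) for k in kept]
    return kept


def merge_collinear_clusters(
    clusters: list[Cluster], join_gap: int = 100, max_overlap: int = 50
) -> list[Cluster]:
    """Join adjacent collinear clusters separated by sub-SV gaps.

    Gaps shorter than ``join_gap`` on both genomes are resolved at base
    level inside one synteny block (where per-column calling picks up
    SNPs and <100-bp indels); anything larger stays a block boundary.
    """
    out: list[Cluster] = []
    keyfn = lambda c: (c.ref_name, c.qry_name, c.strand)
    for key, group in itertools.groupby(sorted(clusters, key=keyfn), key=keyfn):
        # several chains stay open at once: a stray cluster (repeat
        # cross-match, duplication copy) interleaved in reference order
        # must not break the joining of its collinear neighbours
        chains: list[list[Cluster]] = []
        for c in sorted(group, key=lambda c: (c.ref_start, c.qs_start)):
            attached = False
            for chain in reversed(chains):
                p = chain[-1]
                ref_gap = c.ref_start - p.ref_end
                qry_gap = c.qs_start - p.qs_end
                if (
                    -max_overlap <= ref_gap < join_gap
                    and -max_overlap <= qry_gap < join_gap
                ):
                    chain.append(c)
                    attached = True
                    break
            if not attached:
                chains.append([c])
        out.extend(_fuse(chain) for chain in chains)
    out.sort(key=lambda c: (c.ref_name, c.ref_start, c.qry_name, c.qry_start))
    return out


def _fuse(chain: list[Cluster]) -> Cluster:
    if len(chain) == 1:
        return chain[0]
    matches = [m for c in chain for m in c.matches]
    first = chain[0]
    return Cluster(first.ref_name, first.qry_name, first.strand, matches, first.qry_len)
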