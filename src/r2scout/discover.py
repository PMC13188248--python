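"""Find R2-like loci in contigs and recover elements from long reads.

``scan_genome`` is a BLAST-like seeded search: exact k-mer seeds on both
strands (word size 7 by default, matching a sensitive nucleotide search),
diagonal-band chaining, and local affine-gap alignment of the chained
region.  ``rescue_from_reads`` rebuilds elements from long reads when the
assembly is truncated or chimeric: reads hitting the query are clustered by
mutual overlap and polished into a majority-vote consensus — a deliberately
simple stand-in for a dedicated long-read error-correction tool, asserted
only on synthetic data.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .alignment import (
    DEFAULT_AA,
    DEFAULT_NT,
    ScoringScheme,
    local_align,
    revcomp,
)

__all__ = [
    "Hit",
    "Locus",
    "ElementCandidate",
    "scan_genome",
    "merge_loci",
    "rescue_from_reads",
]


@dataclass
class Hit:
    contig_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: float
    identity: float
    query_id: str = ""


@dataclass
class Locus:
    contig_id: str
    start: int
    end: int
    strand: str
    best_score: float
    n_hits: int = 1


@dataclass
class ElementCandidate:
    candidate_id: str
    sequence: str
    source: str  # assembly | read-rescue
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"
    supporting_read_count: int = 0


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

_NT_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i

_AA_CODE = np.full(256, -1, dtype=np.int8)
for _i, _a in enumerate("ACDEFGHIKLMNPQRSTVWY"):
    _AA_CODE[ord(_a)] = _i


def _encode(seq: str, protein: bool) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    table = _AA_CODE if protein else _NT_CODE
    return table[raw].astype(np.int64)


def _kmer_codes(seq: str, k: int, protein: bool) -> np.ndarray:
    """Rolling k-mer codes; windows containing invalid letters get -1."""
    enc = _encode(seq, protein)
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    base = 20 if protein else 4
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = base ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    codes[(win < 0).any(axis=1)] = -1
    return codes


def _seed_pairs(query: str, subject: str, k: int, protein: bool, stride: int):
    """(subject_pos, query_pos) arrays of exact shared k-mers; query k-mers
    sampled every ``stride`` positions (every subject position is scanned)."""
    qc = _kmer_codes(query, k, protein)
    sc = _kmer_codes(subject, k, protein)
    if qc.size == 0 or sc.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qpos = np.arange(0, qc.size, stride)
    qc = qc[qpos]
    ok = qc >= 0
    qc, qpos = qc[ok], qpos[ok]
    order = np.argsort(qc, kind="stable")
    qc_sorted, qpos_sorted = qc[order], qpos[order]
    valid = sc >= 0
    spos_all = np.nonzero(valid)[0]
    sc_valid = sc[valid]
    lo = np.searchsorted(qc_sorted, sc_valid, side="left")
    hi = np.searchsorted(qc_sorted, sc_valid, side="right")
    counts = hi - lo
    has = counts > 0
    spos_rep = np.repeat(spos_all[has], counts[has])
    qidx = np.concatenate(
        [np.arange(l, h) for l, h in zip(lo[has], hi[has])]
    ) if has.any() else np.empty(0, np.int64)
    return spos_rep, qpos_sorted[qidx]


def _chain_regions(
    spos: np.ndarray,
    qpos: np.ndarray,
    qlen: int,
    slen: int,
    band_width: int,
    min_band_seeds: int,
    pad: int,
) -> list[tuple[int, int]]:
    """Cluster seed pairs by diagonal band and return candidate subject
    regions extended to cover the full query projection."""
    if spos.size == 0:
        return []
    diag = spos - qpos + qlen
    band = diag // band_width
    bands, counts = np.unique(band, return_counts=True)
    keep = set(bands[counts >= min_band_seeds].tolist())
    if not keep:
        return []
    # group adjacent kept bands
    kept_sorted = sorted(keep)
    groups: list[list[int]] = [[kept_sorted[0]]]
    for b in kept_sorted[1:]:
        if b - groups[-1][-1] <= 1:
            groups[-1].append(b)
        else:
            groups.append([b])
    regions = []
    for grp in groups:
        mask = np.isin(band, grp)
        s_sel, q_sel = spos[mask], qpos[mask]
        start = max(0, int((s_sel - q_sel).min()) - pad)
        end = min(slen, int((s_sel + (qlen - q_sel)).max()) + pad)
        regions.append((start, end))
    # merge overlapping regions
    regions.sort()
    merged = [list(regions[0])]
    for s, e in regions[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _translate_frames(seq: str):
    """Six-frame translation: [(frame_key, protein, mapper)] where mapper
    converts protein half-open coords to forward-strand nt coords."""
    from .domains import _translate_codon

    out = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            n_codons = (len(s) - f) // 3
            prot = "".join(
                _translate_codon(s[f + 3 * i : f + 3 * i + 3]) for i in range(n_codons)
            )

            def mapper(ps, pe, f=f, strand=strand):
                a, b = f + 3 * ps, f + 3 * pe
                if strand == "+":
                    return a, b
                return L - b, L - a

            out.append((strand, f, prot, mapper))
    return out


def scan_genome(
    queries: dict[str, str],
    contigs: dict[str, str],
    mode: str = "nucleotide",
    k: int | None = None,
    scoring: ScoringScheme | None = None,
    min_score: float = 60.0,
    seed_stride: int = 3,
    band_width: int = 16,
    min_band_seeds: int = 8,
    pad: int = 64,
) -> list[Hit]:
    """Seeded search of queries against contigs on both strands.

    ``mode="nucleotide"`` uses nucleotide queries (default word size 7);
    ``mode="translated"`` scans the six frames of each contig with protein
    queries (default word size 4).  Chained seed regions are confirmed by
    local affine-gap alignment; hits below ``min_score`` are dropped.
    """
    if not queries:
        raise ValueError("no queries supplied")
    if mode not in ("nucleotide", "translated"):
        raise ValueError("mode must be 'nucleotide' or 'translated'")
    protein = mode == "translated"
    if k is None:
        k = 4 if protein else 7
    if k < (2 if protein else 4):
        raise ValueError("word size too small")
    scheme = scoring or (DEFAULT_AA if protein else DEFAULT_NT)
    hits: list[Hit] = []
    for cid, contig in contigs.items():
        if not contig:
            continue
        if protein:
            hits.extend(
                _scan_translated(
                    queries, cid, contig, k, scheme, min_score,
                    seed_stride, band_width, min_band_seeds, pad,
                )
            )
        else:
            hits.extend(
                _scan_nucleotide(
                    queries, cid, contig, k, scheme, min_score,
                    seed_stride, band_width, min_band_seeds, pad,
                )
            )
    return hits


def _scan_nucleotide(
    queries, cid, contig, k, scheme, min_score, stride, band_width, min_band_seeds, pad
):
    hits = []
    seen = set()
    for qid, query in queries.items():
        for strand in "+-":
            q = query if strand == "+" else revcomp(query)
            spos, qpos = _seed_pairs(q, contig, k, False, stride)
            for rs, re_ in _chain_regions(
                spos, qpos, len(q), len(contig), band_width, min_band_seeds, pad
            ):
                res = local_align(q, contig[rs:re_], scheme)
                if res.empty or res.score < min_score:
                    continue
                s_start, s_end = rs + res.s_start, rs + res.s_end
                if strand == "+":
                    q_start, q_end = res.q_start, res.q_end
                else:
                    q_start, q_end = len(q) - res.q_end, len(q) - res.q_start
                key = (qid, strand, s_start, s_end)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    Hit(cid, q_start, q_end, s_start, s_end, strand,
                        res.score, res.identity, qid)
                )
    return hits


def _scan_translated(
    queries, cid, contig, k, scheme, min_score, stride, band_width, min_band_seeds, pad
):
    hits = []
    for strand, frame, prot, mapper in _translate_frames(contig):
        for qid, query in queries.items():
            spos, qpos = _seed_pairs(query, prot, k, True, stride)
            for rs, re_ in _chain_regions(
                spos, qpos, len(query), len(prot), band_width, min_band_seeds, pad
            ):
                res = local_align(query, prot[rs:re_], scheme)
                if res.empty or res.score < min_score:
                    continue
                nt_start, nt_end = mapper(rs + res.s_start, rs + res.s_end)
                hits.append(
                    Hit(cid, res.q_start, res.q_end, nt_start, nt_end, strand,
                        res.score, res.identity, qid)
                )
    return hits


def merge_loci(hits: list[Hit], max_gap: int = 500) -> list[Locus]:
    """Merge hits on the same contig and strand separated by <= max_gap
    into one locus; idempotent, and output loci are pairwise separated by
    more than max_gap."""
    groups: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in hits:
        groups[(h.contig_id, h.strand)].append(h)
    loci: list[Locus] = []
    for (cid, strand), hs in sorted(groups.items()):
        hs.sort(key=lambda h: (h.s_start, h.s_end))
        current = Locus(cid, hs[0].s_start, hs[0].s_end, strand, hs[0].score)
        for h in hs[1:]:
            if h.s_start - current.end <= max_gap:
                current.end = max(current.end, h.s_end)
                current.best_score = max(current.best_score, h.score)
                current.n_hits += 1
            else:
                loci.append(current)
                current = Locus(cid, h.s_start, h.s_end, strand, h.score)
        loci.append(current)
    return loci


# ---------------------------------------------------------------------------
# Read rescue
# ---------------------------------------------------------------------------


def _shared_kmer_positions(a: str, b: str, k: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(b) - k + 1):
        index[b[i : i + k]].append(i)
    out = []
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            out.append((i, j))
    return out


def _orient_read(seq: str, query: str, k: int) -> tuple[str, int, tuple[int, int] | None]:
    """Orient a read against the query by shared k-mer count; returns the
    oriented sequence, the count, and the query-projection interval."""
    best = (None, 0, None)
    for oriented in (seq, revcomp(seq)):
        pairs = _shared_kmer_positions(oriented, query, k)
        if len(pairs) > best[1]:
            qlo = min(j for _, j in pairs)
            qhi = max(j for _, j in pairs) + k
            best = (oriented, len(pairs), (qlo, qhi))
    return best


def _pileup_consensus(backbone: str, reads: list[str], scheme: ScoringScheme) -> str:
    """One round of majority-vote polishing of the backbone from read
    alignments (substitutions, deletions, and insertions)."""
    base_votes: list[Counter] = [Counter() for _ in backbone]
    ins_votes: list[Counter] = [Counter() for _ in range(len(backbone) + 1)]
    for read in reads:
        res = local_align(read, backbone, scheme)
        if res.empty:
            continue
        bpos = res.s_start
        pending_ins: list[str] = []
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if cb == "-":
                pending_ins.append(ca)
                continue
            if pending_ins:
                ins_votes[bpos][("".join(pending_ins))] += 1
                pending_ins = []
            base_votes[bpos][ca if ca != "-" else "-"] += 1
            bpos += 1
        if pending_ins:
            ins_votes[bpos]["".join(pending_ins)] += 1
    out: list[str] = []
    for p, ch in enumerate(backbone):
        votes = base_votes[p]
        cov = sum(votes.values())
        ins = ins_votes[p]
        if ins and cov and sum(ins.values()) * 2 > cov:
            out.append(ins.most_common(1)[0][0])
        if cov == 0:
            out.append(ch)
            continue
        top, n = votes.most_common(1)[0]
        if top != "-":
            out.append(top)
        # '-' majority: deletion, emit nothing
    ins = ins_votes[len(backbone)]
    return "".join(out)


def _extend_backbone(reads, projs, scheme):
    """Greedy layout: start from the read with the widest query projection
    and splice in unaligned overhangs of reads projecting beyond either
    end, until the backbone spans the cluster's whole projection."""
    order = max(range(len(reads)), key=lambda i: projs[i][1] - projs[i][0])
    backbone = reads[order]
    b_lo, b_hi = projs[order]
    remaining = set(range(len(reads))) - {order}
    while True:
        # only reads that both overlap the current span and project beyond it
        left = [
            i for i in remaining
            if projs[i][0] < b_lo - 10 and projs[i][1] > b_lo + 50
        ]
        right = [
            i for i in remaining
            if projs[i][1] > b_hi + 10 and projs[i][0] < b_hi - 50
        ]
        if not left and not right:
            break
        if left:
            i = min(left, key=lambda i: projs[i][0])
        else:
            i = max(right, key=lambda i: projs[i][1])
        remaining.discard(i)
        res = local_align(reads[i], backbone, scheme)
        if res.empty:
            continue
        if i in left and res.s_start <= 5 and res.q_start > 0:
            backbone = reads[i][: res.q_start] + backbone
            b_lo = projs[i][0]
        elif i in right and res.s_end >= len(backbone) - 5 and res.q_end < len(reads[i]):
            backbone = backbone + reads[i][res.q_end :]
            b_hi = projs[i][1]
    return backbone, (b_lo, b_hi)


def rescue_from_reads(
    query: str,
    long_reads,
    short_reads=None,
    polish_rounds: int = 1,
    k: int = 15,
    min_shared_kmers: int = 5,
    min_overlap: int = 100,
    consensus_rounds: int = 2,
    scoring: ScoringScheme | None = None,
    trim_to_query: bool = True,
) -> list[ElementCandidate]:
    """Reconstruct element candidates from long reads hitting the query.

    Reads sharing at least ``min_shared_kmers`` exact k-mers with the query
    (either orientation) are clustered by mutual overlap of their query
    projections; each cluster is polished into a majority-vote consensus
    anchored on the read with the widest projection.  ``polish_rounds``
    extra rounds use the short reads, when given, as additional voters.
    Reads that never hit the query yield an empty list.
    """
    if not long_reads:
        raise ValueError("at least one long read is required")
    scheme = scoring or DEFAULT_NT
    oriented = []
    for rec in long_reads:
        seq = rec[1] if isinstance(rec, (tuple, list)) else str(rec)
        o, count, proj = _orient_read(seq, query, k)
        if count >= min_shared_kmers and proj is not None:
            oriented.append((o, proj))
    if not oriented:
        return []
    # union-find over overlap of query projections
    parent = list(range(len(oriented)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(oriented)):
        for j in range(i + 1, len(oriented)):
            (alo, ahi), (blo, bhi) = oriented[i][1], oriented[j][1]
            if min(ahi, bhi) - max(alo, blo) >= min_overlap:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(oriented)):
        clusters[find(i)].append(i)

    short_seqs = []
    if short_reads:
        for rec in short_reads:
            seq = rec[1] if isinstance(rec, (tuple, list)) else str(rec)
            o, count, _ = _orient_read(seq, query, k)
            if count >= 1:
                short_seqs.append(o)

    candidates = []
    for ci, members in enumerate(sorted(clusters.values(), key=lambda m: -len(m))):
        reads = [oriented[i][0] for i in members]
        projs = [oriented[i][1] for i in members]
        span = max(p[1] for p in projs) - min(p[0] for p in projs)
        if span < min_overlap:
            continue  # marginal edge evidence, not a reportable candidate
        backbone, b_proj = _extend_backbone(reads, projs, scheme)
        for _ in range(consensus_rounds):
            backbone = _pileup_consensus(backbone, reads, scheme)
        for _ in range(polish_rounds if short_seqs else 0):
            backbone = _pileup_consensus(backbone, short_seqs, scheme)
        consensus = backbone
        if trim_to_query:
            res = local_align(query, consensus, scheme)
            if not res.empty:
                lo = max(0, res.s_start - res.q_start)
                hi = min(len(consensus), res.s_end + (len(query) - res.q_end))
                consensus = consensus[lo:hi]
        candidates.append(
            ElementCandidate(
                candidate_id=f"rescue_{ci}",
                sequence=consensus,
                source="read-rescue",
                supporting_read_count=len(members),
            )
        )
    return candidates
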