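"""Alignment, trimming, neighbor-joining trees, and tree comparison.

The tree machinery is deliberately distance-based: canonical neighbor
joining is exact on additive matrices and therefore fully oracle-testable,
with nonparametric bootstrap supports (column resampling) and outgroup
rooting on the outgroup's pendant edge.  Alignment is progressive (k-mer
guide tree, then profile-profile affine-gap alignment); trimming drops
columns above a gap-fraction threshold.  All of this is recorded in tree
metadata as a distance-based reconstruction, not a maximum-likelihood one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .alignment import DEFAULT_AA, ScoringScheme, global_align

__all__ = [
    "Msa",
    "Clade",
    "align_progressive",
    "trim_alignment",
    "distance_matrix",
    "neighbor_joining",
    "rf_distance",
    "identity_matrix",
    "partition_trees",
    "parse_newick",
]

GAP = "-"


@dataclass
class Msa:
    """A multiple sequence alignment: unique taxa, equal-length gapped rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.taxa)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.taxa, self.rows))

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass
class Clade:
    """A rooted tree node; ``support`` is a bootstrap percentage on the
    edge above this node (internal edges only)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            label = self.name or ""
            if any(ch in label for ch in " (),:;"):
                label = f"'{label}'"
            return f"{label}:{self.length:.6g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


def parse_newick(text: str) -> Clade:
    """Parse a newick string (internal labels read as bootstrap supports)."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(node) -> Clade:
        if node.is_leaf():
            return Clade(name=node.taxon.label if node.taxon else node.label,
                         length=node.edge.length or 0.0)
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        return Clade(
            name=None,
            length=node.edge.length or 0.0,
            support=support,
            children=[convert(c) for c in node.child_nodes()],
        )

    return convert(dtree.seed_node)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(_AA)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {}
    for i in range(len(a) - k + 1):
        ka[a[i : i + k]] = ka.get(a[i : i + k], 0) + 1
    shared = 0
    kb = {}
    for i in range(len(b) - k + 1):
        kb[b[i : i + k]] = kb.get(b[i : i + k], 0) + 1
    for km, ca in ka.items():
        shared += min(ca, kb.get(km, 0))
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


def _profile_freqs(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    F = np.zeros((ncol, 20))
    for r in rows:
        for j, c in enumerate(r):
            i = _AA_IDX.get(c)
            if i is not None:
                F[j, i] += 1
    return F / len(rows)


def _subst_array(scheme: ScoringScheme) -> np.ndarray:
    m = scheme.substitution_matrix()
    S = np.zeros((20, 20))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            S[i, j] = m[a, b]
    return S


def _align_profiles(rows1, rows2, S, gap_open, gap_extend):
    """Global affine-gap profile-profile alignment; returns the two gapped
    row lists merged under the optimal path (sum-of-pairs expected score)."""
    F1, F2 = _profile_freqs(rows1), _profile_freqs(rows2)
    M = F1 @ S @ F2.T
    n, m = M.shape
    NEG = -1e18
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in rows1 (consumes profile 2)
    Fm = np.full((n + 1, m + 1), NEG)  # gap in rows2 (consumes profile 1)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -go - (j - 1) * ge
        H[0, j] = E[0, j]
        ptr[0, j, 0] = 1
        ptr[0, j, 1] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        Fm[i, 0] = -go - (i - 1) * ge
        H[i, 0] = Fm[i, 0]
        ptr[i, 0, 0] = 2
        ptr[i, 0, 2] = 1 if i > 1 else 0
    for i in range(1, n + 1):
        Mi = M[i - 1]
        for j in range(1, m + 1):
            e_ext, e_open = E[i, j - 1] - ge, H[i, j - 1] - go
            if e_ext >= e_open:
                E[i, j], ptr[i, j, 1] = e_ext, 1
            else:
                E[i, j], ptr[i, j, 1] = e_open, 0
            f_ext, f_open = Fm[i - 1, j] - ge, H[i - 1, j] - go
            if f_ext >= f_open:
                Fm[i, j], ptr[i, j, 2] = f_ext, 1
            else:
                Fm[i, j], ptr[i, j, 2] = f_open, 0
            diag = H[i - 1, j - 1] + Mi[j - 1]
            best, state = diag, 0
            if E[i, j] > best:
                best, state = E[i, j], 1
            if Fm[i, j] > best:
                best, state = Fm[i, j], 2
            H[i, j], ptr[i, j, 0] = best, state
    # traceback over the three-state lattice
    i, j, state = n, m, 0
    path = []
    while i > 0 or j > 0:
        if state == 0:
            move = int(ptr[i, j, 0])
            if move == 1:
                state = 1
            elif move == 2:
                state = 2
            else:
                path.append("M")
                i, j = i - 1, j - 1
        elif state == 1:
            path.append("E")
            state = 1 if ptr[i, j, 1] else 0
            j -= 1
        else:
            path.append("F")
            state = 2 if ptr[i, j, 2] else 0
            i -= 1
    path.reverse()
    # rebuild rows from the path
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    i = j = 0
    for op in path:
        if op == "M":
            for t, r in enumerate(rows1):
                out1[t] += r[i]
            for t, r in enumerate(rows2):
                out2[t] += r[j]
            i += 1
            j += 1
        elif op == "E":  # column from profile 2 only
            for t in range(len(rows1)):
                out1[t] += GAP
            for t, r in enumerate(rows2):
                out2[t] += r[j]
            j += 1
        else:  # column from profile 1 only
            for t, r in enumerate(rows1):
                out1[t] += r[i]
            for t in range(len(rows2)):
                out2[t] += GAP
            i += 1
    return out1, out2


def align_progressive(seqs, scoring: ScoringScheme | None = None) -> Msa:
    """Progressive multiple alignment.

    Guide tree from pairwise k-mer distances (average linkage), then
    profile-profile global affine-gap alignment along the merge order.
    Gaps are only ever inserted; ungapping any output row reproduces the
    corresponding input sequence.
    """
    scheme = scoring or DEFAULT_AA
    pairs = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(pairs) < 2:
        raise ValueError("need at least 2 sequences")
    if len(pairs) == 2:
        res = global_align(pairs[0][1], pairs[1][1], scheme)
        return Msa(taxa=ids, rows=[res.aligned_a, res.aligned_b])
    n = len(pairs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(pairs[i][1], pairs[j][1])
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    S = _subst_array(scheme)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [pairs[i][1]]) for i in range(n)
    }
    for step, (a, b, _dist, _cnt) in enumerate(Z):
        ta, ra = clusters.pop(int(a))
        tb, rb = clusters.pop(int(b))
        if len(ra) == 1 and len(rb) == 1:
            res = global_align(ra[0], rb[0], scheme)
            merged = ([*ta, *tb], [res.aligned_a, res.aligned_b])
        else:
            o1, o2 = _align_profiles(ra, rb, S, scheme.gap_open, scheme.gap_extend)
            merged = ([*ta, *tb], [*o1, *o2])
        clusters[n + step] = merged
    taxa, rows = clusters.popitem()[1]
    order = {t: i for i, t in enumerate(ids)}
    paired = sorted(zip(taxa, rows), key=lambda tr: order[tr[0]])
    return Msa(taxa=[t for t, _ in paired], rows=[r for _, r in paired])


def trim_alignment(msa: Msa, max_gap_fraction: float = 0.9) -> tuple[Msa, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the dropped column indices; raises
    when nothing survives.
    """
    nrow = len(msa)
    keep, dropped = [], []
    for j in range(msa.n_columns):
        gaps = sum(1 for r in msa.rows if r[j] in "-.")
        (dropped if gaps / nrow > max_gap_fraction else keep).append(j)
    if not keep:
        raise ValueError("all columns dropped by trimming")
    rows = ["".join(r[j] for j in keep) for r in msa.rows]
    return Msa(taxa=list(msa.taxa), rows=rows), dropped


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

CORRECTIONS = ("p", "poisson", "kimura-protein")


def distance_matrix(msa: Msa, correction: str = "poisson") -> pd.DataFrame:
    """Pairwise distances over columns where both rows are ungapped.

    p: raw proportion of differing sites; poisson: -ln(1-p);
    kimura-protein: -ln(1 - p - 0.2 p^2).
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if len(msa) < 2:
        raise ValueError("need at least 2 rows")
    n = len(msa)
    arr = np.array([list(r) for r in msa.rows])
    ungapped = ~np.isin(arr, ["-", "."])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            if not both.any():
                raise ValueError(
                    f"no comparable columns between {msa.taxa[i]} and {msa.taxa[j]}"
                )
            p = float((arr[i, both] != arr[j, both]).mean())
            if correction == "p":
                d = p
            elif correction == "poisson":
                d = -np.log(max(1.0 - p, 1e-12))
            else:
                d = -np.log(max(1.0 - p - 0.2 * p * p, 1e-12))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=msa.taxa, columns=msa.taxa)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _nj_core(D: np.ndarray, taxa: list[str]) -> Clade:
    """Canonical NJ agglomeration; ties in the Q criterion are broken by
    the lowest (i, j) node-index pair.  Negative branch lengths are clamped
    to zero with the deficit moved to the sister edge.  Returns an
    unrooted tree as a trifurcating (or 3-taxon star) root."""
    nodes = [Clade(name=t) for t in taxa]
    D = D.astype(float).copy()
    active = list(range(len(taxa)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ii, jj = min((min(a, b), max(a, b)) for a, b in cand)
        i_g, j_g = active[ii], active[jj]
        d_ij = sub[ii, jj]
        li = 0.5 * d_ij + (r[ii] - r[jj]) / (2 * (n - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        ni, nj = nodes[i_g], nodes[j_g]
        ni.length, nj.length = float(li), float(lj)
        new = Clade(children=[ni, nj])
        new_idx = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (i_g, j_g):
                continue
            d = 0.5 * (D[i_g, kk] + D[j_g, kk] - d_ij)
            D[new_idx, kk] = D[kk, new_idx] = d
        active = [a for a in active if a not in (i_g, j_g)] + [new_idx]
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for idx, l in zip((a, b, c), (la, lb, lc)):
            nodes[idx].length = float(max(l, 0.0))
        return Clade(children=[nodes[a], nodes[b], nodes[c]])
    if len(active) == 2:
        a, b = active
        nodes[a].length = float(max(D[a, b], 0.0)) / 2
        nodes[b].length = float(max(D[a, b], 0.0)) / 2
        return Clade(children=[nodes[a], nodes[b]])
    return nodes[active[0]]


def _edges(tree: Clade):
    """Undirected edge list (u, v, length, support) plus node registry."""
    edges = []

    def rec(node):
        for c in node.children:
            edges.append((node, c, c.length, c.support))
            rec(c)

    rec(tree)
    return edges


def _reroot_on_pendant(tree: Clade, outgroup: str) -> Clade:
    """Root the (unrooted) tree at the midpoint of the outgroup's pendant
    edge."""
    adj: dict[int, list[tuple[Clade, float, float | None]]] = {}
    nodes: dict[int, Clade] = {}

    for u, v, length, support in _edges(tree):
        nodes[id(u)] = u
        nodes[id(v)] = v
        adj.setdefault(id(u), []).append((v, length, support))
        adj.setdefault(id(v), []).append((u, length, support))

    leaf = next((n for n in nodes.values() if n.is_leaf() and n.name == outgroup), None)
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    (neighbor, length, support) = adj[id(leaf)][0]

    def build(node: Clade, parent: Clade | None, elen: float, esup) -> Clade:
        out = Clade(name=node.name if node.is_leaf() else None, length=elen,
                    support=esup)
        for nxt, l, s in adj[id(node)]:
            if parent is not None and nxt is parent:
                continue
            if nxt is node:
                continue
            out.children.append(build(nxt, node, l, s))
        return out

    root = Clade(name=None, length=0.0)
    root.children.append(build(leaf, neighbor, length / 2.0, None))
    root.children.append(build(neighbor, leaf, length / 2.0, support))
    return root


def bipartitions(tree: Clade, leafset: frozenset | None = None) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets (the side not
    containing the lexicographically smallest leaf)."""
    all_leaves = frozenset(leafset or tree.leaves())
    ref = min(all_leaves)
    out = set()
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaves())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if ref in side:
            side = all_leaves - side
        out.add(side)
    return out


def neighbor_joining(
    dist,
    outgroup: str | None = None,
    bootstrap: dict | None = None,
) -> Clade:
    """Build an NJ tree from a symmetric distance matrix.

    ``dist`` is a pandas DataFrame (taxa as index/columns) or a (matrix,
    taxa) pair.  With ``bootstrap={"msa": Msa, "B": int, "seed": int,
    "correction": str}`` alignment columns are resampled B times and each
    internal edge is annotated with the percentage of replicates containing
    its bipartition.  With an outgroup, the tree is rooted on the
    outgroup's pendant edge.
    """
    if isinstance(dist, pd.DataFrame):
        taxa = [str(t) for t in dist.index]
        D = dist.to_numpy(dtype=float)
    else:
        D, taxa = dist
        D = np.asarray(D, dtype=float)
        taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if outgroup is not None and outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    tree = _nj_core(D, taxa)

    if bootstrap is not None:
        msa: Msa = bootstrap["msa"]
        B = int(bootstrap.get("B", 1000))
        seed = int(bootstrap.get("seed", 0))
        correction = bootstrap.get("correction", "poisson")
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        ncol = msa.n_columns
        for _ in range(B):
            cols = rng.integers(0, ncol, size=ncol)
            rows = ["".join(r[j] for j in cols) for r in msa.rows]
            Db = distance_matrix(Msa(taxa=list(msa.taxa), rows=rows), correction)
            rep = _nj_core(Db.loc[taxa, taxa].to_numpy(), taxa)
            for bp in bipartitions(rep):
                counts[bp] = counts.get(bp, 0) + 1
        all_leaves = frozenset(taxa)
        ref = min(all_leaves)
        for node in tree.walk():
            if node is tree or node.is_leaf():
                continue
            side = frozenset(node.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            canon = all_leaves - side if ref in side else side
            node.support = 100.0 * counts.get(canon, 0) / B

    if outgroup is not None:
        tree = _reroot_on_pendant(tree, outgroup)
    return tree


def _prune_to(tree: Clade, keep: set) -> Clade | None:
    if tree.is_leaf():
        return (
            Clade(name=tree.name, length=tree.length, support=tree.support)
            if tree.name in keep
            else None
        )
    kids = [k for k in (_prune_to(c, keep) for c in tree.children) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        kid = kids[0]
        kid.length += tree.length
        return kid
    return Clade(name=None, length=tree.length, support=tree.support, children=kids)


def rf_distance(t1: Clade, t2: Clade) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of
    internal bipartitions on the shared leaf set (trees are pruned to it
    first).  Requires at least 4 shared leaves."""
    shared = set(t1.leaves()) & set(t2.leaves())
    if len(shared) < 4:
        raise ValueError("trees share fewer than 4 leaves")
    p1 = _prune_to(t1, shared)
    p2 = _prune_to(t2, shared)
    fs = frozenset(shared)
    b1 = bipartitions(p1, fs)
    b2 = bipartitions(p2, fs)
    return len(b1 ^ b2)


def identity_matrix(seqs) -> pd.DataFrame:
    """Percentage identity matrix.

    Accepts an Msa or unaligned sequences (aligned first).  Identity for a
    pair is 100 * matches / columns where at least one of the two rows has
    a residue; diagonal is 100.
    """
    if isinstance(seqs, Msa):
        msa = seqs
    else:
        pairs = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
        if len(pairs) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for _, s in pairs}
        if len(lengths) == 1:
            msa = Msa(taxa=[i for i, _ in pairs], rows=[s for _, s in pairs])
        else:
            msa = align_progressive(pairs)
    n = len(msa)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            cols = sum(1 for x, y in zip(a, b) if not (x in "-." and y in "-."))
            matches = sum(1 for x, y in zip(a, b) if x == y and x not in "-.")
            out[i, j] = out[j, i] = 100.0 * matches / cols if cols else 0.0
    return pd.DataFrame(out, index=msa.taxa, columns=msa.taxa)


def partition_trees(
    msa: Msa,
    partitions: dict[str, tuple[int, int]],
    correction: str = "poisson",
    outgroup: str | None = None,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> dict[str, Clade]:
    """Build one NJ tree per domain partition (disjoint, in-bounds column
    ranges, 0-based half-open)."""
    spans = sorted(partitions.values())
    for (s, e) in spans:
        if not (0 <= s < e <= msa.n_columns):
            raise ValueError(f"partition ({s}, {e}) out of bounds")
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("partitions overlap")
    out = {}
    for name, (s, e) in partitions.items():
        sub = Msa(taxa=list(msa.taxa), rows=[r[s:e] for r in msa.rows])
        boot = (
            {"msa": sub, "B": bootstrap_B, "seed": seed, "correction": correction}
            if bootstrap_B
            else None
        )
        out[name] = neighbor_joining(
            distance_matrix(sub, correction), outgroup=outgroup, bootstrap=boot
        )
    return out
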