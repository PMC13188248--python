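"""Lineage placement of RT domains and per-site evolutionary rates.

The two deep R2 lineages (A and D) are distinguished by scoring reference RT
sequences against a position-specific scoring matrix (PSSM) built from the
candidate family: the family forms the profile and the lineage
representatives are the queries, mirroring a PSI-BLAST database search
queried with known-active RT domains.  Scores are half-bit log-odds.

Per-column evolutionary rates are posterior means over K discrete-gamma rate
categories under a 20-state equal-rates amino-acid substitution model, with
the gamma shape fitted by maximum likelihood via Felsenstein's pruning
recursion.  Rates are reported binned into equal-frequency sextiles
(bin 1 = most conserved), the convention used for RT-domain conservation
tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_STATES = 20
# Rate constant of the 20-state equal-rates model normalised so that branch
# lengths are expected substitutions per site: P_diff(t) = (19/20)(1-e^(-20t/19)).
_LAMBDA = N_STATES / (N_STATES - 1)

GAP_CHARS = set("-.")

__all__ = [
    "Pssm",
    "LineagePlacement",
    "SiteRates",
    "build_pssm",
    "score_against_pssm",
    "lineage_placement",
    "site_rates",
    "save_pssm",
    "load_pssm",
]


@dataclass
class Pssm:
    """Position-specific half-bit log-odds profile over the 20 amino acids."""

    scores: np.ndarray  # (length, 20) half-bit integers
    background: np.ndarray  # (20,), sums to 1
    pseudocount: float
    kept_columns: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        """Score of the per-column best residue (ungapped consensus)."""
        return float(self.scores.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.scores.argmax(axis=1))


@dataclass
class LineagePlacement:
    """Placement of a candidate RT family relative to the A/D references."""

    score_vs_A: float
    score_vs_D: float
    call: str  # "A", "D", or "ambiguous"
    margin: float


@dataclass
class SiteRates:
    alpha_hat: float
    posterior_mean: np.ndarray  # per-column; NaN where all rows are gaps
    bins: np.ndarray  # integers 1..6; 0 where rate undefined
    log_likelihood: float = float("nan")


def _rows(msa) -> list[str]:
    """Accept an Msa object, a mapping id->seq, or a sequence of (id, seq)."""
    if hasattr(msa, "rows"):
        return list(msa.rows)
    if isinstance(msa, Mapping):
        return list(msa.values())
    return [seq for _, seq in msa]


def _pairs(msa) -> list[tuple[str, str]]:
    if hasattr(msa, "taxa") and hasattr(msa, "rows"):
        return list(zip(msa.taxa, msa.rows))
    if isinstance(msa, Mapping):
        return list(msa.items())
    return list(msa)


def build_pssm(
    aligned_seqs,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    max_gap_fraction: float = 0.5,
) -> Pssm:
    """Build a half-bit log-odds PSSM from aligned sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped (their
    indices recorded in ``kept_columns``' complement).  Column frequencies
    use Dirichlet-style smoothing ``(counts + pc * bg) / (n + pc)`` and
    scores are ``2 * log2(freq / bg)`` rounded to the nearest half-bit.
    """
    rows = [r.upper() for r in _rows(aligned_seqs)]
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("unequal row lengths")
    bg = (
        np.full(N_STATES, 1.0 / N_STATES)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must sum to 1")

    kept, cols = [], []
    for j in range(ncol):
        column = [r[j] for r in rows]
        gap_frac = sum(c in GAP_CHARS for c in column) / len(column)
        if gap_frac > max_gap_fraction:
            continue
        kept.append(j)
        counts = np.zeros(N_STATES)
        n = 0
        for c in column:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
                n += 1
        freqs = (counts + pseudocount * bg) / (n + pseudocount)
        with np.errstate(divide="ignore"):
            col_scores = 2.0 * np.log2(freqs / bg)
        cols.append(np.round(col_scores))
    if not cols:
        raise ValueError("no columns retained")
    return Pssm(
        scores=np.vstack(cols),
        background=bg,
        pseudocount=pseudocount,
        kept_columns=kept,
    )


_UNKNOWN_SCORE = -8.0  # half-bits for X/B/Z against any profile column


def _query_scores(query: str, pssm: Pssm) -> np.ndarray:
    """(len(query), length) lookup of profile scores for each query residue."""
    out = np.full((len(query), pssm.length), _UNKNOWN_SCORE)
    for i, c in enumerate(query.upper()):
        j = _AA_INDEX.get(c)
        if j is not None:
            out[i] = pssm.scores[:, j]
    return out


def score_against_pssm(
    query_aa: str, pssm: Pssm, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal affine-gap local alignment score of a query to the profile.

    Smith-Waterman over profile columns; a gap of length L costs
    ``gap_open + L * gap_extend`` half-bits.  Returns 0 when no
    positive-scoring alignment exists.
    """
    if not query_aa:
        raise ValueError("empty query")
    S = _query_scores(query_aa, pssm)
    n, m = S.shape
    NEG = -1e18
    H = np.zeros(m + 1)
    E = np.full(m + 1, NEG)  # gap in query (profile columns consumed)
    best = 0.0
    for i in range(1, n + 1):
        prev = H.copy()
        F = NEG  # gap in profile (query residues consumed)
        H[0] = 0.0
        for j in range(1, m + 1):
            E[j] = max(E[j] - gap_extend, prev[j] - gap_open - gap_extend)
            F = max(F - gap_extend, H[j - 1] - gap_open - gap_extend)
            H[j] = max(0.0, prev[j - 1] + S[i - 1, j - 1], E[j], F)
            if H[j] > best:
                best = H[j]
    return float(best)


def lineage_placement(
    candidate_family,
    ref_A_rt: str,
    ref_D_rt: str,
    pseudocount: float = 1.0,
    tie_epsilon: float = 2.0,
) -> LineagePlacement:
    """Place a candidate RT family relative to the lineage A/D references.

    The candidate family (one or more aligned or unaligned equal-length RT
    sequences) forms the PSSM; each reference is scored against it.  The
    call is the higher-scoring reference unless the two scores are within
    ``tie_epsilon`` half-bits, in which case the placement is ambiguous.
    """
    pssm = build_pssm(candidate_family, pseudocount=pseudocount)
    score_a = score_against_pssm(ref_A_rt, pssm)
    score_d = score_against_pssm(ref_D_rt, pssm)
    margin = abs(score_a - score_d)
    if margin < tie_epsilon:
        call = "ambiguous"
    elif score_a > score_d:
        call = "A"
    else:
        call = "D"
    return LineagePlacement(score_vs_A=score_a, score_vs_D=score_d, call=call, margin=margin)


# ---------------------------------------------------------------------------
# Discrete-gamma site rates under the 20-state equal-rates model
# ---------------------------------------------------------------------------


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean rate of each of K equal-probability gamma(alpha, alpha) bins.

    The gamma prior has mean 1; the category rate is the conditional mean
    of the distribution within each quantile bin, so the categories always
    average to exactly 1.
    """
    edges = special.gammaincinv(alpha, np.linspace(0.0, 1.0, K + 1)) / alpha
    # E[X ; X <= q] for Gamma(alpha, rate=alpha) equals gammainc(alpha+1, alpha*q)
    cum = special.gammainc(alpha + 1.0, alpha * edges)
    cum[-1] = 1.0
    return K * np.diff(cum)


class _TreeArrays:
    """Postorder flattening of a dendropy tree for vectorised pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.postorder = []
        self.children: dict[int, list[tuple[int, float]]] = {}
        self.leaf_taxon: dict[int, str] = {}
        for idx, node in enumerate(tree.postorder_node_iter()):
            node._r2idx = idx
            self.postorder.append(node)
            if node.is_leaf():
                self.leaf_taxon[idx] = node.taxon.label
            else:
                self.children[idx] = [
                    (ch._r2idx, max(ch.edge.length or 0.0, 0.0))
                    for ch in node.child_nodes()
                ]
        self.root = len(self.postorder) - 1


def _leaf_partials(seqs: dict[str, str], taxa_needed) -> dict[str, np.ndarray]:
    out = {}
    for taxon in taxa_needed:
        seq = seqs[taxon].upper()
        arr = np.ones((len(seq), N_STATES))
        for s, c in enumerate(seq):
            j = _AA_INDEX.get(c)
            if j is not None:
                arr[s] = 0.0
                arr[s, j] = 1.0
            # gaps and ambiguity stay as all-ones (missing data)
        out[taxon] = arr
    return out


def _site_likelihoods(arrays: _TreeArrays, partials: dict[str, np.ndarray], rate: float, n_sites: int):
    """Per-site likelihood at one rate via the pruning recursion.

    The equal-rates transition matrix has the spectral form
    ``P(t) = e^(-Lt) I + (1 - e^(-Lt)) J/20`` which turns the per-branch
    message into one exponential and one row-sum: no matrix products needed.
    """
    node_partial: dict[int, np.ndarray] = {}
    scale_log = np.zeros(n_sites)
    for idx, node in enumerate(arrays.postorder):
        if idx in arrays.leaf_taxon:
            node_partial[idx] = partials[arrays.leaf_taxon[idx]]
            continue
        acc = np.ones((n_sites, N_STATES))
        for child_idx, blen in arrays.children[idx]:
            p = node_partial.pop(child_idx)
            decay = np.exp(-_LAMBDA * blen * rate)
            msg = decay * p + (1.0 - decay) * p.sum(axis=1, keepdims=True) / N_STATES
            acc *= msg
        # rescale to avoid underflow on deep trees
        m = acc.max(axis=1)
        m[m == 0.0] = 1.0
        acc /= m[:, None]
        scale_log += np.log(m)
        node_partial[idx] = acc
    root = node_partial[arrays.root]
    return root.mean(axis=1), scale_log  # uniform 1/20 root prior


def _category_site_likelihoods(arrays, partials, rates, n_sites):
    Ls = np.empty((len(rates), n_sites))
    logs = np.empty((len(rates), n_sites))
    for k, r in enumerate(rates):
        Ls[k], logs[k] = _site_likelihoods(arrays, partials, r, n_sites)
    return Ls, logs


def site_rates(msa, tree, K: int = 4, alpha_bounds=(0.05, 20.0), n_bins: int = 6) -> SiteRates:
    """Posterior-mean per-column rates with ML gamma shape.

    Parameters
    ----------
    msa
        Aligned sequences (Msa, mapping, or (id, seq) pairs); tree leaves
        must be a subset of the alignment taxa.
    tree
        Newick string, path-like handled by the caller, or a dendropy Tree.
    K
        Number of equal-probability gamma rate categories.
    n_bins
        Number of equal-frequency rate bins for reporting (bin 1 = most
        conserved).

    All-gap columns get NaN rate and bin 0 and are excluded from the
    bin quantiles.
    """
    pairs = dict(_pairs(msa))
    if isinstance(tree, dendropy.Tree):
        dtree = tree
    else:
        dtree = dendropy.Tree.get(data=str(tree), schema="newick", preserve_underscores=True)
    arrays = _TreeArrays(dtree)
    taxa = list(arrays.leaf_taxon.values())
    missing = [t for t in taxa if t not in pairs]
    if missing:
        raise ValueError(f"tree taxa absent from alignment: {missing}")
    n_sites = len(next(iter(pairs.values())))
    partials = _leaf_partials(pairs, taxa)

    informative = np.array(
        [
            any(pairs[t][s] in _AA_INDEX for t in taxa)
            for s in range(n_sites)
        ]
    )

    def neg_loglik(alpha: float) -> float:
        rates = discrete_gamma_rates(alpha, K)
        Ls, logs = _category_site_likelihoods(arrays, partials, rates, n_sites)
        site_l = np.log(np.mean(Ls * np.exp(logs - logs.max(axis=0)), axis=0)) + logs.max(axis=0)
        return -float(site_l[informative].sum())

    opt = minimize_scalar(neg_loglik, bounds=alpha_bounds, method="bounded")
    alpha_hat = float(opt.x)

    rates = discrete_gamma_rates(alpha_hat, K)
    Ls, logs = _category_site_likelihoods(arrays, partials, rates, n_sites)
    w = Ls * np.exp(logs - logs.max(axis=0))
    denom = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = (rates[:, None] * w).sum(axis=0) / denom
    post[~informative] = np.nan

    bins = np.zeros(n_sites, dtype=int)
    idx = np.nonzero(informative)[0]
    order = idx[np.argsort(post[idx], kind="stable")]
    splits = np.array_split(order, n_bins)
    for b, cols in enumerate(splits, start=1):
        bins[cols] = b
    return SiteRates(
        alpha_hat=alpha_hat,
        posterior_mean=post,
        bins=bins,
        log_likelihood=-float(opt.fun),
    )


# ---------------------------------------------------------------------------
# Plain-text PSSM interchange
# ---------------------------------------------------------------------------


def save_pssm(pssm: Pssm, path) -> None:
    """Write a PSSM as TSV: header row of residues, one row per column."""
    with open(path, "w") as fh:
        fh.write("# half-bit log-odds PSSM\n")
        fh.write(f"# pseudocount\t{pssm.pseudocount}\n")
        fh.write("# background\t" + "\t".join(f"{b:.6g}" for b in pssm.background) + "\n")
        fh.write("pos\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, row in enumerate(pssm.scores):
            fh.write(str(i) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def load_pssm(path) -> Pssm:
    pseudocount = 1.0
    background = np.full(N_STATES, 1.0 / N_STATES)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif not line or line.startswith("#") or line.startswith("pos\t"):
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    return Pssm(
        scores=np.array(rows), background=background, pseudocount=pseudocount
    )
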