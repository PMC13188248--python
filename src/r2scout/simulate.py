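"""Synthetic genomes, elements, reads, and tree-evolved alignments.

This module generates the ground-truth worlds the rest of the toolkit is
tested against: tandem rDNA arrays whose 28S-like segment carries an
annotated canonical nick position; R2-like elements assembled from the
shipped domain templates (full-length, 5'-truncated, or inserted offset
from the nick site); Myb-less Utopia-like elements at a U2-like locus;
non-site-specific Myb-bearing homologs in random sequence; sequencing reads
with substitution/indel error; and amino-acid alignments evolved along a
tree under the 20-state equal-rates model.

Every operation is deterministic given its inputs and a single integer
seed; per-element randomness is derived with ``numpy.random.SeedSequence``
so no global RNG state is involved.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import motifs

__all__ = [
    "RdnaReference",
    "ElementSpec",
    "ReadParams",
    "make_reference_rdna",
    "make_element",
    "build_genome_and_truth",
    "simulate_reads",
    "evolve_on_tree",
    "draw_gamma_rates",
    "write_fastq",
    "write_fasta",
]

NT = np.array(list("ACGT"))
# Linker residues avoid C and H so synthetic linkers can never satisfy the
# zinc-finger grammar; W is kept since Myb detection is profile-based.
LINKER_AA = "ADEFGIKLMNPQRSTVWY"

ARCH_LABELS = ("A", "B", "C", "D", "D+Myb2", "4ZnF", "no-Myb")

# N->C finger composition per architecture as (assigned number, pair type)
_ARCH_FINGERS: dict[str, list[tuple[int, str]]] = {
    "A": [(3, "CCHH"), (2, "CCHC"), (1, "CCHH")],
    "B": [(2, "CCHC"), (1, "CCHH")],
    "C": [(3, "CCHH"), (1, "CCHH")],
    "D": [(1, "CCHH")],
    "D+Myb2": [(1, "CCHH")],
    "4ZnF": [(4, "CCHH"), (3, "CCHH"), (2, "CCHC"), (1, "CCHH")],
    "no-Myb": [(2, "CCHH"), (1, "CCHH")],
}

DEFAULT_UNIT_LAYOUT = (("18S-like", 900), ("ITS-like", 300), ("28S-like", 2400))
DEFAULT_NICK_POS = 1200


@dataclass(frozen=True)
class RdnaReference:
    """A 28S rDNA stand-in with its canonical first-strand nick position.

    ``seq`` is the 28S-like segment only; ``unit_seq`` is one full rDNA
    unit (all layout segments concatenated) and ``unit_28s_offset`` is where
    the 28S-like segment starts within it.
    """

    seq: str
    nick_pos: int  # 0-based offset into seq
    unit_layout: tuple[tuple[str, int], ...]
    unit_seq: str
    unit_28s_offset: int

    def __post_init__(self):
        if not (0 < self.nick_pos < len(self.seq)):
            raise ValueError("nick_pos must lie strictly inside the 28S segment")

    @property
    def nick_unit_pos(self) -> int:
        """Nick position in full-unit coordinates."""
        return self.unit_28s_offset + self.nick_pos


def _rng(seed, *key: int) -> np.random.Generator:
    if int(seed) < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def make_reference_rdna(
    seed: int,
    unit_layout=DEFAULT_UNIT_LAYOUT,
    nick_pos: int = DEFAULT_NICK_POS,
) -> RdnaReference:
    """Generate one rDNA unit and annotate the canonical nick in its
    28S-like segment.  Deterministic for a fixed seed."""
    layout = tuple((str(label), int(length)) for label, length in unit_layout)
    if any(length <= 0 for _, length in layout):
        raise ValueError("all unit segment lengths must be > 0")
    labels_28s = [label for label, _ in layout if "28S" in label]
    if len(labels_28s) != 1:
        raise ValueError("unit_layout must contain exactly one 28S-like segment")
    rng = _rng(seed, 0)
    segments = {label: _random_nt(rng, length) for label, length in layout}
    seq28 = segments[labels_28s[0]]
    if not (0 < nick_pos < len(seq28)):
        raise ValueError(
            f"nick_pos {nick_pos} outside the 28S-like segment (length {len(seq28)})"
        )
    offset = 0
    for label, length in layout:
        if label == labels_28s[0]:
            break
        offset += length
    return RdnaReference(
        seq=seq28,
        nick_pos=nick_pos,
        unit_layout=layout,
        unit_seq="".join(segments[label] for label, _ in layout),
        unit_28s_offset=offset,
    )


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one synthetic element.

    ``insertion_offset`` is in nt relative to the canonical nick (negative =
    upstream); ``truncate5_nt`` removes that many nt from the element 5' end
    before insertion (the typical TPRT degradation mode).  Elements sharing
    a ``family`` name are byte-identical copies, as real rDNA-embedded R2
    copies within a genome nearly are.
    """

    arch_label: str = "D"
    znf_variants: dict = field(default_factory=dict)  # finger number -> variant
    lineage: str = "D"
    orf_len_aa: int = 1000
    utr5_len: int = 300
    utr3_len: int = 250
    insertion_offset: int = 0
    truncate5_nt: int = 0
    placement: str = "rdna"  # rdna | u2 | random
    family: str | None = None

    def __post_init__(self):
        if self.arch_label not in ARCH_LABELS:
            raise ValueError(f"arch_label must be one of {ARCH_LABELS}")
        if self.lineage not in ("A", "D"):
            raise ValueError("lineage must be 'A' or 'D'")
        if self.orf_len_aa < 0 or self.truncate5_nt < 0:
            raise ValueError("lengths must be non-negative")
        if self.utr5_len < 3 or self.utr3_len < 3:
            raise ValueError("UTRs must be at least 3 nt (room for a stop codon)")
        if self.placement not in ("rdna", "u2", "random"):
            raise ValueError("placement must be rdna, u2, or random")
        valid_numbers = {n for n, _ in _ARCH_FINGERS[self.arch_label]}
        bad = set(self.znf_variants) - valid_numbers
        if bad:
            raise ValueError(
                f"znf_variants keys {sorted(bad)} not in architecture {self.arch_label}"
            )

    @property
    def true_class(self) -> str:
        if self.arch_label == "no-Myb":
            return "Utopia-like"
        if self.placement == "rdna":
            return "R2-site-specific"
        return "R2-homolog-non-site-specific"


_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()


def _linker(rng: np.random.Generator, n: int) -> str:
    letters = np.array(list(LINKER_AA))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


def _build_protein(spec: ElementSpec, rng: np.random.Generator) -> str:
    parts: list[str] = [_linker(rng, 10)]
    fingers = _ARCH_FINGERS[spec.arch_label]
    for i, (number, pair_type) in enumerate(fingers):
        variant = spec.znf_variants.get(number, "CxxC")
        parts.append(motifs.znf_template(pair_type, variant))
        if i < len(fingers) - 1:
            parts.append(motifs.inter_znf_linker())
    if spec.arch_label != "no-Myb":
        parts.append(_linker(rng, 6))
        parts.append(motifs.myb_template())
        if spec.arch_label == "D+Myb2":
            parts.append(_linker(rng, 6))
            parts.append(motifs.myb_template())
    parts.append(_linker(rng, 8))
    parts.append(motifs.rt_domain_consensus(spec.lineage))
    parts.append(_linker(rng, 6))
    parts.append(motifs.rle_template())
    parts.append(_linker(rng, 6))
    parts.append(motifs.knuckle_template())
    core = "".join(parts)
    if spec.orf_len_aa < len(core):
        raise ValueError(
            f"orf_len_aa={spec.orf_len_aa} smaller than the template total {len(core)}"
        )
    return core + _linker(rng, spec.orf_len_aa - len(core))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        codons = _AA_TO_CODONS[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def make_element(spec: ElementSpec, seed: int) -> tuple[str, str]:
    """Build one element: the encoded protein and its nucleotide sequence.

    The protein concatenates domain templates in N->C order (ZnFs, Myb(s),
    RT motifs 0-7 with lineage-specific linkers, RLE, thumb-zinc-knuckle)
    padded with random linkers to ``orf_len_aa``; there is no initiator
    methionine requirement.  The nucleotide sequence is a randomised
    synonymous-codon reverse translation flanked by UTRs, with in-frame
    stop codons placed immediately outside the ORF so that the ORF is a
    maximal stop-free stretch of exactly ``orf_len_aa`` codons.
    """
    rng = _rng(seed, 1)
    protein = _build_protein(spec, rng)
    orf_nt = _reverse_translate(protein, rng)
    utr5 = _random_nt(rng, spec.utr5_len - 3) + "TAA"
    utr3 = "TAA" + _random_nt(rng, spec.utr3_len - 3)
    return protein, utr5 + orf_nt + utr3


def _element_seed(base_seed: int, spec: ElementSpec, index: int) -> int:
    """Per-element seed; elements in the same family share a sequence."""
    if spec.family is not None:
        h = zlib.crc32(spec.family.encode()) % (2**31)
        return (int(base_seed) * 2654435761 + h) % (2**31)
    return (int(base_seed) * 2654435761 + 7919 * (index + 1)) % (2**31)


def build_genome_and_truth(
    specs: list[ElementSpec],
    n_rdna_units: int,
    seed: int,
    rdna: RdnaReference | None = None,
    misassemble: bool = False,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Assemble contigs with embedded elements and the matching truth table.

    Site-specific specs (placement ``rdna``) are inserted at
    ``nick_pos + insertion_offset`` of distinct units of one tandem array;
    Utopia-like specs land at their own U2-like locus contig; ``random``
    placements land in random non-rDNA contigs.  With ``misassemble`` the
    last rDNA element is split across two contigs with chimeric junctions,
    emulating a collapsed assembly.

    Coordinates in the truth table are 0-based half-open on the forward
    strand; extracting ``[start, end)`` from the contig reproduces the
    (possibly truncated) element sequence exactly.
    """
    rdna = rdna or make_reference_rdna(seed)
    rdna_specs = [s for s in specs if s.placement == "rdna" and s.arch_label != "no-Myb"]
    u2_specs = [s for s in specs if s.arch_label == "no-Myb"]
    random_specs = [
        s for s in specs if s.placement == "random" and s.arch_label != "no-Myb"
    ]
    if len(rdna_specs) > n_rdna_units:
        raise ValueError(
            f"{len(rdna_specs)} site-specific elements exceed {n_rdna_units} rDNA units"
        )
    rng = _rng(seed, 2)
    rows = []
    contigs: dict[str, str] = {}

    def element_for(spec: ElementSpec, index: int) -> tuple[str, str, int]:
        eseed = _element_seed(seed, spec, index)
        _, element_nt = make_element(spec, eseed)
        return element_nt, element_nt[spec.truncate5_nt :], eseed

    # --- tandem rDNA array, elements in distinct units ---
    occupied = sorted(
        rng.choice(n_rdna_units, size=len(rdna_specs), replace=False).tolist()
    )
    spec_by_unit = dict(zip(occupied, rdna_specs))
    array_parts: list[str] = []
    pos = 0
    eid = 0
    for unit_idx in range(n_rdna_units):
        unit = rdna.unit_seq
        if unit_idx in spec_by_unit:
            spec = spec_by_unit[unit_idx]
            full_nt, placed_nt, eseed = element_for(spec, eid)
            site = rdna.nick_unit_pos + spec.insertion_offset
            array_parts.append(unit[:site])
            start = pos + site
            if spec.truncate5_nt > 0:
                # a 5'-truncated copy has lost its upstream junction; model
                # the broken boundary as non-rDNA junk
                junk = _random_nt(rng, 400)
                array_parts.append(junk)
                start += len(junk)
                pos += len(junk)
            array_parts.append(placed_nt)
            array_parts.append(unit[site:])
            rows.append(
                dict(
                    contig_id="rdna_array",
                    start=start,
                    end=start + len(placed_nt),
                    strand="+",
                    element_id=f"e{eid:03d}",
                    arch_label=spec.arch_label,
                    lineage=spec.lineage,
                    insertion_offset=spec.insertion_offset,
                    truncate5_nt=spec.truncate5_nt,
                    placement=spec.placement,
                    true_class=spec.true_class,
                    full_length_nt=len(full_nt),
                    element_seed=eseed,
                    part="all",
                )
            )
            pos += len(unit) + len(placed_nt)
        else:
            array_parts.append(unit)
            pos += len(unit)
        eid += 1 if unit_idx in spec_by_unit else 0
    contigs["rdna_array"] = "".join(array_parts)

    # --- U2-like locus contigs for Myb-less (Utopia-like) elements ---
    for k, spec in enumerate(u2_specs):
        full_nt, placed_nt, eseed = element_for(spec, eid)
        left = _random_nt(rng, 1500)
        right = _random_nt(rng, 1500)
        cid = f"u2_locus_{k}"
        contigs[cid] = left + placed_nt + right
        rows.append(
            dict(
                contig_id=cid,
                start=len(left),
                end=len(left) + len(placed_nt),
                strand="+",
                element_id=f"e{eid:03d}",
                arch_label=spec.arch_label,
                lineage=spec.lineage,
                insertion_offset=spec.insertion_offset,
                truncate5_nt=spec.truncate5_nt,
                placement="u2",
                true_class=spec.true_class,
                full_length_nt=len(full_nt),
                element_seed=eseed,
                part="all",
            )
        )
        eid += 1

    # --- non-site-specific homologs in random sequence ---
    for k, spec in enumerate(random_specs):
        full_nt, placed_nt, eseed = element_for(spec, eid)
        left = _random_nt(rng, 1000 + int(rng.integers(0, 1000)))
        right = _random_nt(rng, 1000 + int(rng.integers(0, 1000)))
        cid = f"floating_{k}"
        contigs[cid] = left + placed_nt + right
        rows.append(
            dict(
                contig_id=cid,
                start=len(left),
                end=len(left) + len(placed_nt),
                strand="+",
                element_id=f"e{eid:03d}",
                arch_label=spec.arch_label,
                lineage=spec.lineage,
                insertion_offset=spec.insertion_offset,
                truncate5_nt=spec.truncate5_nt,
                placement="random",
                true_class=spec.true_class,
                full_length_nt=len(full_nt),
                element_seed=eseed,
                part="all",
            )
        )
        eid += 1

    truth = pd.DataFrame(rows)

    if misassemble and len(truth) and (truth.contig_id == "rdna_array").any():
        contigs, truth = _split_misassembled(contigs, truth, rng)

    # round-trip consistency guard
    for row in truth.itertuples():
        assert 0 <= row.start < row.end <= len(contigs[row.contig_id])
    return contigs, truth


def _split_misassembled(contigs, truth, rng):
    """Split the last rDNA-array element across two chimeric contigs."""
    arr = contigs["rdna_array"]
    target = truth[truth.contig_id == "rdna_array"].iloc[-1]
    mid = (int(target.start) + int(target.end)) // 2
    junk1 = _random_nt(rng, 200)
    junk2 = _random_nt(rng, 200)
    contigs = dict(contigs)
    contigs["rdna_array"] = arr[:mid] + junk1
    contigs["rdna_array_chim"] = junk2 + arr[mid:]
    rows = []
    for row in truth.to_dict("records"):
        if row["contig_id"] != "rdna_array":
            rows.append(row)
            continue
        if row["end"] <= mid:
            rows.append(row)
        elif row["start"] >= mid:
            row = dict(row, contig_id="rdna_array_chim", start=row["start"] - mid + 200, end=row["end"] - mid + 200)
            rows.append(row)
        else:
            five = dict(row, end=mid, part="5p", element_id=row["element_id"] + ".5p")
            three = dict(
                row,
                contig_id="rdna_array_chim",
                start=200,
                end=200 + row["end"] - mid,
                part="3p",
                element_id=row["element_id"] + ".3p",
            )
            rows.extend([five, three])
    return contigs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadParams:
    mode: str = "long"  # long | short
    n: int = 100
    mean_len: int = 5000
    sub_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.mode not in ("long", "short"):
            raise ValueError("mode must be 'long' or 'short'")
        if not (0.0 <= self.sub_rate <= 0.3 and 0.0 <= self.indel_rate <= 0.3):
            raise ValueError("error rates must lie in [0, 0.3]")
        if self.n <= 0 or self.mean_len <= 0:
            raise ValueError("n and mean_len must be positive")


def _apply_errors(seq: str, sub_rate: float, indel_rate: float, rng) -> str:
    out = []
    for base in seq:
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(NT[rng.integers(0, 4)]))  # insertion before the base
            out.append(base)
        elif r < indel_rate + sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out)


def simulate_reads(
    contigs: dict[str, str], params: ReadParams, seed: int
) -> list[tuple[str, str, str]]:
    """Sample reads uniformly over positions and strands.

    Returns (read_id, sequence, quality) tuples; read ids encode the true
    origin as ``read<i>|contig|start|end|strand``.  Quality is a constant
    Phred encoding of the requested error rate.
    """
    from .alignment import revcomp

    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError("empty contigs")
    max_len = max(len(s) for s in contigs.values())
    if params.mean_len > max_len:
        raise ValueError("mean_len exceeds the longest contig")
    rng = _rng(seed, 3)
    names = sorted(contigs)
    weights = np.array([len(contigs[n]) for n in names], dtype=float)
    weights /= weights.sum()
    err = params.sub_rate + params.indel_rate
    q = int(min(60, round(-10 * np.log10(max(err, 1e-6)))))
    qchar = chr(33 + q)
    reads = []
    for i in range(params.n):
        cid = names[rng.choice(len(names), p=weights)]
        seq = contigs[cid]
        if params.mode == "short":
            length = min(params.mean_len, len(seq))
        else:
            length = int(np.clip(rng.normal(params.mean_len, 0.15 * params.mean_len),
                                 50, len(seq)))
        start = int(rng.integers(0, len(seq) - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = seq[start:end]
        if strand == "-":
            fragment = revcomp(fragment)
        fragment = _apply_errors(fragment, params.sub_rate, params.indel_rate, rng)
        rid = f"read{i}|{cid}|{start}|{end}|{strand}"
        reads.append((rid, fragment, qchar * len(fragment)))
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Sequence evolution on a tree
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_LAMBDA = 20.0 / 19.0


def draw_gamma_rates(alpha: float, n_sites: int, seed: int) -> np.ndarray:
    """Continuous per-site rates from Gamma(alpha, rate=alpha) (mean 1)."""
    return _rng(seed, 4).gamma(alpha, 1.0 / alpha, size=n_sites)


def evolve_on_tree(root_aa: str, tree, site_rates=None, seed: int = 0) -> dict[str, str]:
    """Evolve a root protein along a tree under the 20-state equal-rates
    model; expected substitutions per site on a branch of length t at rate r
    is t*r.  No gaps are introduced, so the leaves come back aligned.

    ``site_rates`` may be a per-site vector, ``("gamma", alpha)`` to draw
    rates internally, or None for rate 1 everywhere.
    """
    if not root_aa:
        raise ValueError("root sequence must be non-empty")
    if isinstance(tree, dendropy.Tree):
        dtree = tree
    else:
        dtree = dendropy.Tree.get(data=str(tree), schema="newick", preserve_underscores=True)
    n = len(root_aa)
    if site_rates is None:
        rates = np.ones(n)
    elif isinstance(site_rates, tuple) and site_rates[0] == "gamma":
        rates = draw_gamma_rates(float(site_rates[1]), n, seed)
    else:
        rates = np.asarray(site_rates, dtype=float)
        if rates.shape != (n,):
            raise ValueError("site_rates length must match the root sequence")
    if (rates < 0).any():
        raise ValueError("site rates must be non-negative")
    idx = {a: i for i, a in enumerate(AA20)}
    try:
        root_states = np.array([idx[a] for a in root_aa.upper()])
    except KeyError as exc:
        raise ValueError(f"invalid amino acid {exc} in root sequence") from exc
    rng = _rng(seed, 5)
    states = {id(dtree.seed_node): root_states}
    leaves: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            current = states[id(node)]
        else:
            t = node.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            parent = states[id(node.parent_node)]
            p_diff = (19.0 / 20.0) * (1.0 - np.exp(-_LAMBDA * t * rates))
            mutate = rng.random(n) < p_diff
            current = parent.copy()
            if mutate.any():
                # uniform over the 19 other states
                shift = rng.integers(1, 20, size=int(mutate.sum()))
                current[mutate] = (current[mutate] + shift) % 20
            states[id(node)] = current
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(leaves)}"
            leaves[label] = "".join(AA20[s] for s in current)
    return leaves
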