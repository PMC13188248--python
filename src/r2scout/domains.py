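"""ORF extraction and N-terminal domain architecture of R2 proteins.

R2 ORFs are non-canonically translated and need not begin with a
methionine, so ORFs are maximal stop-free stretches in the three frames of
the element strand.  ORFs shorter than 900 aa (the shortest credible R2
protein) are kept separately as partials.

Zinc fingers are detected with a grammar over coordinating residues,
``C x(s) C x(8-14) H x(3-5) [H|C]`` with first-pair spacing s in {1,2,3}:
the final coordinating residue distinguishes CCHH (ZnF1/ZnF3-type) from
CCHC (the ZnF2 signature), and the first-pair spacing gives the CxC / CxxC
/ CxxxC variants, with the literal sequence C,P,C,C flagged as the avian
CPCC variant of CxxC.  ZnF numbering starts at the finger adjacent to the
Myb domain (ZnF1) and increases toward the N-terminus; fingers C-terminal
of the first Myb are never numbered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .motifs import Profile, default_profiles, scan_profile

__all__ = [
    "OrfRecord",
    "ZnfHit",
    "DomainArchitecture",
    "extract_orfs",
    "annotate_znf",
    "annotate_myb_and_aux",
    "annotate_rt_motifs",
    "classify_architecture",
    "trim_n_terminus",
    "annotate_protein",
]

MIN_FULL_ORF_AA = 900  # "full" means not shorter than the shortest known R2p


@dataclass
class OrfRecord:
    aa_seq: str
    nt_start: int  # 0-based half-open in the element, element strand
    nt_end: int
    frame: int  # 0, 1, or 2

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _CODON_TO_AA.get(codon, "X")  # any N -> X; X never matches motifs


def extract_orfs(
    element_nt: str,
    min_len_aa: int = MIN_FULL_ORF_AA,
    min_partial_len_aa: int = 30,
) -> tuple[list[OrfRecord], list[OrfRecord]]:
    """Maximal stop-free translations in the 3 frames of the element strand.

    Returns ``(full, partial)`` where full ORFs have length >= min_len_aa
    (the boundary is inclusive: a 900-aa ORF is full under the default) and
    partials are shorter stretches down to ``min_partial_len_aa``; anything
    below that is inter-stop noise, not an ORF record.  No start codon is
    required.  Codons containing N translate to X.
    """
    seq = element_nt.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in element sequence: {sorted(bad)}")
    if len(seq) < 3:
        raise ValueError("element sequence shorter than one codon")
    full: list[OrfRecord] = []
    partial: list[OrfRecord] = []
    for frame in range(3):
        aas = []
        for i in range(frame, len(seq) - 2, 3):
            aas.append(_translate_codon(seq[i : i + 3]))
        run_start = None
        aa_str = "".join(aas)
        for pos, aa in enumerate(aa_str + "*"):  # sentinel stop flushes the last run
            if aa == "*":
                if run_start is not None:
                    stretch = aa_str[run_start:pos]
                    rec = OrfRecord(
                        aa_seq=stretch,
                        nt_start=frame + 3 * run_start,
                        nt_end=frame + 3 * pos,
                        frame=frame,
                    )
                    if rec.length_aa >= min_len_aa:
                        full.append(rec)
                    elif rec.length_aa >= min_partial_len_aa:
                        partial.append(rec)
                    run_start = None
            elif run_start is None:
                run_start = pos
    return full, partial


# ---------------------------------------------------------------------------
# Zinc-finger grammar
# ---------------------------------------------------------------------------


@dataclass
class ZnfHit:
    start: int  # 0-based half-open aa coordinates
    end: int
    pair_type: str  # "CCHH" or "CCHC"
    first_pair_variant: str  # "CxC", "CxxC", "CxxxC"
    cpcc_flag: bool = False
    assigned_number: int | None = None


_VARIANT_BY_SPACING = {1: "CxC", 2: "CxxC", 3: "CxxxC"}


def _znf_candidates(aa: str) -> list[tuple[int, int, int, int, int, str]]:
    """All grammar matches as (start, s, g1, g2, end, final_residue)."""
    n = len(aa)
    out = []
    for i in range(n):
        if aa[i] != "C":
            continue
        for s in (1, 2, 3):
            j = i + 1 + s  # second C of the first pair
            if j >= n or aa[j] != "C":
                continue
            for g1 in range(8, 15):
                h = j + 1 + g1
                if h >= n or aa[h] != "H":
                    continue
                for g2 in range(3, 6):
                    k = h + 1 + g2
                    if k >= n or aa[k] not in "HC":
                        continue
                    out.append((i, s, g1, g2, k + 1, aa[k]))
    return out


def annotate_znf(aa: str) -> list[ZnfHit]:
    """Scan a protein with the zinc-finger grammar.

    Overlapping candidates are resolved greedily left-to-right; at the same
    start the longest first-pair spacing wins (so the literal C,P,C,C region
    parses as the CPCC variant of CxxC rather than as CxC), and among equal
    spacings the shortest overall match wins.
    """
    if not aa:
        raise ValueError("empty protein")
    aa = aa.upper()
    cands = _znf_candidates(aa)
    cands.sort(key=lambda c: (c[0], -c[1], c[4]))
    hits: list[ZnfHit] = []
    occupied_until = -1
    for start, s, _g1, _g2, end, final in cands:
        if start <= occupied_until:
            continue
        hits.append(
            ZnfHit(
                start=start,
                end=end,
                pair_type="CCHH" if final == "H" else "CCHC",
                first_pair_variant=_VARIANT_BY_SPACING[s],
                cpcc_flag=aa[start : start + 4] == "CPCC",
            )
        )
        occupied_until = end - 1
    return hits


# ---------------------------------------------------------------------------
# Profile-based motifs: Myb, RLE, knuckle, RT 0-7
# ---------------------------------------------------------------------------


def annotate_myb_and_aux(
    aa: str, profiles: dict[str, Profile] | None = None
) -> tuple[list[tuple[int, int, float]], tuple | None, tuple | None]:
    """Locate Myb (possibly duplicated), RLE, and thumb-zinc-knuckle hits.

    Returns ``(mybs, rle, knuckle)``; the latter two are the single best
    hit or None.  Two or more non-overlapping Myb hits indicate a Myb
    duplication (the Myb2 pattern seen in cyprinid fish R2s).
    """
    profiles = profiles or default_profiles()
    for key in ("myb", "rle", "knuckle"):
        if key not in profiles:
            raise KeyError(f"missing profile {key!r}")
    mybs = scan_profile(aa, profiles["myb"])
    rle_hits = scan_profile(aa, profiles["rle"])
    knuckle_hits = scan_profile(aa, profiles["knuckle"])
    rle = max(rle_hits, key=lambda h: h[2]) if rle_hits else None
    knuckle = max(knuckle_hits, key=lambda h: h[2]) if knuckle_hits else None
    return mybs, rle, knuckle


def annotate_rt_motifs(
    aa: str, profiles: dict[str, Profile] | None = None
) -> tuple[dict[int, tuple[int, int, float]], bool]:
    """Locate RT motifs 0-7 independently; ``intact`` requires all eight
    present in increasing coordinate order."""
    profiles = profiles or default_profiles()
    found: dict[int, tuple[int, int, float]] = {}
    for i in range(8):
        hits = scan_profile(aa, profiles[f"rt{i}"])
        if hits:
            found[i] = max(hits, key=lambda h: h[2])
    intact = len(found) == 8 and all(
        found[i][1] <= found[i + 1][0] for i in range(7)
    )
    return found, intact


# ---------------------------------------------------------------------------
# Architecture classification
# ---------------------------------------------------------------------------


@dataclass
class DomainArchitecture:
    znfs: list[ZnfHit] = field(default_factory=list)
    mybs: list[tuple[int, int, float]] = field(default_factory=list)
    rt_motifs: dict[int, tuple[int, int, float]] = field(default_factory=dict)
    rt_intact: bool = False
    rle: tuple | None = None
    knuckle: tuple | None = None
    label: str = "other"
    cofold_znf32_plausible: bool | None = None

    @property
    def has_myb(self) -> bool:
        return bool(self.mybs)


def classify_architecture(
    znfs: list[ZnfHit],
    mybs: list[tuple[int, int, float]],
    max_cofold_linker: int = 10,
    rt_motifs: dict | None = None,
    rt_intact: bool = False,
    rle: tuple | None = None,
    knuckle: tuple | None = None,
) -> DomainArchitecture:
    """Assign the architecture label from ZnF and Myb hits.

    Only ZnFs N-terminal to the first Myb are numbered, from the finger
    nearest the Myb (ZnF1) toward the N-terminus.  Labels: 3 ZnFs -> A,
    1 -> D (D+Myb2 with a duplicated Myb), 4 -> 4ZnF, 0 Mybs -> no-Myb;
    with exactly 2 ZnFs the retained finger's pair type disambiguates:
    a CCHC N-terminal finger means ZnF2 is present (label B), a CCHH one
    means ZnF3 (label C).  This is a sequence-evidence stand-in for the
    phylogenetic B/C assignment and is recorded as such in output metadata.

    ``cofold_znf32_plausible`` is a linker-length heuristic for the
    interdependently folded ZnF3:2 pair of lineage A proteins: plausible
    when both fingers are present and separated by at most
    ``max_cofold_linker`` residues.
    """
    arch = DomainArchitecture(
        znfs=list(znfs),
        mybs=list(mybs),
        rt_motifs=rt_motifs or {},
        rt_intact=rt_intact,
        rle=rle,
        knuckle=knuckle,
    )
    if not mybs:
        arch.label = "no-Myb"
        return arch
    first_myb_start = min(m[0] for m in mybs)
    numbered = [z for z in znfs if z.end <= first_myb_start]
    numbered.sort(key=lambda z: z.start)
    for rank, z in enumerate(reversed(numbered), start=1):
        z.assigned_number = rank if rank <= 4 else None
    count = len(numbered)
    n_myb = len(mybs)
    if count == 3:
        arch.label = "A"
    elif count == 1:
        arch.label = "D+Myb2" if n_myb >= 2 else "D"
    elif count == 4:
        arch.label = "4ZnF"
    elif count == 2:
        arch.label = "B" if numbered[0].pair_type == "CCHC" else "C"
    else:
        arch.label = "other"
    by_number = {z.assigned_number: z for z in numbered if z.assigned_number}
    if 2 in by_number and 3 in by_number:
        linker = by_number[2].start - by_number[3].end
        arch.cofold_znf32_plausible = linker <= max_cofold_linker
    else:
        arch.cofold_znf32_plausible = None
    return arch


def trim_n_terminus(aa: str, znfs: list[ZnfHit], margin: int = 10) -> str:
    """Trim a protein to ``margin`` residues N-terminal of the most
    N-terminal ZnF (clamped at the sequence start); identity with a warning
    when no ZnF was found."""
    if not znfs:
        warnings.warn("no ZnF hit; returning sequence untrimmed", stacklevel=2)
        return aa
    first = min(z.start for z in znfs)
    return aa[max(0, first - margin) :]


def annotate_protein(
    aa: str,
    profiles: dict[str, Profile] | None = None,
    max_cofold_linker: int = 10,
) -> DomainArchitecture:
    """Run all detectors and classify in one call."""
    znfs = annotate_znf(aa)
    mybs, rle, knuckle = annotate_myb_and_aux(aa, profiles)
    rt, intact = annotate_rt_motifs(aa, profiles)
    return classify_architecture(
        znfs,
        mybs,
        max_cofold_linker=max_cofold_linker,
        rt_motifs=rt,
        rt_intact=intact,
        rle=rle,
        knuckle=knuckle,
    )
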