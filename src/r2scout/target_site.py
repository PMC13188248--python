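"""28S target-site junction analysis and element classification.

R2 elements insert by target-primed reverse transcription at a conserved
nick in the 28S rRNA gene; completed insertions carry 28S sequence on both
flanks, while the typical degradation mode leaves a 5'-truncated copy with
only a 3' (downstream) 28S junction.  Junctions are located by locally
aligning the windows flanking a candidate to the 28S reference, and the
signed offset of the insertion point from the canonical nick is reported
(negative = upstream, the frame in which an 11-bp upstream insertion is
written as -11).  Offsets are always measured on the rDNA forward strand.

Element classes follow the Myb-hallmark rule: a Myb-bearing element at the
28S site is a site-specific R2; Myb-bearing with non-rDNA flanks is a
non-site-specific R2 homolog; a Myb-less element is Utopia-like.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import DEFAULT_NT, ScoringScheme, local_align
from .domains import DomainArchitecture
from .simulate import RdnaReference

__all__ = [
    "TargetSiteCall",
    "ELEMENT_CLASSES",
    "classify_junctions",
    "nick_offset",
    "classify_element",
]

ELEMENT_CLASSES = (
    "R2-site-specific",
    "R2-homolog-non-site-specific",
    "Utopia-like",
    "unclassified",
)

COMPLETENESS = ("full-length", "5prime-truncated", "3prime-truncated", "no-rdna-flanks")


@dataclass
class TargetSiteCall:
    up_flank_identity: float | None
    down_flank_identity: float | None
    up_junction_pos: int | None  # 0-based position in the 28S reference
    down_junction_pos: int | None
    completeness: str
    up_evaluable: bool = True
    down_evaluable: bool = True


def _flank_junction(
    flank: str,
    rdna_seq: str,
    side: str,
    min_identity: float,
    min_span: int,
    scheme: ScoringScheme,
) -> tuple[float | None, int | None]:
    """Identity and extrapolated 28S junction coordinate for one flank.

    For the upstream flank the junction is the 28S position abutting the
    element 5' end; alignment ends short of the window edge are
    extrapolated to it.
    """
    res = local_align(flank, rdna_seq, scheme)
    if res.empty:
        return None, None
    span = res.q_end - res.q_start
    if span < min_span or res.identity < min_identity:
        return res.identity, None
    if side == "up":
        junction = res.s_end + (len(flank) - res.q_end)
    else:
        junction = res.s_start - res.q_start
    return res.identity, junction


def classify_junctions(
    contig_seq: str,
    start: int,
    end: int,
    rdna: RdnaReference,
    window: int = 200,
    min_identity: float = 0.80,
    min_span: int = 50,
    scoring: ScoringScheme | None = None,
) -> TargetSiteCall:
    """Match the windows flanking ``[start, end)`` against the 28S
    reference and assign completeness.

    A flank matches when the local alignment covers at least ``min_span``
    of it at identity >= ``min_identity``.  A flank shorter than
    ``min_span`` (candidate at a contig edge) is unevaluable and treated
    as non-matching.  Both junctions -> full-length; downstream only ->
    5prime-truncated (the TPRT degradation mode); upstream only ->
    3prime-truncated; neither -> no-rdna-flanks.
    """
    if not (window >= min_span >= 20):
        raise ValueError("require window >= min_span >= 20")
    scheme = scoring or DEFAULT_NT
    up_seq = contig_seq[max(0, start - window) : start]
    down_seq = contig_seq[end : end + window]

    up_eval = len(up_seq) >= min_span
    down_eval = len(down_seq) >= min_span
    up_id = up_j = down_id = down_j = None
    if up_eval:
        up_id, up_j = _flank_junction(up_seq, rdna.seq, "up", min_identity, min_span, scheme)
    if down_eval:
        down_id, down_j = _flank_junction(
            down_seq, rdna.seq, "down", min_identity, min_span, scheme
        )
    if up_j is not None and down_j is not None:
        completeness = "full-length"
    elif down_j is not None:
        completeness = "5prime-truncated"
    elif up_j is not None:
        completeness = "3prime-truncated"
    else:
        completeness = "no-rdna-flanks"
    return TargetSiteCall(
        up_flank_identity=up_id,
        down_flank_identity=down_id,
        up_junction_pos=up_j,
        down_junction_pos=down_j,
        completeness=completeness,
        up_evaluable=up_eval,
        down_evaluable=down_eval,
    )


def nick_offset(call: TargetSiteCall, rdna: RdnaReference) -> int | None:
    """Signed offset of the insertion point from the canonical nick.

    Uses the 5' junction when defined, otherwise the 3' junction; negative
    means the element sits upstream of the canonical nick.  None when no
    junction was located.
    """
    if call.up_junction_pos is not None:
        return call.up_junction_pos - rdna.nick_pos
    if call.down_junction_pos is not None:
        return call.down_junction_pos - rdna.nick_pos
    return None


def classify_element(
    call: TargetSiteCall | None, arch: DomainArchitecture | None
) -> str:
    """Myb-hallmark classification.

    Myb present + rDNA flanks -> site-specific R2; Myb present without
    rDNA flanks -> non-site-specific R2 homolog; Myb absent -> Utopia-like;
    no usable ORF/architecture -> unclassified.
    """
    if arch is None:
        return "unclassified"
    if not arch.has_myb:
        return "Utopia-like"
    if call is not None and call.completeness in (
        "full-length",
        "5prime-truncated",
        "3prime-truncated",
    ):
        return "R2-site-specific"
    return "R2-homolog-non-site-specific"
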