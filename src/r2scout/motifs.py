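"""Shipped motif templates and profile construction.

Templates are synthetic consensus sequences for the R2 protein domain
vocabulary: the four zinc-finger spacing variants (CxC / CxxC / CxxxC /
CPCC, each as CCHH or CCHC), the Myb helix-turn-helix, the eight ordered RT
motifs (0-7), the restriction-enzyme-like endonuclease (RLE), and the
C-terminal thumb-zinc-knuckle block.  They live in an editable JSON data
file; outside the zinc-coordinating positions every template avoids C and H
so the zinc-finger grammar never fires inside another domain.

Profiles are half-bit log-odds PSSMs derived from each template, with a
detection threshold expressed as a fraction of the profile's maximum
attainable score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

import numpy as np

from .lineage import AA_ALPHABET, Pssm, build_pssm

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

PAIR_TYPES = ("CCHH", "CCHC")
FIRST_PAIR_VARIANTS = ("CxC", "CxxC", "CxxxC", "CPCC")
RT_MOTIF_COUNT = 8
LINEAGES = ("A", "D")


@lru_cache(maxsize=1)
def templates() -> dict:
    raw = files("r2scout.data").joinpath("motif_templates.json").read_text()
    return json.loads(raw)


def znf_template(pair_type: str = "CCHH", first_pair: str = "CxxC") -> str:
    """Concrete zinc-finger template: C-x(s)-C ... H-x(3)-[H|C]."""
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"pair_type must be one of {PAIR_TYPES}")
    if first_pair not in FIRST_PAIR_VARIANTS:
        raise ValueError(f"first_pair must be one of {FIRST_PAIR_VARIANTS}")
    t = templates()["znf"]
    final = "H" if pair_type == "CCHH" else "C"
    return t["first_pair"][first_pair] + t["mid"] + "H" + t["tail"] + final


def myb_template() -> str:
    return templates()["myb"]


def rle_template() -> str:
    return templates()["rle"]


def knuckle_template() -> str:
    return templates()["knuckle"]


def rt_motif_templates() -> list[str]:
    return list(templates()["rt_motifs"])


def inter_znf_linker() -> str:
    return templates()["inter_znf_linker"]


def rt_domain_consensus(lineage_label: str) -> str:
    """RT-domain consensus for one lineage: motifs 0-7 joined by
    lineage-specific linkers.  The motif blocks are shared between lineages;
    the linkers diverge, which is what the PSSM placement keys on."""
    if lineage_label not in LINEAGES:
        raise ValueError(f"lineage must be one of {LINEAGES}")
    motifs = rt_motif_templates()
    linkers = templates()["rt_linkers"][lineage_label]
    parts = []
    for i, m in enumerate(motifs):
        parts.append(m)
        if i < len(linkers):
            parts.append(linkers[i])
    return "".join(parts)


@dataclass
class Profile:
    """A PSSM plus an absolute detection threshold in half-bits."""

    name: str
    pssm: Pssm
    threshold: float

    @property
    def length(self) -> int:
        return self.pssm.length


def profile_from_template(name: str, template: str, threshold_fraction: float) -> Profile:
    """Build a detection profile from a single consensus string.

    The PSSM is built as if from ten identical observations with
    pseudocount 1 and uniform background, giving ~+8 half-bits per matching
    consensus residue and ~-7 per mismatch; the threshold is a fraction of
    the profile's maximum score.
    """
    pssm = build_pssm([("t", template)] * 10, pseudocount=1.0)
    return Profile(name=name, pssm=pssm, threshold=threshold_fraction * pssm.max_score())


@lru_cache(maxsize=1)
def default_profiles() -> dict[str, Profile]:
    """Profiles for Myb, RLE, thumb-zinc-knuckle, and RT motifs rt0..rt7."""
    t = templates()
    frac = t["threshold_fraction"]
    out = {
        "myb": profile_from_template("myb", t["myb"], frac["myb"]),
        "rle": profile_from_template("rle", t["rle"], frac["rle"]),
        "knuckle": profile_from_template("knuckle", t["knuckle"], frac["knuckle"]),
    }
    for i, m in enumerate(t["rt_motifs"]):
        out[f"rt{i}"] = profile_from_template(f"rt{i}", m, frac["rt"])
    return out


_NO_MATCH = -1e4  # residues outside the 20-letter alphabet never satisfy a motif


def scan_profile(aa: str, profile: Profile) -> list[tuple[int, int, float]]:
    """Slide a profile over a protein; report non-overlapping windows
    scoring at or above the threshold, best-score-first greedy selection.

    Returns (start, end, score) tuples in N->C order.
    """
    L = profile.length
    n = len(aa)
    if n < L:
        return []
    idx = np.array([_AA_INDEX.get(c, -1) for c in aa.upper()])
    # Windowed sum: for each offset j within the profile add the score of
    # the residue at window_start + j.
    per_pos = np.full((n, L), _NO_MATCH)
    valid = idx >= 0
    per_pos[valid] = profile.pssm.scores[:, idx[valid]].T
    n_windows = n - L + 1
    window_scores = np.zeros(n_windows)
    for j in range(L):
        window_scores += per_pos[j : j + n_windows, j]
    hits = []
    taken = np.zeros(n_windows, dtype=bool)
    for w in np.argsort(window_scores, kind="stable")[::-1]:
        if window_scores[w] < profile.threshold:
            break
        if taken[max(0, w - L + 1) : w + L].any():
            continue
        taken[w] = True
        hits.append((int(w), int(w + L), float(window_scores[w])))
    hits.sort()
    return hits
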