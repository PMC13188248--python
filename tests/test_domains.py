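"""ORF extraction, the zinc-finger grammar (vs an independent regex
oracle), profile motif detection, architecture labels, and trimming."""

import re
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from r2scout import motifs, simulate as sim
from r2scout.domains import (
    ZnfHit,
    annotate_myb_and_aux,
    annotate_rt_motifs,
    annotate_znf,
    classify_architecture,
    extract_orfs,
    trim_n_terminus,
)

LINKER = "".join(
    np.random.default_rng(0).choice(list("ADEFGIKLMNPQRSTVWY"), 200)
)  # C/H-free filler


class TestExtractOrfs:
    def test_generator_roundtrip_single_full_orf(self, element_d):
        spec, prot, nt = element_d
        full, _ = extract_orfs(nt)
        assert len(full) == 1
        assert full[0].aa_seq == prot
        assert full[0].length_aa == 1000

    def test_900_boundary_is_inclusive(self):
        for length, expect_full in ((899, False), (900, True)):
            _, nt = sim.make_element(sim.ElementSpec(orf_len_aa=length), 3)
            full, partial = extract_orfs(nt)
            if expect_full:
                assert any(o.length_aa == length for o in full)
            else:
                assert not full
                assert any(o.length_aa == length for o in partial)

    def test_all_stops_everywhere_yields_nothing(self):
        full, partial = extract_orfs("TAATAATAATAA")
        assert full == [] and partial == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            extract_orfs("ACGTRY")

    def test_n_codons_translate_to_x_and_never_match_motifs(self):
        _, nt = sim.make_element(sim.ElementSpec(orf_len_aa=1000), 4)
        # corrupt 60 nt in the middle of the Myb-encoding region with N
        prot, _ = sim.make_element(sim.ElementSpec(orf_len_aa=1000), 4)
        mybs, _, _ = annotate_myb_and_aux(prot)
        myb_start_nt = 300 + 3 * mybs[0][0]
        corrupted = nt[:myb_start_nt] + "N" * 60 + nt[myb_start_nt + 60 :]
        full, partial = extract_orfs(corrupted)
        best = max(full + partial, key=lambda o: o.length_aa)
        assert "X" in best.aa_seq
        mybs2, _, _ = annotate_myb_and_aux(best.aa_seq)
        assert mybs2 == []


ZNF_RE = re.compile(
    r"(?=(C.{1,3}C.{8,14}H.{3,5}[HC]))"
)  # overlapping-match oracle, spacing checked separately


def oracle_znf_candidates(aa: str):
    """Independent enumeration of all grammar matches via regex lookahead."""
    out = []
    for s in (1, 2, 3):
        for g1 in range(8, 15):
            for g2 in range(3, 6):
                pat = re.compile(
                    rf"(?=(C.{{{s}}}C.{{{g1}}}H.{{{g2}}}[HC]))"
                )
                for m in pat.finditer(aa):
                    out.append((m.start(), s, g1, g2, m.start() + len(m.group(1))))
    return out


def oracle_znf(aa: str):
    cands = oracle_znf_candidates(aa)
    cands.sort(key=lambda c: (c[0], -c[1], c[4]))
    hits, occupied = [], -1
    for start, s, g1, g2, end in cands:
        if start <= occupied:
            continue
        hits.append((start, end, s, aa[end - 1]))
        occupied = end - 1
    return hits


class TestAnnotateZnf:
    def test_planted_cchh_cxxc(self):
        aa = LINKER[:10] + "CAECGKAFSRSDELTQHIRTH" + LINKER[10:20]
        hits = annotate_znf(aa)
        assert len(hits) == 1
        h = hits[0]
        assert (h.pair_type, h.first_pair_variant, h.cpcc_flag) == ("CCHH", "CxxC", False)

    def test_planted_cchc_signature(self):
        aa = LINKER[:10] + "CAECGKAFSRSDELTQHIRTC" + LINKER[10:20]
        (h,) = annotate_znf(aa)
        assert h.pair_type == "CCHC"

    def test_cpcc_parses_as_cxxc_variant_with_flag(self):
        aa = LINKER[:5] + "CPCCGKAFSRSDELTQHIRTH" + LINKER[5:15]
        (h,) = annotate_znf(aa)
        assert h.first_pair_variant == "CxxC" and h.cpcc_flag

    def test_motif_free_string_has_no_hits(self):
        assert annotate_znf(LINKER) == []

    @given(st.text(alphabet="CHPA", min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_agrees_with_regex_oracle(self, aa):
        mine = [(h.start, h.end) for h in annotate_znf(aa)]
        theirs = [(s, e) for s, e, _, _ in oracle_znf(aa)]
        assert mine == theirs


class TestProfileMotifs:
    def test_lineage_d_protein_has_one_myb(self, element_d):
        _, prot, _ = element_d
        mybs, rle, knuckle = annotate_myb_and_aux(prot)
        assert len(mybs) == 1 and rle and knuckle

    def test_myb_duplication_detected(self):
        prot, _ = sim.make_element(sim.ElementSpec(arch_label="D+Myb2"), 9)
        mybs, _, _ = annotate_myb_and_aux(prot)
        assert len(mybs) == 2

    def test_shuffled_protein_rarely_hits(self, element_d):
        _, prot, _ = element_d
        rng = np.random.default_rng(12)
        false_pos = 0
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(prot)))
            mybs, rle, knuckle = annotate_myb_and_aux(shuffled)
            if mybs or rle or knuckle:
                false_pos += 1
        assert false_pos <= 5

    def test_missing_profile_is_configuration_error(self, element_d):
        _, prot, _ = element_d
        with pytest.raises(KeyError):
            annotate_myb_and_aux(prot, profiles={"myb": None})


class TestRtMotifs:
    def test_intact_on_generator_protein(self, element_d):
        _, prot, _ = element_d
        found, intact = annotate_rt_motifs(prot)
        assert intact and sorted(found) == list(range(8))
        starts = [found[i][0] for i in range(8)]
        assert starts == sorted(starts)

    def test_deleted_motif_breaks_intactness(self):
        tmpl = motifs.templates()
        rt = "".join(
            m + l for m, l in zip(tmpl["rt_motifs"], tmpl["rt_linkers"]["D"] + [""])
        )
        rt_no5 = rt.replace(tmpl["rt_motifs"][5], LINKER[:12])
        found, intact = annotate_rt_motifs(LINKER[:30] + rt_no5 + LINKER[30:60])
        assert not intact
        assert 5 not in found

    def test_swapped_motif_order_breaks_intactness(self):
        tmpl = motifs.templates()
        ms = list(tmpl["rt_motifs"])
        ms[3], ms[4] = ms[4], ms[3]
        rt = "".join(m + l for m, l in zip(ms, tmpl["rt_linkers"]["D"] + [""]))
        found, intact = annotate_rt_motifs(LINKER[:30] + rt + LINKER[30:60])
        assert len(found) == 8
        assert not intact


def _znf(start, pair_type="CCHH"):
    return ZnfHit(start=start, end=start + 21, pair_type=pair_type,
                  first_pair_variant="CxxC")


class TestClassifyArchitecture:
    def test_three_fingers_plus_myb_is_a(self):
        arch = classify_architecture(
            [_znf(10), _znf(40, "CCHC"), _znf(70)], [(100, 124, 90.0)]
        )
        assert arch.label == "A"
        numbers = [z.assigned_number for z in arch.znfs]
        assert numbers == [3, 2, 1]

    def test_single_finger_is_d(self):
        arch = classify_architecture([_znf(10)], [(40, 64, 90.0)])
        assert arch.label == "D"

    def test_two_fingers_disambiguated_by_pair_type(self):
        b = classify_architecture([_znf(10, "CCHC"), _znf(40)], [(70, 94, 90.0)])
        c = classify_architecture([_znf(10, "CCHH"), _znf(40)], [(70, 94, 90.0)])
        assert (b.label, c.label) == ("B", "C")

    def test_myb_duplication_relabels_d(self):
        arch = classify_architecture([_znf(10)], [(40, 64, 90.0), (70, 94, 85.0)])
        assert arch.label == "D+Myb2"

    def test_no_myb_leaves_fingers_unnumbered(self):
        arch = classify_architecture([_znf(10), _znf(40)], [])
        assert arch.label == "no-Myb"
        assert all(z.assigned_number is None for z in arch.znfs)

    def test_fingers_after_myb_are_not_numbered(self):
        arch = classify_architecture([_znf(10), _znf(200)], [(50, 74, 90.0)])
        assert arch.label == "D"

    def test_cofold_heuristic_uses_linker_length(self):
        short = classify_architecture(
            [_znf(10), _znf(36, "CCHC"), _znf(70)], [(100, 124, 90.0)]
        )  # ZnF3 ends at 31, ZnF2 starts at 36: linker 5
        assert short.cofold_znf32_plausible is True
        long = classify_architecture(
            [_znf(10), _znf(60, "CCHC"), _znf(100)], [(130, 154, 90.0)]
        )  # linker 29
        assert long.cofold_znf32_plausible is False
        only_d = classify_architecture([_znf(10)], [(40, 64, 90.0)])
        assert only_d.cofold_znf32_plausible is None


class TestTrim:
    def test_trim_starts_ten_residues_before_first_finger(self):
        aa = LINKER[:50] + "CAECGKAFSRSDELTQHIRTH" + LINKER[50:100]
        znfs = annotate_znf(aa)
        trimmed = trim_n_terminus(aa, znfs)
        assert trimmed == aa[40:]

    def test_trim_clamps_at_sequence_start(self):
        aa = LINKER[:4] + "CAECGKAFSRSDELTQHIRTH" + LINKER[4:20]
        trimmed = trim_n_terminus(aa, annotate_znf(aa))
        assert trimmed == aa

    def test_no_finger_returns_input_with_warning(self):
        with pytest.warns(UserWarning):
            assert trim_n_terminus(LINKER, []) == LINKER

    @given(st.integers(0, 150))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_trim_output_is_suffix_no_longer_than_input(self, pos):
        aa = LINKER[: pos % 100] + "CAECGKAFSRSDELTQHIRTH" + LINKER[:50]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trimmed = trim_n_terminus(aa, annotate_znf(aa))
        assert aa.endswith(trimmed) and len(trimmed) <= len(aa)


class TestFullPanel:
    @pytest.mark.parametrize("arch_label", sim.ARCH_LABELS)
    @pytest.mark.parametrize("variant", ("CxC", "CxxC", "CxxxC", "CPCC"))
    def test_generator_labels_are_reproduced(self, arch_label, variant):
        from r2scout.domains import annotate_protein

        spec = sim.ElementSpec(
            arch_label=arch_label, znf_variants={1: variant}, orf_len_aa=1000
        )
        prot, _ = sim.make_element(spec, 21)
        arch = annotate_protein(prot)
        assert arch.label == arch_label
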