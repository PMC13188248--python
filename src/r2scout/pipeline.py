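"""End-to-end orchestration: discover -> target site -> domains -> lineage
-> phylogeny, plus the summary tables (architecture census, completeness
counts, lineage co-occurrence).

The pipeline is deterministic for a fixed config and seed; a JSON manifest
records the package version, all parameters, and SHA-256 checksums of the
inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, motifs
from .alignment import revcomp
from .discover import merge_loci, scan_genome
from .domains import annotate_protein, extract_orfs, trim_n_terminus
from .io import write_fasta, write_gff3
from .lineage import lineage_placement, site_rates
from .phylo import Clade, align_progressive, distance_matrix, neighbor_joining, rf_distance, trim_alignment
from .simulate import RdnaReference
from .target_site import classify_element, classify_junctions, nick_offset

__all__ = ["PipelineParams", "ResultBundle", "run", "summarize", "write_result_bundle"]


@dataclass(frozen=True)
class PipelineParams:
    """All stage parameters with defaults; unknown keys are rejected by
    :meth:`from_dict`."""

    seed: int = 0
    mode: str = "nucleotide"
    word_size: int | None = None
    min_score: float = 60.0
    merge_max_gap: int = 500
    flank_window: int = 200
    flank_min_identity: float = 0.80
    flank_min_span: int = 50
    min_full_orf_aa: int = 900
    min_classify_orf_aa: int = 200
    build_tree: bool = True
    bootstrap: int = 100
    tree_correction: str = "poisson"
    compute_rates: bool = True
    outgroup: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ResultBundle:
    elements: pd.DataFrame
    orfs: dict[str, str] = field(default_factory=dict)
    trimmed: dict[str, str] = field(default_factory=dict)
    tree: Clade | None = None
    rates: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


_ELEMENT_COLUMNS = [
    "element_id", "contig_id", "start", "end", "strand", "score",
    "completeness", "nick_offset", "element_class", "arch_label",
    "orf_len_aa", "rt_intact", "cofold_znf32_plausible",
    "lineage_call", "score_vs_A", "score_vs_D", "lineage_margin",
]


def _checksum(data: dict[str, str]) -> str:
    h = hashlib.sha256()
    for k in sorted(data):
        h.update(k.encode())
        h.update(data[k].encode())
    return h.hexdigest()


def run(
    contigs: dict[str, str],
    queries: dict[str, str],
    rdna: RdnaReference,
    params: PipelineParams | None = None,
    ref_rt_a: str | None = None,
    ref_rt_d: str | None = None,
    outgroup_protein: tuple[str, str] | None = None,
) -> ResultBundle:
    """Run every stage on in-memory inputs.

    Each discovered locus receives a target-site call, a domain
    architecture, an element class, and a lineage placement; elements with
    a Myb domain and a full-length ORF feed the NJ tree and the per-site
    rate track.  Lineage references default to the shipped A/D RT-domain
    consensi.
    """
    p = params or PipelineParams()
    ref_rt_a = ref_rt_a or motifs.rt_domain_consensus("A")
    ref_rt_d = ref_rt_d or motifs.rt_domain_consensus("D")

    hits = scan_genome(
        queries, contigs, mode=p.mode, k=p.word_size, min_score=p.min_score
    )
    loci = merge_loci(hits, max_gap=p.merge_max_gap)

    rows = []
    orfs: dict[str, str] = {}
    trimmed: dict[str, str] = {}
    for i, locus in enumerate(sorted(loci, key=lambda l: (l.contig_id, l.start))):
        eid = f"elem_{i:03d}"
        contig_seq = contigs[locus.contig_id]
        seq = contig_seq[locus.start : locus.end]
        if locus.strand == "-":
            seq = revcomp(seq)
        call = classify_junctions(
            contig_seq, locus.start, locus.end, rdna,
            window=p.flank_window,
            min_identity=p.flank_min_identity,
            min_span=p.flank_min_span,
        )
        offset = nick_offset(call, rdna)
        full, partial = extract_orfs(seq, min_len_aa=p.min_full_orf_aa)
        best = max(full, key=lambda o: o.length_aa) if full else (
            max(partial, key=lambda o: o.length_aa) if partial else None
        )
        arch = None
        placement = None
        if best is not None and best.length_aa >= p.min_classify_orf_aa:
            arch = annotate_protein(best.aa_seq)
            rt_region = best.aa_seq
            if arch.rt_intact:
                lo = arch.rt_motifs[0][0]
                hi = arch.rt_motifs[7][1]
                rt_region = best.aa_seq[lo:hi]
            placement = lineage_placement([(eid, rt_region)], ref_rt_a, ref_rt_d)
            orfs[eid] = best.aa_seq
            if arch.znfs:
                trimmed[eid] = trim_n_terminus(best.aa_seq, arch.znfs)
        element_class = classify_element(call, arch)
        rows.append(
            dict(
                element_id=eid,
                contig_id=locus.contig_id,
                start=locus.start,
                end=locus.end,
                strand=locus.strand,
                score=locus.best_score,
                completeness=call.completeness,
                nick_offset=offset,
                element_class=element_class,
                arch_label=arch.label if arch else None,
                orf_len_aa=best.length_aa if best else 0,
                rt_intact=arch.rt_intact if arch else False,
                cofold_znf32_plausible=arch.cofold_znf32_plausible if arch else None,
                lineage_call=placement.call if placement else None,
                score_vs_A=placement.score_vs_A if placement else None,
                score_vs_D=placement.score_vs_D if placement else None,
                lineage_margin=placement.margin if placement else None,
            )
        )
    elements = pd.DataFrame(rows, columns=_ELEMENT_COLUMNS)

    tree = None
    rates = None
    tree_input = {
        r["element_id"]: trimmed.get(r["element_id"], orfs.get(r["element_id"]))
        for r in rows
        if r["element_class"].startswith("R2")
        and r["orf_len_aa"] >= p.min_full_orf_aa
        and r["element_id"] in orfs
    }
    if outgroup_protein is not None:
        tree_input[outgroup_protein[0]] = outgroup_protein[1]
    if p.build_tree and len(tree_input) >= 3:
        msa = align_progressive(tree_input)
        msa, _dropped = trim_alignment(msa)
        dist = distance_matrix(msa, p.tree_correction)
        boot = (
            {"msa": msa, "B": p.bootstrap, "seed": p.seed, "correction": p.tree_correction}
            if p.bootstrap
            else None
        )
        outgroup = p.outgroup or (outgroup_protein[0] if outgroup_protein else None)
        tree = neighbor_joining(dist, outgroup=outgroup, bootstrap=boot)
        if p.compute_rates and len(tree_input) >= 4:
            sr = site_rates(msa, tree.to_newick())
            rates = pd.DataFrame(
                {
                    "column": range(msa.n_columns),
                    "posterior_mean": sr.posterior_mean,
                    "bin": sr.bins,
                }
            )
            rates.attrs["alpha_hat"] = sr.alpha_hat

    manifest = {
        "package": "r2scout",
        "version": __version__,
        "params": asdict(p),
        "input_checksums": {
            "contigs": _checksum(contigs),
            "queries": _checksum(queries),
            "rdna": hashlib.sha256(rdna.unit_seq.encode()).hexdigest(),
        },
        "tree_method": "neighbor joining on poisson-corrected distances "
                       "(distance-based, not maximum likelihood)",
    }
    return ResultBundle(
        elements=elements, orfs=orfs, trimmed=trimmed, tree=tree, rates=rates,
        manifest=manifest,
    )


def summarize(bundles, host_tree: Clade | None = None) -> dict:
    """Paper-style summary across one or more genomes.

    ``bundles`` is a ResultBundle or a mapping genome -> ResultBundle.
    Returns per-genome counts by class/completeness/architecture, the list
    of genomes where lineage A and D R2s co-occur, and (optionally) the
    Robinson-Foulds discordance between the R2 tree and the host tree on
    their shared leaves.
    """
    if isinstance(bundles, ResultBundle):
        bundles = {"genome": bundles}
    counts = {}
    co_occurrence = []
    for genome, bundle in bundles.items():
        df = bundle.elements
        counts[genome] = {
            "by_class": df.element_class.value_counts().to_dict(),
            "by_completeness": df.completeness.value_counts().to_dict(),
            "by_architecture": df.arch_label.dropna().value_counts().to_dict(),
        }
        r2 = df[df.element_class == "R2-site-specific"]
        lineages = set(r2.lineage_call.dropna())
        if {"A", "D"} <= lineages:
            co_occurrence.append(genome)
    out = {"counts": counts, "lineage_co_occurrence": sorted(co_occurrence)}
    if host_tree is not None:
        trees = [b.tree for b in bundles.values() if b.tree is not None]
        if trees:
            shared = set(trees[0].leaves()) & set(host_tree.leaves())
            if len(shared) >= 4:
                out["host_discordance_rf"] = rf_distance(trees[0], host_tree)
    return out


def write_result_bundle(bundle: ResultBundle, outdir) -> None:
    """Write the element table (TSV), GFF3, FASTA (ORFs, trimmed), newick
    tree, rates table, and the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.elements.to_csv(outdir / "elements.tsv", sep="\t", index=False)
    feats = [
        dict(
            contig_id=r.contig_id,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            score=float(r.score),
            type="mobile_genetic_element",
            attributes={
                "ID": r.element_id,
                "completeness": r.completeness,
                "element_class": r.element_class,
                "nick_offset": r.nick_offset if r.nick_offset is not None else "NA",
                "arch_label": r.arch_label or "NA",
                "lineage": r.lineage_call or "NA",
            },
        )
        for r in bundle.elements.itertuples()
    ]
    write_gff3(feats, outdir / "elements.gff3")
    if bundle.orfs:
        write_fasta(bundle.orfs, outdir / "orfs.fasta")
    if bundle.trimmed:
        write_fasta(bundle.trimmed, outdir / "orfs_trimmed.fasta")
    if bundle.tree is not None:
        (outdir / "tree.nwk").write_text(bundle.tree.to_newick() + "\n")
    if bundle.rates is not None:
        bundle.rates.to_csv(outdir / "site_rates.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")
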