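# Methods

## Scope and model of the problem

R2 retrotransposons insert site-specifically into the 28S rRNA genes of
tandem rDNA arrays by target-primed reverse transcription (TPRT): the
element-encoded protein (a single ORF carrying N-terminal zinc fingers and
a Myb domain, a reverse-transcriptase (RT) domain with eight ordered
conserved motifs 0–7, a restriction-enzyme-like endonuclease (RLE), and a
C-terminal thumb–zinc-knuckle) nicks the 28S target and primes cDNA
synthesis from the nick. The package implements the computational side of
curating such elements from genome sequence: locus discovery, target-site
junction analysis, domain-architecture annotation, lineage placement of RT
domains, and distance-based phylogenetics — with a synthetic-data module
that generates genomes with known ground truth so every stage has a closed
test loop.

## Synthetic data generator

`r2scout.simulate` builds one rDNA unit (default layout 18S-like 900 nt,
ITS-like 300 nt, 28S-like 2400 nt; canonical nick at offset 1200 of the
28S segment) and repeats it as a tandem array. Element proteins are
concatenations of shipped domain templates (`data/motif_templates.json`)
joined by random linkers drawn from an alphabet without C or H, so the
zinc-finger grammar can never fire outside a real finger. Nucleotide
elements are randomized synonymous-codon reverse translations flanked by
UTRs (defaults 300/250 nt) with in-frame stops placed immediately outside
the ORF, making the ORF a maximal stop-free stretch of exactly the
requested length; there is no initiator-methionine requirement, matching
R2's non-canonical translation.

Site-specific elements are inserted at `nick_pos + insertion_offset` of
distinct units (negative offsets = upstream of the nick, the frame in
which an 11-bp-upstream insertion is recorded as −11). 5′-truncated copies
lose `truncate5_nt` bases and receive 400 nt of random junk at the broken
5′ boundary, emulating the unrecoverable upstream junction of a truncated
or misassembled copy; full-length copies keep perfect 28S flanks on both
sides. Myb-less (Utopia-like) elements are placed at their own U2-like
locus contig and Myb-bearing non-site-specific homologs in random
contigs. Copies sharing a `family` name are byte-identical, as real
rDNA-embedded copies within one genome nearly are. A `misassemble` mode
splits one element across two contigs with chimeric junctions.

Reads are sampled uniformly over positions and strands with independent
per-base substitution and indel errors (rates capped at 0.3); read ids
encode the true origin. Protein evolution on a tree uses the 20-state
equal-rates model with rate normalized so branch lengths are expected
substitutions/site: `P_diff(t) = (19/20)(1 − e^(−20t/19))`. The closed
form is the reason this model was chosen over empirical matrices (LG
etc.): it gives exact oracles for the simulator, the pruning likelihood,
and the rate machinery. The model is a simplification; profiles and
distances are the components where an empirical exchangeability matrix
would slot in.

All operations take a single integer seed and derive any internal
randomness through `numpy.random.SeedSequence`; everything is
bit-reproducible.

### What the generator does not emulate

Real rDNA promoter structure and Pol I dependence, piRNA repression,
unit-to-unit rDNA polymorphism, GC/codon bias, structured UTRs, and
realistic long-read error profiles (errors here are i.i.d., not
homopolymer-biased). Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not performance on real
genomes; thresholds (flank identity, profile cutoffs) were chosen to be
tolerant but are not benchmarked against curated repeat libraries.

## Discovery

`scan_genome` is a BLAST-like seeded search: exact k-mer seeds (word size
7 in nucleotide mode, reflecting a sensitive search; 4 in translated
mode), counted per diagonal band (band width 16, minimum 8 seeds per band;
query k-mers sampled every 3 positions for memory, every subject position
scanned), adjacent qualifying bands grouped into a candidate region
extended to the full query projection, and the region confirmed by local
affine-gap alignment (+2/−3, gap 5 + 2·L nucleotide; BLOSUM62, gap 10 +
1·L protein; a gap of length L costs open + L·extend). Pairwise alignment
itself wraps Biopython's `PairwiseAligner`; ties among co-optimal local
alignments break toward the smallest (subject start, query start). N is a
mismatch to everything including itself; other ambiguity codes are
rejected. Translated mode scans all six frames and maps protein
coordinates back to forward-strand nucleotide coordinates.

Boundary exactness caveat: at a 5′-truncation break the true element
boundary is ambiguous whenever a flanking base happens to equal the
corresponding base of the full-length query — the optimal local alignment
legitimately includes such bases (a negative-drift random-walk excursion, usually 0–3 nt, tail-bounded at 25 nt in the shipped checks).
Recovery of truncated copies is therefore judged with an exact 3′
(junction) boundary and at most 25 nt of overshoot at the break; full-length
copies are judged exactly at both ends.

`rescue_from_reads` is a deliberately simple stand-in for dedicated
long-read error correction. Reads sharing ≥5 exact 15-mers with the query
(either orientation) are oriented and clustered by ≥100 nt mutual overlap
of their query projections; each cluster gets a backbone (widest
projection), greedy splice-in extension from reads projecting beyond
either end, and two rounds of majority-vote pileup polishing
(substitutions, deletions, and insertions all voted; an insertion or
deletion must win more than half the local coverage). Optional extra
rounds use short reads as voters. Consensus accuracy is asserted only on
synthetic data; with 30 spanning reads at 8 % error the consensus is
≥ 99.5 % identical to truth.

## Target sites and classification

Windows of 200 nt flanking a candidate are locally aligned to the 28S
reference; a flank matches at identity ≥ 0.80 over ≥ 50 aligned nt
(tolerant of diverged 28S, far above random). The junction coordinate is
the 28S position abutting the element, extrapolated to the window edge if
the alignment stops short. Both junctions → full-length; downstream only →
5′-truncated (the TPRT degradation mode); upstream only → 3′-truncated (a
case the three-way completeness vocabulary cannot express, added here);
neither → no rDNA flanks. The nick offset is the 5′ junction minus the
canonical nick position (3′ junction when the 5′ is absent), always
measured on the rDNA forward strand.

Classification follows the Myb hallmark: Myb + rDNA flanks →
site-specific R2; Myb without rDNA flanks → non-site-specific R2 homolog;
no Myb → Utopia-like; no usable ORF → unclassified. Known limitation: a
copy truncated past its Myb-encoding region classifies as Utopia-like even
though it descends from a site-specific R2 — the hallmark rule is only
meaningful for complete predicted proteins, and the pipeline reports
completeness alongside the class so such calls are interpretable.

## ORFs and domain grammar

ORFs are maximal stop-free stretches in the three frames of the element
strand (no start codon required); stretches ≥ 900 aa are "full" (the
boundary is inclusive: the filter removes ORFs *less than* 900 aa),
shorter stretches down to 30 aa are "partial", and anything below 30 aa is
inter-stop noise, not an ORF record. Codons containing N translate to X,
and X satisfies no motif position.

Zinc fingers are matched by the grammar `C x(s) C x(8–14) H x(3–5) [H|C]`
with first-pair spacing s ∈ {1,2,3}: the final coordinating residue gives
CCHH vs CCHC (the ZnF2 signature), s gives CxC/CxxC/CxxxC, and the literal
sequence C,P,C,C is flagged as the avian CPCC variant of CxxC. The
spacing windows (8–14 between the pairs, 3–5 before the last residue) are
canonical C2H2 geometry. Overlaps resolve greedily left-to-right; at the
same start the longest first-pair spacing wins — this is what makes CPCC
parse as a CxxC variant rather than CxC — and among equal spacings the
shortest match wins. An independent regex-lookahead oracle checks the
scanner over the full {C,H,P,A} string space up to length 30.

Myb, RLE, thumb–zinc-knuckle, and RT motifs 0–7 are detected by sliding
ungapped log-odds profiles built from the shipped templates (ten pseudo-
observations, pseudocount 1, uniform background; detection threshold 0.6 ×
the profile's maximum score, which demands ≈93 % template agreement —
shuffled proteins essentially never hit). The templates are synthetic
consensi chosen for self-consistency with these detectors, since no
reference consensus sequences ship with the package; users can replace
them in `data/motif_templates.json` or via the plain-text PSSM format
(`save_pssm`/`load_pssm`). The RT domain is considered intact when all
eight motifs occur in increasing coordinate order.

Architecture labels: only fingers N-terminal to the first Myb are
numbered, ZnF1 adjacent to the Myb and numbers increasing toward the
N-terminus. Three fingers → A, one → D (D+Myb2 with a duplicated Myb),
four → 4ZnF, none with no Myb → no-Myb. With exactly two fingers the
retained finger's pair type decides: CCHC N-terminal finger → ZnF2 present
→ B; CCHH → ZnF3 present → C. This is sequence evidence standing in for a
phylogenetic assignment and is labelled as such in output metadata. The
co-folded ZnF3:2 of lineage A is approximated by a declared linker-length
heuristic (`cofold_znf32_plausible`: both fingers present and ≤ 10 aa
between them), never presented as a structural result. The N-terminal trim
keeps 10 residues before the most N-terminal finger.

## Lineage placement and site rates

Placement mirrors a PSI-BLAST search in the direction the protocol uses:
the candidate RT family builds the PSSM (column frequencies
`(counts + pc·bg)/(n + pc)`, pc = 1, uniform background; scores
`2·log2(freq/bg)` rounded to half-bits; columns > 50 % gap dropped) and
the two lineage representatives are scored against it by affine-gap local
alignment over profile columns (gap 11 + 1·L half-bits). The call is the
higher-scoring reference; scores within 2 half-bits are ambiguous. Scores
are raw half-bits with no E-value calibration — they are placement
coordinates, not significance statistics. The shipped A and D references
share the motif blocks and differ in the inter-motif linkers, which is
exactly the signal family-vs-reference scoring keys on; at 0.5
substitutions/site the benchmark calls ≥ 95 % of 40 simulated families
correctly.

Per-column rates use K = 4 equal-probability discrete-gamma categories
(category rate = the conditional mean of the Gamma(α, α) distribution
within each quantile bin, so categories always average exactly 1). The
gamma shape is fitted by maximizing the pruning-recursion likelihood under
the 20-state equal-rates model (bounded scalar optimization on α ∈
[0.05, 20]); the equal-rates transition matrix has the spectral form
`e^(−λt)·I + (1 − e^(−λt))·J/20`, so each branch message is one
exponential and a row sum. Per-column posterior-mean rates are reported
and binned into equal-frequency sextiles (bin 1 = most conserved, ties by
column index), the convention used for RT-motif conservation tracks;
all-gap columns get no rate and bin 0. Recovery under the generator: α
within ±30 % for each of α ∈ {0.3, 1, 3} (10 seeds, 12 taxa, 500 sites)
and Spearman ≥ 0.7 between true and posterior-mean rates (300 sites,
α = 0.5).

## Phylogenetics

Trees are built by canonical neighbor joining — chosen over ML tree search
deliberately: NJ is exact on additive matrices, which makes the whole
stage oracle-testable, and the downstream claims are topological. The
choice is recorded in every tree manifest. Q-criterion ties break toward
the lowest node-index pair; negative branch lengths clamp to zero with the
deficit moved to the sister edge. Distances are p, Poisson
(−ln(1 − p)), or Kimura-protein (−ln(1 − p − 0.2p²)) over columns where
both rows are ungapped. Bootstrap = column resampling, NJ per replicate,
support = percentage of replicates containing each internal bipartition
(default B = 1000; bit-reproducible for a fixed seed; the display
convention flags supports under 80). Outgroup rooting bisects the
outgroup's pendant edge. Robinson–Foulds distance is the symmetric
difference of internal bipartitions after pruning to the shared leaf set
(cross-checked against dendropy). Domain-partition trees run the same
pipeline on disjoint, in-bounds column ranges.

Progressive alignment builds a guide tree from pairwise 3-mer distances
(average linkage) and merges by global affine profile–profile alignment
(sum-of-pairs expected score under BLOSUM62); pairwise merges use the same
DP as the two-sequence oracle, so the two-sequence case is exactly the
pairwise optimum. Trimming drops columns whose gap fraction exceeds 0.9
(a declared approximation of site-trimming tools whose exact mode is
unspecified) and reports the dropped indices.

## Pipeline and reporting

`pipeline.run` chains discover → merge → junctions → ORFs/domains →
classification → lineage placement, then (optionally) aligns the trimmed
ORFs of full-length R2 elements, trims, and builds a bootstrapped NJ tree
plus the site-rate track on the same alignment. The element table, GFF3
(1-based inclusive, converted by a single audited function from the
0-based half-open internal convention), FASTA, newick, rates TSV, and a
JSON manifest (version, parameters, SHA-256 input checksums) are written
per run; reruns with the same config and seed are byte-identical.
`summarize` produces the per-genome census by class/completeness/
architecture, the list of genomes carrying both lineage A and D
site-specific elements, and, given a host tree, the RF discordance between
the R2 tree and the host tree on shared leaves. The pipeline's own tree
stage defaults to 100 bootstrap replicates (the library default for
`neighbor_joining` remains 1000, the protocol's value); this is the
pipeline's runtime choice for routine runs, adjustable in
`PipelineParams`.

## Problem sizes used in the shipped checks

Discovery: two 10-unit arrays, 12 full-length + 8 truncated elements
(~150 kb total, 4 query families). Rescue: one ~3.4 kb element, 30 long
reads at 8 % combined error. Lineage: 40 four-taxon families at 0.5
subs/site. Rates: 12 taxa × 300–500 columns. Phylogenetics oracles: all
15 five-leaf topologies, 5-leaf brute-force likelihood enumeration. These
sizes exercise every code path with exact or statistical oracles; the
algorithms scale to real single-genome inputs (the scan is linear in
genome length at fixed query set, and NJ is cubic in taxa).

## Known limitations

- The substitution model everywhere is 20-state equal-rates; empirical
  matrices are a data-file swap away but not shipped.
- Domain profiles are synthetic consensi, not curated family models; on
  real data users should substitute profiles derived from reference
  alignments.
- The B/C architecture call uses retained-finger evidence, not phylogeny.
- `cofold_znf32_plausible` is a linker-length heuristic, not structure.
- Rescue has no quality model and assumes clusters correspond to loci;
  collapsed near-identical families within one genome are one cluster.
- No E-value statistics anywhere; score thresholds are calibrated only on
  the generator's null (shuffles, random sequence).
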