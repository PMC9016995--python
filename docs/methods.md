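# Methods

This note documents the models, estimators and numerical choices behind
`plastcomp`, and what the synthetic-data experiments do and do not show.

## Coordinates and canonical form

All coordinates are 0-based half-open on a circular sequence; GFF3 I/O
converts to 1-based closed at the boundary. A genome is *canonical* when the
LSC starts at position 0 and the region order is LSC → IRb → SSC → IRa.
Orientation is fixed by ycf1 when annotated (it must intersect SSC ∪ IRa);
without annotation the orientation giving the lexicographically smaller SSC
is chosen. The SSC is defined as the shorter of the two single-copy
segments; a length tie is broken by GC (lower GC = SSC) and a double tie
raises `AmbiguousPartition`.

## Inverted-repeat detection

The detector compares the doubled sequence against its reverse complement.
Exact matches lie on anti-diagonals (x pairs with c−1−x for constant c), so
21-mer seeds identify candidate anti-diagonals; seeds are expanded into full
exact runs, and each run of ≥ max(21, `min_terminal_matches`) bases becomes
a core. A core is extended outward, absorbing one mismatch at a time, but
only when the exact run beyond that mismatch carries at least
`min_terminal_matches` (default 10) matches and the running mismatch
fraction stays within `max_mismatch_frac` (default 0.02). This
run-supported extension is deliberate: the textbook "maximal window with
mismatch fraction ≤ f" objective always absorbs a few chance
complement-matches past the true boundary (each flank base matches with
probability 1/4), so it cannot return exact junction coordinates.
Requiring ≥10 matches beyond an absorbed mismatch makes a false extension a
4^−10 event while still chaining through isolated internal substitutions.
The trade-off: a genuine IR substitution within 10 bp of a junction would be
trimmed off, shifting the boundary to the substitution — accepted and
documented. Candidate pairs must be circularly disjoint with 2·IR ≤ genome;
the maximal-length pair wins, equal-length non-equivalent pairs raise
`AmbiguousPartition` with both candidates attached, and no qualifying pair
raises `NoIRFound`. An exhaustive anti-diagonal oracle in the test suite
confirms coordinates and mismatch counts on constructed genomes.

## Repeat detection

SSRs are perfect tandem repeats only. For each period u ∈ 1..6 the boolean
array s[i] = s[i−u] (circularly) is computed; maximal true runs of length m
correspond to tandem runs of m+u bases starting at the run head minus u.
Copies are ⌊run/u⌋; thresholds are 8 copies for u=1 and 5 for u=2..6.
Non-primitive motifs are suppressed so a run is reported once at its true
period. Circular scanning reports origin-crossing runs with a `wraps` flag.

Dispersed repeats follow the REPuter definition: maximal pairs with at most
3 mismatches, ≥30 bp and ≥90% identity, in four orientations. All four
reduce to plain diagonal comparisons of the sequence against itself, its
complement, its reverse and its reverse complement. Maximality means
extension in either direction would add a (k+1)-th mismatch. Enumeration is
seed-driven: any ≥30 bp window with ≤3 mismatches contains an exact run of
≥⌈27/4⌉ = 7 bases (pigeonhole), so 7-mer seeds find every qualifying window;
each seeded exact run yields the h+1 maximal windows trading left for right
mismatches. Linear mode is proven exactly equivalent to an O(n²)
full-diagonal oracle in the tests; circular mode scans the doubled sequence,
canonicalises pairs mod n, drops boundary-clipped duplicates, and excludes
the trivial self-identity diagonal at offset n.

Densities are bp/kbp: repeat bases (both copies of a dispersed pair)
counted with multiplicity, junction-spanning hits pro-rated base by base,
IRb+IRa pooled. This preserves Σ density·region_kb = total repeat bases
exactly, which the suite asserts.

## Junctions

Pseudogene fragments are geometric, not similarity-searched: Ψycf1 is the
portion of the J_SA-spanning ycf1 inside IRa (duplicated by the IR into
IRb beside J_SB), Ψrpl22 the portion of rpl22 inside IRb, and ΨndhF is
present when ndhF overlaps IRb across J_SB (its length is that overlap;
when absent, the distance from ndhF to J_SB is reported instead — both
conventions are carried in the output table). J_SB types: C when no ΨndhF;
otherwise A when Ψycf1 ≥ 578 bp, else B. The observed fragment ranges
(796–1434 bp for A, 156–360 bp for B) leave 361–795 bp unassigned; 578 is
the midpoint of the gap and is exposed as `ab_threshold` so every profile
maps to exactly one type without inventing data.

## Sequence variability

For an aligned non-coding locus with terminal gap columns removed:
conserved = gap-free columns with one state; SNP = gap-free columns with
≥2 states; an InDel event is a maximal run of columns gapped in the same
non-empty row subset (DnaSP-like event counting; a per-column variant is
available via `indel_unit="column"`). Columns inside InDel runs count
toward neither SNPs nor conserved sites, so SNPs + conserved + gapped
columns equals the alignment length exactly. SV = 100·(SNPs + InDels) /
(SNPs + InDels + conserved), reported to 4 decimals. Loci with fewer than
100 conserved sites are removed before ranking (the boundary case of
exactly 100 is kept); ranking is SV-descending with name tie-breaks, and
the top-10 sets of two clades are intersected for shared hotspots.

## InDel dating

Events are maximal gap runs of a reference-anchored pairwise alignment
(insertion = gap in the reference row), merged across taxa on identical
(reference position, type, length); a ±`slop` window (default 0) absorbs
alignment jitter. Placement: a carrier set that is exactly a clade's leaf
set goes on the clade's stem; otherwise binary Fitch parsimony with
absence preferred at an ambiguous root (the reference state is ancestral)
yields gain branches; multi-gain events are flagged homoplastic and split
evenly, conserving total event length exactly. Branch rate = assigned bp /
branch duration (myr); clade rate = pooled bp / pooled duration over every
branch in the clade, stem included. The clade estimator is a documented
choice — published clade rates depend on the original alignments and an
unstated estimator and are not asserted.

## NG86 selection statistics

Synonymous site fraction of a codon position = synonymous single-base
changes / 3, with changes to stop codons counted toward the nonsynonymous
fraction, so N + S = 3·codons exactly. Pairwise differences are averaged
over all orderings of the differing positions; orderings passing through a
stop codon are excluded, and if all are blocked, all orderings are used
with stop steps counted nonsynonymous. pN and pS receive the Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p) separately; p ≥ 3/4 raises
`SaturationError`. ω = dN/dS is NA when dS = 0 and NA values are excluded
(and counted) in every screen. The standard genetic code is the default
with the bacterial/plastid table (11) available. This counting method
replaces maximum-likelihood branch models deliberately: it is exact,
deterministic and fully specifiable, and the output headers say so. Gene
lists from ML branch models are therefore not comparable targets; the
planted-ω recovery experiment below is the corresponding check.

## The synthetic plastome generator

The generator is the package's study-condition definition. The ancestor is
a 14.5 kbp toy plastome — LSC 8000, IR 2500, SSC 1500, a scaled-down
plastome with the same architecture as the real 150 kbp molecules — with a
12-feature annotation: five content-bearing CDSs in the LSC (psbA, atpA,
rbcL, matK, psbZ) generated in-frame and stop-free, rpl22 spanning J_LB by
62 bp (within the observed 10–79 bp Ψrpl22 range), rrn16 in the IR, ndhF
at or near J_SB per scenario, rpl32 in the SSC, ycf1 spanning J_SA by
1000/250/500 bp in scenarios A/B/C (inside the observed type-A and type-B
fragment ranges), and the Ψycf1 fragment annotated in IRb. Three planted
SSRs and two planted dispersed repeats sit in spacers with
maximality-breaking flank bases so detector output equals planted truth
exactly.

Evolution runs along a chronogram (default: two 3-leaf clades, crowns at
4 myr, clade stems 8 myr, divergence 12 myr ago, whole-tree stem 6 myr —
a scaled-down version of a late-Oligocene two-clade split) with, per
branch, in order: neutral substitutions (Poisson, rate 2×10⁻³ /site/myr,
region multipliers LSC 1 / SSC 3 / IR 0.3 reflecting the observed
variability ordering), codon-level events in the content CDSs (proposal
rate 1.5×10⁻³ /site/myr; synonymous proposals accepted, nonsynonymous
accepted with probability ω for ω ≤ 1, the reciprocal rule for ω > 1,
stops rejected), and InDels (rate 2×10⁻⁴ /site/myr, geometric lengths with
p = 0.25 i.e. mean 4 bp, insertions and deletions equiprobable, region
multipliers LSC 1 / SSC 3 / IR 0).

Three modelling choices keep the truth exact and are also biologically
motivated:

1. **IR gene conversion** — substitutions hitting IRb are mirrored into
   IRa, so the two copies remain exact reverse complements in every
   descendant (real plastome IRs are homogenised by copy correction).
2. **No InDels in IRs or genes** — plastome IRs are nearly InDel-free and
   coding InDels are overwhelmingly purged; confining InDels to
   single-copy non-coding zones keeps annotations liftable and per-leaf
   partition truth well defined.
3. **Junction anchors** — the four bases flanking the IR boundaries are
   held fixed so the maximal inverted repeat stays the planted one;
   without this, chance complement-matches would legitimately extend the
   IR and "exact recovery" would be ill-posed.

Every event is logged with entry identities; replaying a leaf's log from
the ancestor reproduces its sequence byte for byte (asserted). Alignments
are *induced* from the log — columns are ancestor positions plus
insertion columns keyed by inserted-entry identity, so an insertion
inherited from an internal branch occupies the same columns in every
descendant. This replaces a heuristic aligner with homology by
construction; real-data workflows instead accept externally aligned FASTA.

What passing these tests does **not** show: the generator has uniform base
composition, no rearrangements or inversions, no IR expansion/contraction
during evolution, no alignment error, and planted elements placed clear of
junctions. Real plastomes violate all of these; the tests validate the
estimators' correctness on their stated model, not robustness to
annotation or alignment noise.

## Problem sizes and statistical checks

Scales were chosen so the full suite runs in minutes on one core: 14.5 kbp
genomes, 4–6 leaf trees, 50-seed InDel-rate batches, 20-seed selection
batches, 30-seed Poisson-calibration batches (aggregate count within 3σ of
the planted expectation, computed with InDels disabled so site counts stay
fixed). Published plastome InDel rates of tens to hundreds of bp/myr
presuppose 150 kbp genomes; on the toy's ~2 kbp of InDel-eligible sites
the rate-recovery experiments plant ~30 bp/myr instead — the estimator
and its 20% recovery tolerance are unchanged. The generator itself is unbiased for
insertions (they are never truncated; the eligible-site pool is a
martingale under equal insertion/deletion pressure), and the realised
event bp matches the planted expectation to ~1%. The *estimator* runs a
little hot at the tested density (~10–15%): an insertion inherited from an
internal branch merges across descendants only when its (position, type,
length) manifestation is identical, so when a later overlapping event
alters one descendant's copy, the shared event is counted once per
divergent form. This over-count scales with event density, is inherent to
the exact-identity merge rule, and stays within the 20% recovery
tolerance; deletion bp is conversely slightly conservative because draws
truncate at zone boundaries.

## Pipeline

Stages run in dependency order (simulate → partition → repeats → junctions
→ hotspots → indels → dnds → report) into one directory; a JSON manifest
records the config hash and SHA-256 of every output. A re-run whose every
stage matches is a no-op; a stage failure is recorded and its dependents
are skipped. Group comparisons use the two-sided Mann–Whitney U (exact
null when both n ≤ 8 and no ties) or Welch's t; the per-gene ω screen
reports Benjamini–Hochberg FDR alongside raw p values (the screen flags on
raw p at 5%, the FDR column is informational). With three genomes per
clade the rank-sum test cannot reach p < 0.05 (minimum two-sided p is
0.1); the pipeline reports the statistics and directions, and the
published 27-genome table is the dataset on which the GC contrast is
actually significant.
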