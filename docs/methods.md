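# Methods

## Problem and model

A rearranged receptor read is `V′ – N – J′ (– C)`: a germline V segment
whose 3′ end lost `d_V` bases, non-templated N additions, and a germline J
segment whose 5′ end lost `d_J` bases, followed (depending on library
design) by constant-region sequence. Two empirical regularities make the
germline recoverable from such reads alone. First, junctional deletion
lengths decay quickly — for TRB more than half of V deletions are within
1 bp — so for every segment a sizeable fraction of reads carries the
intact terminus. Second, somatic hypermutation (SHM) and PCR/sequencing
errors are mostly random per read, so within a set of reads of common
origin they are low-frequency at every position, whereas the germline base
is carried by a large majority. Inference therefore reduces to (i)
grouping reads by origin without a reference and (ii) reading off a gated
consensus whose gates also locate the segment's junction-facing end.

## Pipeline stages and the parameters that matter

### Data processing

* `--c-mismatch 2`, `--c-probe-len 18` — a read is oriented by locating
  the first 18 bases of any supplied C reference on either strand with at
  most 2 mismatches; the best (fewest-mismatch) window wins, ties going to
  the most 3′ window because the C region terminates the amplicon. N bases
  count as mismatches. Without C references, reads are assumed
  forward-oriented (`--no-c-region`).
* `--jm 60`, `--vm 40` — the J part is the read's last 60 bases; the V
  part is the read minus its last 40 bases. The two overlap by design so
  neither segment is truncated; each may contain junction bases, which the
  assembly gates discard. Parts shorter than `--min-part-len 30` are
  dropped.

### Seed_Clust

* Seed lengths: V 40, J 20 (long-read data: 200). Seeds are enumerated
  only from the germline-confident region — the last 10 bases of a V part
  and the first 5 of a J part are excluded — but membership is plain
  substring containment anywhere.
* A seed's score is the summed abundance of the unique reads containing
  it; the `matrix` scorer additionally credits each non-containing read
  0.2 × its abundance. The 0.2 background term is constant across seeds at
  any iteration, so both scorers rank seeds identically; `count` is the
  default.
* Greedy extraction with exact incremental score updates; ties broken by
  lexicographically smallest seed. Extraction stops when the best cluster
  would hold fewer than `--min-cluster-reads 10` reads; the remainder is
  residue. A germline segment present in ≥ 0.1 % of a 10⁴-read sample
  comfortably clears this floor.

### Assembly

* A multiway position tree anchored at the seed tallies read and
  unique-read support per (position, nucleotide). Extension is one base at
  a time, junction side first (V: 3′-ward then 5′-ward; J mirrored), all
  four bases examined at each frontier.
* Gates: `Ar > 0.15 / Ur > 0.12` (V) and `Ar > 0.12 / Ur > 0.10` (J).
  Several bases may pass, forking the path (true heterozygous alleles,
  abundant shared mutations); at most `--max-paths 16` maximal paths are
  kept, pruned by lowest minimum per-step Ar.
* **Support semantics.** A read supports the extension `(i, j)` if it
  covers `i`, carries `j` there, and agrees with the path over the
  trailing `support_window = 15` bases. This windowed contract is the
  load-bearing design choice. Requiring agreement with the *entire* path
  makes support decay geometrically with length — at a 1 % per-base
  mutation rate no read is clean over 150 bp, and assembly truncates even
  though the position-wise consensus is unambiguous. Requiring only the
  base at `i` does the opposite: beyond the segment's end the junction
  content is read-specific, every base sits near 25 % ≥ the gates, and
  paths would walk indefinitely into junction noise. The 15-base window
  keeps both properties: a read that disagreed near the frontier cannot
  push the path further (so extension dies within a base or two of
  entering the junction), while a read with a scattered mutation elsewhere
  still votes. 15 bases is long enough that random junction content almost
  never matches by chance (4⁻¹⁵) and short enough that at a 5 % per-base
  mutation rate roughly half the reads are still clean over the window.
* `--min-extend-cov 2` — coverage floor at the frontier.
  `--min-branch-unique 3` — an extension must be observed in at least 3
  distinct unique reads; one- or two-molecule branches are statistically
  indistinguishable from mutation/error noise and, left unchecked, small
  clusters of mutated reads emit spurious single-read variant paths.

### Optimization

Support for a sequence is substring containment within the candidate's own
source cluster (cluster-local, reproducible). The five statistics follow
the printed ×100 convention; the gates interpret them on the scale where
each is discriminative:

* *Trim5 Ratio1/2* (> 1.5 on the fold scale) — support of the 5 bp-trimmed
  form relative to the candidate's own support. A genuine junction-facing
  terminus roughly doubles its support when trimmed (deletion diversity);
  non-specific amplification and over-extended candidates sit at 1.
* *Trim5 Rate1/2* (> 2) and *More5 Rate* (> 5), both as percent of the
  same-segment cohort mean — weak relative-support floors that remove
  candidates with vanishing absolute evidence. For TRB J data the rate
  threshold drops to 0.5 (`--chain TRB`).
  An empty cohort leaves the rates undefined and the gates pass vacuously.
* Merging: a candidate contained in another (allowing ≤ 2 mismatches, all
  within the junction-facing 5 bp of the overlap) is absorbed by the
  longer/better-supported one; merge counts feed the score.
* SHM grouping: candidates are grouped by masked substitution distance
  (≤ 3 for V, ≤ 2 for J; the junction-facing 3 terminal bases are masked)
  at the best ungapped offset, groups seeded by highest read support.
  Offset alignment (rather than junction-anchored alignment) lets partial
  assemblies of a gene fall into the gene's group instead of founding
  their own. One individual carries at most two alleles of a gene, and the
  rarer allele is rarely more than 10× rarer, so each group keeps its
  center plus the member with the smallest Ratio(S) ≤ 10.
* Sequences inferred independently in several individuals are almost
  certainly germline; `infer_samples(..., min_samples=k)` annotates and
  filters by cross-sample occurrence.

### Annotation

Score(S) sums six cohort-normalized terms — the five filter statistics and
the merge count, each `value/max × weight` — plus a major/minor allele
bonus, with weights (20, 20, 15, 10, 10, 15, 10, 5); the major branch sums
to 100 and scores are clipped to [0, 100]. Classification against known
alleles uses ungapped end-free alignment (germline alleles differ almost
exclusively by substitutions) with an edlib gapped fallback for
length-discordant, poorly fitting pairs; by default the junction-facing 3
terminal bases are masked in mismatch counting (`--no-terminal-mask`
restores raw counts). Categories: `known` (0 masked mismatches, |deviated|
≤ 5), `novel_allele` (< 7 mismatches for V, ≤ 5 for J), else
`novel_gene`; novel genes are grouped at the same 7/5 dividing lines and
named `GENE<letter>*<index>` — suggestions only, not official
nomenclature.

## Simulator

The generator emulates the study conditions end to end and records every
event so each read can be replayed exactly:

* Deletion lengths are truncated geometric, `P(L) ∝ (1−q)^L`:
  `q_V = 0.30` (P(d ≤ 1) = 0.51, matching the observed "more than half of
  TRB V deletions within 1 bp"; cap 10) and `q_J = 0.25` (J deletions are
  more diverse; cap 15).
* Insertions are the sum of **two** independent geometric zones
  (`q = 0.12`, cap 12 each), modelling the V–D and D–J N-addition zones;
  a junction with zero inserted bases is accordingly rare (~1.4 %). A D
  stub between the zones is supported but off by default.
* Mutation layers, in order and all recorded: per-base sequencing error on
  every read (default 0.5 %); random SHM at `shm_rate` (0–20 %) on
  `shm_fraction` (default 80 %) of reads; per V allele one fixed
  (position, substitution) hotspot applied to exactly
  `round(hotspot_rate × n_allele_reads)` of that allele's reads — the
  construct that emulates clonally shared mutations, the hardest artifact
  to distinguish from a real novel allele. Later events overwrite earlier
  bases; the truth history keeps both.
* The default panel is synthetic: 20 V alleles of 150 bp and 10 J alleles
  of 50 bp of uniform random sequence (pairwise ~75 % divergent, i.e.
  distinct genes); novel alleles for spike-ins are made by substituting a
  few bases of an existing allele. Spike-ins simulate reads from novel V
  sequences (defaults 0.5 % error, 1 % SHM) and append them with truth
  flags.

What the generator does **not** emulate: clonal lineage structure (real
SHM is phylogenetically correlated; here it is i.i.d. per read — harder
for the assembler in one way, easier in another since no sub-clone shares
mutations except the explicit hotspot), biased SHM motifs (WRCY), skewed
allele usage, base-quality profiles, and partial 5′ coverage (every
simulated read spans its full V portion, so 5′ termini are easier than in
real 5′RACE data). Passing tests therefore demonstrate the machinery's
correctness and its robustness to random noise and shared hotspots, not
performance on real libraries.

## Evaluation

Each inferred sequence is assigned its nearest truth allele by maximal
ungapped identity (ties: fewer mismatches, then name). A call is *correct*
when identity > 90 % and the junction-facing terminal deviation is at most
5 bases; *exact* when it equals the source allele base for base (the
strictest reading of complete correctness, used for the hotspot
experiments). Summary means follow the correct-calls-only convention, with
all-call means reported alongside.

At the scale used by the bundled experiments (30-allele panel, 10⁴ reads —
chosen so a full six-rate, three-seed SHM sweep completes in a few
minutes), correctness-rule accuracy is flat across SHM rates 0–20 % while
base-exact recovery eases from 1.0 to ≈ 0.85 at the highest rates: as SHM
removes reads from clusters the sampling variance of the junction-position
support grows, and an occasional terminus acquires a single extra junction
base (mismatches stay at zero). This ±1 terminal jitter is inherent to the
gate statistics at reduced cluster sizes and mirrors the ~1 bp mean
terminal deviation seen on real data; it is distinct from hotspot-induced
errors, where a shared substitution creates a genuinely competing allele
branch and exact recovery drops markedly between hotspot rates of 5 % and
30 %.

## Numerical choices and degenerate inputs

* All tie-breaks are deterministic: lexicographic for seeds, group
  centers, and More5 extensions; reference-name order for equal-identity
  nearest alleles. Results are invariant to input ordering.
* Scores with an undefined term (cohort maximum 0, or an infinite rate
  from an empty cohort) drop that term rather than propagate it.
* Candidates spanning no single read (containment support 0) take ratio
  +inf and pass the ratio gates; this cannot arise with the bundled
  simulator, where every read spans its segment portions.
* Degenerate inputs: empty read sets, clusters whose every eligible seed
  region is shorter than k, and empty inferred sets all return empty
  results with logged warnings rather than raising.

## Known limitations

* D segments are not inferred (the V/J machinery would apply once V and J
  are assigned, but that step is out of scope).
* Gapped germline variation (indels between alleles) is handled only at
  annotation time, not during assembly, which is strictly ungapped.
* Termini carry ±1–2 bases of uncertainty at low coverage; cross-sample
  intersection (`infer_samples`) is the recommended guard, as shared
  junction noise across individuals is vanishingly rare.
* Official nomenclature assignment requires genomic loci and is explicitly
  not attempted.
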