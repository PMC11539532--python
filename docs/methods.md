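# Methods

## The model

An intact LTR retrotransposon carries two long terminal repeats (LTRs)
that are identical copies of one another at the moment of insertion.
From then on each copy accumulates substitutions independently, so the
divergence between the two LTRs of an element behaves as a molecular
clock for the insertion event itself.

The estimator has four stages:

1. **Duplicate collapse.** Structural annotators frequently emit
   several records for one physical insertion. Two records are treated
   as duplicates when they lie on the same scaffold, their left LTR
   intervals overlap, their right LTR intervals overlap, and the sum of
   nonoverlapping bases — the symmetric difference of the paired left
   intervals plus that of the paired right intervals, i.e.
   `|Δ left starts| + |Δ left ends| + |Δ right starts| + |Δ right ends|`
   given both overlaps — is below a threshold (default 50 bp). The
   relation is closed transitively into connected components and, within
   each component, the record with the byte-wise lexicographically
   smallest `element_id` is retained. A greedy non-transitive mode is
   kept behind the `transitive` flag for sensitivity analysis, because
   chained near-duplicates could in principle be collapsed either way;
   transitive closure is the default because it is deterministic and
   input-order independent.

2. **LTR-pair alignment.** The two LTR sequences of each element are
   extracted on the forward strand (pairwise divergence is invariant
   under joint reverse-complement) and globally aligned with affine gap
   costs: match +5, mismatch −4, gap opening 16 and gap extension 4,
   a run of *k* gap positions costing `open + (k−1)·extend`, terminal
   gaps fully penalized. These are the standard nucleotide defaults of
   EMBOSS-style global aligners; all four scalars are configurable.
   Columns containing non-ACGT characters score as mismatches and are
   excluded from divergence counting downstream. The alignment engine
   is Biopython's `PairwiseAligner` (global mode with a substitution
   matrix implementing the scheme above); among co-optimal alignments
   its canonical first traceback is reported, which is deterministic
   for fixed inputs. Optimality of the reported score is verified in
   the test suite against exhaustive enumeration of every alignment
   path on short sequences.

3. **K2P divergence.** Over aligned columns, after pairwise deletion of
   any column with a gap or ambiguity character, transitions (A↔G,
   C↔T) and transversions (all other mismatches) are counted. With
   transition proportion P and transversion proportion Q over n
   comparable sites, the Kimura two-parameter distance is

       K = −1/2 · ln((1 − 2P − Q) · √(1 − 2Q))    [substitutions/site]

   K is undefined — the element is flagged *saturated* — when
   `1 − 2P − Q ≤ 0`, `1 − 2Q ≤ 0`, or no comparable sites remain.
   Saturated elements are kept in the per-element output with the flag
   set but are excluded from age summaries and histograms: in conifer
   genomes, where median insertion ages can exceed 100 MYA, saturation
   is a reportable state of the data, not an error. Distances are
   stored in substitutions/site throughout (some tools print per 100
   sites; no such scaling is applied here).

4. **Clock dating.** Because both LTR copies accumulate substitutions
   independently, the expected pairwise divergence after t years is
   `2 r t` for a per-site, per-year rate r, so the insertion age is

       T = K / (2 r)

   The default rate is r = 0.59 × 10⁻⁹ substitutions/site/year, the
   value reported for *Cryptomeria japonica*; it is a single per-run
   parameter (`--rate`) and should be set per species — the artifact
   deliberately does not guess rates for other taxa.

Clade labels (REXdb clades within the Copia and Gypsy superfamilies)
are consumed from a TEsorter-style classification table, never
recomputed. TEsorter suffixes identifiers with `#classification`; ids
are reconciled by stripping at the first `#`. Superfamily assignment
prefers the classification table, falls back to the annotation's parent
feature type (e.g. `Copia_LTR_retrotransposon`), then to
`other/unknown`. Per-clade summaries report count, length min/max/
mean/median (element span, bp) and age min/max/mean/median (MYA, over
non-saturated elements), with even-count medians taken as the midpoint
of the two central values. Age histograms use half-open bins
`[k·w, (k+1)·w)`.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| dedup `nonoverlap_threshold` | bp | 50 | duplicate records of one insertion differ by a few bases of boundary jitter; 50 bp separates jitter from genuinely distinct neighboring insertions |
| match / mismatch | score | +5 / −4 | standard nucleotide scoring (EDNAFULL diagonal/off-diagonal) |
| gap open / extend | penalty | 16 / 4 | standard nucleotide affine defaults of EMBOSS-style global aligners |
| clock rate r | subs/site/year | 0.59e-9 | reported for *C. japonica*; override per species |
| histogram bin width | MYA | 5 | resolves structure over a 0–200 MYA conifer age range |
| simulator κ | ratio | 2.0 | typical plant nuclear transition/transversion rate ratio |

## Annotation input conventions

Coordinates are GFF3 convention (1-based, closed) throughout. The
GFF3 dialect accepts any parent feature whose two children are of type
`long_terminal_repeat` (structural annotators emit superfamily-specific
parent types); the left LTR is the child with the smaller start,
regardless of file order. Records violating the coordinate ordering
invariant, or parents without exactly two LTR children, are dropped
with a logged warning and counted in the run manifest — annotation
output is noisy and a malformed record should not abort a genome-scale
run. Which structural output file (intact GFF3 vs. pass-list) best
feeds the pipeline can differ between annotator versions, so both a
GFF3 and a normalized-TSV dialect are supported via `--dialect`.

## The simulator: what it emulates and what it does not

`simulate_genome` inverts the inference model exactly: an ancestral LTR
drawn uniformly over ACGT, laid out as LTR–internal–LTR in random
background sequence, with the two copies evolved independently for
`r·t` substitutions/site each under the K2P process at ratio κ,
sampled from the closed-form transition probabilities (exact at any
branch length, O(L) cost — no event-by-event simulation). Uniform
base composition is used because K2P assumes equal frequencies; this
keeps simulation and inference self-consistent. Indels are off by
default and available only as a robustness knob (insertion/deletion
equally likely, geometric lengths) to exercise the aligner. Injected
near-duplicate records jitter the four LTR endpoints inward by small
deltas whose total stays below the dedup threshold, and carry ids that
sort lexicographically after the source record, so ground truth about
what dedup must remove is exact. `clade_by_age=True` ties clade labels
to the age cycle (one true age per clade) so per-clade summary
statistics can be compared against truth without order-statistic noise
from mixed-age clades; by default labels are arbitrary draws from the
REXdb clade list.

The simulator does **not** model nested insertions, solo LTRs,
recombination or ectopic exchange between elements, rate variation
across sites or lineages, selection, or realistic genome composition.
Passing tests therefore validate the estimator under its own model
assumptions — they show the pipeline recovers ages without systematic
bias when the clock model holds, not that real conifer annotations are
free of biological violations of those assumptions (e.g. gene
conversion between LTRs shrinks apparent ages).

## Numerical and design choices

- Saturation is detected on the exact domain boundary of the logarithm;
  K is clamped at 0 so that elements with zero observed divergence
  report age exactly 0 rather than −0.
- `K(P, Q)` is strictly increasing in P for fixed Q on the valid
  domain; this and invariance under row swap and joint complementation
  are asserted as properties in the suite.
- Dating is linear in K and inverse in r, so rate changes rescale ages
  without recomputation of divergences.
- Outputs are sorted by `element_id` before writing, making runs
  byte-identical regardless of the worker count used for per-element
  alignment.
- Problem sizes in the validation suite — 200 elements per true age
  with 1 kb LTRs for age recovery, 10⁵ sites for simulator calibration,
  exhaustive alignment enumeration up to length 8 — were chosen so the
  binomial sampling error of P and Q keeps the mean recovered age
  within ~1% of truth (3 SE ≪ the 5% recovery check) while the whole
  suite runs in well under a minute per check.

## Known limitations

- One global clock rate per run; comparative multi-species analyses
  must supply each species' rate explicitly.
- No confidence intervals on K or T (a bootstrap over aligned columns
  is a natural extension).
- Jukes–Cantor or GTR alternatives to K2P are not provided.
- The duplicate rule is purely coordinate-based, as defined; no
  sequence-identity clustering.
- Ages beyond saturation (roughly K ≳ 0.7 for κ = 2) are unreportable
  by construction; the saturated count per clade is the honest output
  for such elements.
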