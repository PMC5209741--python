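# Methods

This note records the statistical model behind `its-screen`, every
user-facing parameter with its default and rationale, the scope of the
synthetic generator, and the numerical choices that could affect results.

## 1. Unit of analysis and coordinates

The unit of analysis is a *clone*: one sequenced plasmid insert sampling
one repeat variant of the rDNA cistron (18S–ITS1–5.8S–ITS2–26S) from one
individual (*sample*). Coordinates are 0-based half-open internally;
human-readable reports use 1-based inclusive positions (the `nt-16`
notation of the pseudogene literature). Sample membership defaults to
stripping the trailing `-<cloneNumber>` from the FASTA ID and can be
overridden with a two-column TSV map.

## 2. Region delimiting

Three reference blocks anchor the regions: an 18S tail, the 5.8S gene, and
a 26S head. Each is placed on the clone by **local pairwise alignment**
(Biopython `PairwiseAligner`; match +1, mismatch −1, gap open −2, gap
extend −0.5). The affine extension term is deliberate: decayed rDNA
copies carry long deletions (tens to >100 bp), and a linear −2/column gap
cost fragments the anchor across them, while −0.5/column bridges them in
one alignment.

**Penalized identity.** An anchor is accepted when its *score divided by
the reference length* reaches the floor (0.5 for the 5.8S, 0.5 for
flanks). Raw matched-fraction is not used: under affine gaps, 600 bp of
random sequence still collects up to ~0.65 raw matched fraction against
the 160 bp 5.8S reference, but its score stays near 0.1 of the maximum,
whereas genuine anchors — even with a 30 bp internal deletion or a few
percent divergence — score ≥ 0.7. The penalized measure therefore
separates the two regimes with a wide margin at the unchanged 0.5 floor.

The aligned 5.8S span is extended by any unaligned reference stubs so that
terminal substitutions (trimmed off by a local alignment) do not shift
boundaries. A flank anchor below its floor marks the clone *truncated* on
that side and the boundary falls at the sequence end. A 5.8S anchor below
its floor raises `DelimitError`. Clones are collapsed to distinct
haplotypes by exact sequence identity.

The packaged reference unit is **synthetic** (see §7); supply your own
`ReferenceSet` for real taxa.

## 3. Pseudogene evidence screen

Three independent criteria are computed per clone and combined by an OR
policy (configurable minimum criterion count, default 1):

**GC erosion.** GC percentage per region over unambiguous bases only.
Flagging is two-pass and within-sample: the baseline per sample and region
is the *median GC of co-sample clones whose motifs and helices are all
intact* (if none, all co-sample clones; samples with < 3 clones use the
global median). A region is flagged when its GC falls more than
`delta_pp` (default **2.0** percentage points) below the baseline. The
median-minus-delta rule operationalizes "significantly lower GC" without
assuming a distribution; excluding lesioned clones from the baseline stops
a pseudogene-rich sample from dragging its own baseline down.

**Conserved 5.8S motifs.** The three angiosperm-invariant motifs

```
M1 = CGATGAAGAACGTAGC   M2 = GAATTGCAGAATCC   M3 = TTTGAACGCA
```

are first sought as exact substrings. On a miss, the motif's span on the
reference 5.8S is projected onto the clone through a global alignment;
substitutions are reported 1-based within the motif (`nt-7,12`) and spans
falling into clone gaps as `missing 4-16` / `all missing`.

**Helix foldability.** The five conserved helices are represented by
forced base-pair blocks on the reference 5.8S (1-based, i..i+k−1 with
j..j−k+1):

```
B4 (45,105,3)  B5 (48,61,3)  B6 (69,96,3)  B7 (110,118,3)
B8 (119,142,4) + (126,135,3)
```

A helix scores `X` iff every forced pair projects onto two non-gap clone
bases forming a Watson–Crick or G·U (DNA: G·T) pair, else `-`. This
deterministic feasibility check replaces thermodynamic folding (Mfold):
the diagnostic question is "can the helix still form", which needs no
energy model, and the check is exactly reproducible. Clones whose 5.8S
aligns below 40% global identity are reported unalignable (all `-`).

## 4. Diversity statistics

A site is **variable** iff ≥ 2 distinct unambiguous bases occur (gaps and
IUPAC ambiguity codes never count as states); **parsimony-informative**
iff ≥ 2 distinct bases each occur in ≥ 2 sequences. Percentages print to
one decimal.

*k* is the mean number of pairwise differences; *Pi* the per-site mean.
Default deletion policy is **complete deletion** — every column holding a
gap or ambiguity in any sequence is excluded globally, so `Pi =
k / length_used` exactly; pairwise deletion (per-pair column sets, Pi =
mean of per-pair fractions) is available by option. The F-vs-P contrast
slices the alignment into regions (ITS1, 5.8S, ITS2, entire ITS) and
computes both classes per region; classes with < 2 members report NA.

**Simple indel coding**: each distinct gap (identical start and end)
becomes one binary character; a sequence scores 1 with exactly that gap, 0
with contiguous bases across the span, `?` when a longer or overlapping
gap obscures it. Output as TSV and as a NEXUS standard-characters block.

## 5. Recombination scan

For a (child, parent A, parent B) triplet, the **informative sites** are
the columns where the parents differ and the child matches exactly one.
The **MaxChi** statistic slides a window of `window` informative sites
(default 30, i.e. 15 each side; shrunk to the available sites), splits it
at the centre, and takes the maximum 2×2 chi-squared of (side × matched
parent), no continuity correction. Significance comes from `permutations`
(default 1000) random permutations of the match labels — the exact
exchangeability null, which automatically absorbs the maximization over
split positions; `p` is the fraction of permuted maxima ≥ the observed
one. Triplets with < 8 informative sites report "insufficient signal".
The breakpoint estimate is the alignment column midway between the
informative sites flanking the maximizing split.

The **dataset scan** tests every clone as child against all pairs of its
closest candidate parents (candidates ranked by identity; pair count
capped at 200), keeps the minimum-p pair, and Bonferroni-corrects across
children. Because a MaxChi signal belongs to the whole triplet — when a
chimera sits in a *clean* clone's best pair, the clean clone also shows a
significant breakpoint — calls are then attributed to events: a called
clone is demoted (`signal attributed to X`) when its best pair contains
another called clone with strictly greater maximum chi-squared. The
initially-called set is snapshotted first, so the outcome does not depend
on report order. Consequence: the scan is *event-level* — occasionally
the called member of an event is a true parent rather than the chimera
itself, an ambiguity inherent to the statistic.

Null calibration uses triplets of three independent lineages from one
ancestor (the child descends from a single parental lineage). A child
copied directly from parent A would give a degenerate all-one label vector
(p ≡ 1) and could not calibrate the test; the shared-ancestor null keeps
the labels i.i.d., which is the permutation null. Measured rejection at
α = 0.05 is ≈ 0.015–0.07 over 200-triplet batches.

## 6. Generator (synthetic data)

`simulate_clone_set` emits clones, ground truth, and the **exact** gapped
alignment in ancestral coordinates — possible because indels are modelled
as *deletions only* (matching the large deletions reported in decayed ITS
copies), so no external aligner is needed downstream.

| parameter | default | rationale |
|---|---|---|
| `n_samples` × `clones_per_sample` | 10 × 10 | a typical clone-library study size |
| `base_rate` | 0.005 | functional-spacer substitutions/site |
| `s58_rate_factor` | 0.075 | functional 5.8S and flanks mutate at `base_rate` × this; chosen from the observed functional-class ratio of 5.8S to spacer diversity (~0.005/0.067) |
| `pseudo_rate_multiplier` | 5.0 | relaxed constraint; makes the F-vs-P contrast qualitative, not numeric |
| `cpg_transition_bias` | 0.8 | substitutions hitting C/G in CpG/GpC context become the deamination product (C→T, G→A), eroding GC |
| `pseudo_fraction` | 0.3 | labelled pseudogene share; counts are exact (`round(n × fraction)`) |
| `recombinant_fraction` | 0.05 | chimeras spliced from two (preferably cross-sample) pseudogene donors at a recorded breakpoint |
| `indel_rate`, `deletion_mean_length` | 0.2, 8.0 | Poisson count × geometric length deletions in pseudogenes |
| `motif_lesion_prob`, `helix_lesion_prob` | 0.8, 0.6 | explicit recorded lesions (motif substitutions / non-pairing helix bases), set so that most but not all pseudogenes carry a structural lesion |

All lesion injections are recorded in the truth table
(`motif:M2:nt-7`, `helix:B8`, `deletion:301-312`), so classifier reasons
are checkable criterion-by-criterion. Sub-seeds are derived with
`numpy.random.default_rng([seed, k])`; identical parameters give
byte-identical outputs.

The defaults were fixed **a priori** from the rationale above and then
verified once: pooled over ten default runs, classifier sensitivity 0.983
and specificity 0.966; they were not adjusted afterwards.

**Scope and limits.** No coalescent genealogies, no forward simulation of
concerted evolution, no insertions, no polyploid subgenome structure; the
reference unit is synthetic (§7), so absolute GC levels and region lengths
are stylized, not taxon-realistic.

## 7. Synthetic reference unit

A 650 bp unit: 25 bp 18S/26S stubs, 230/210 bp spacers at 62% GC, and a
160 bp 5.8S (≈ 54% GC) that carries M1/M2/M3 exactly once each, in order,
and satisfies every forced helix pair by construction (the j-side base is
set to the complement of the i-side). It stands in for published
reference sequences, which cannot be redistributed here; all structural
checks hold on it exactly, which the acceptance suite exploits
(reference → `XXXXX`, every single forced-pair disruption flips exactly
its helix).

## 8. Numerical choices

- Percentages print to 1 decimal (site classes) or 2 (GC); underlying
  statistics keep full double precision, and `k`/`Pi` match an independent
  brute force to 1e-12 (acceptance criterion).
- Chi-squared uses the closed-form 2×2 formula with prefix sums; the
  permutation null is fully vectorized (`rng.permuted`), ~1000 permutations
  in milliseconds.
- GC, diversity and informative-site computations exclude ambiguity codes
  from numerators *and* denominators; similarity windows with < 50%
  comparable sites are masked.
- Default problem sizes (100-clone sets, 200-pair scan cap, 1000
  permutations) are package choices for fast, stable test statistics — not
  estimates of any real dataset.

## 9. Limitations

- Helix checks test pairing feasibility at fixed reference positions, not
  free energy; compensatory double mutations that preserve pairing are
  (correctly) not flagged, but helix *shifts* are invisible.
- The low-GC criterion is relative to co-sample clones; a sample whose
  copies are uniformly degenerate can evade it (motif/helix criteria then
  carry the verdict).
- The recombination scan is event-level (see §5) and assumes the true
  parents (or close relatives) are present in the clone set.
- Delimiting assumes the clone is in the forward orientation of the
  reference set.
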