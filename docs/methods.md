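# Methods

## Model and assumptions

`resmut` classifies binding-site mutations of a drug target by their
predicted effect on *relative* drug affinity, clonal fitness, and
mutational feasibility, then ranks the surviving mutants. The underlying
assumptions are:

- A mutation drives clinical resistance only if it (i) weakens drug
  binding *relative to* the endogenous ligand, (ii) retains endogenous
  binding (a clone whose oncoprotein loses its function does not persist
  under selection), and (iii) can plausibly be generated at the DNA level
  in the tumor type of interest.
- The affinity estimate (*K\** score) is a dimensionless ensemble quantity
  per (protein construct, ligand); absolute binding free energies are
  neither required nor computed. All downstream logic uses log10 ratios,
  so any common rescaling of the score tables cancels.
- Effects are local to the binding site as captured by the input scores;
  global conformational changes are outside the model.

## Wild-type statistics and the cutoff

Residue positions are evaluated individually or in pairs by the upstream
estimator, giving several wild-type scores per ligand (one per `run_id`).
`avwt` is their arithmetic mean. The per-run wild-type log-ratio for a
(drug, endogenous) pair is `r_i = log10(K*_endo,i / K*_drug,i)`, matched on
`run_id`; a run scored for only one ligand substitutes the other ligand's
`avwt` (the same substitution supplies mutant scores at positions
evaluated one-sided). `range_wt = max(r_i) − min(r_i)` is the intrinsic
variation allowance; with a single run it is exactly 0. The resistance
cutoff is `log10(avwt_endo / avwt_drug) + range_wt`, and a mutant is
resistant when its own log-ratio *strictly* exceeds it — ties are
sensitive, which is the conservative reading of "higher than".

Choices made where the procedure was genuinely open:

- **Log base.** Base 10 throughout. Any fixed base yields identical
  classifications because cutoff and mutant ratios share it.
- **avwt mean.** Arithmetic rather than geometric mean of the wild-type
  scores.
- **Unpaired WT runs.** Retained via avwt substitution rather than
  dropped, so every run contributes to `range_wt`.
- **Multiple endogenous ligands** (e.g. EGF and TGF-α for an extracellular
  target): a mutant is unfit if *any* endogenous score is 0, and resistant
  only if it clears the cutoff against *every* endogenous ligand. Both
  choices are the conservative direction.
- **Histidine protonation.** All protonation variants of a His mutant are
  grouped into one logical mutant; it is resistant only if every variant
  is resistant, and (by the same conservative AND) fit only if every
  variant binds the endogenous ligand.
- **Tied scores across runs.** A mutant scored under several `run_id`s for
  the same ligand and variant is averaged; in practice each mutant is
  scored once.
- **Catalytically essential residues** (e.g. the DFG motif, catalytic Asp
  and the Lys–Glu salt bridge of kinases) are excluded up front via the
  `excluded_residues` config list, before classification.

## Filter cascade and attrition accounting

Filters are applied in the order affinity → fitness → triple-point; each
removed mutant is attributed to the first filter that rejects it, so the
four reported fractions (three removal stages plus survivors) sum to 1
exactly. Final survivor membership is order-independent. The survivor
summary also reports the share of survivors reachable only by double-point
mutation.

## Codon feasibility

Residue → codon mapping uses `codon index = position − residue_offset`
(1-based residues, default offset 1) on the user-supplied coding-strand
CDS; the first and last codons have no flanking base and raise rather than
being padded. Feasibility is the minimum Hamming distance from the
wild-type codon to any codon of the target amino acid under the standard
genetic code (translation table 1 only): 1 = SPM, 2 = DPM, 3 = TPM
(discarded), 0 = synonymous. Path enumeration emits one path per target
codon at distance 1 or 2; a two-base path carries its changes as an
unordered pair. Mutations to Pro are handled by this module — their
absence from real score tables is an upstream-estimator limitation, which
the synthetic generator mirrors by never planting them.

## Signature probabilities and relP

The 96 trinucleotide substitution classes are pyrimidine-centered;
purine-centered queries are folded by reverse complement (an involution,
tested as such). Signature distributions are renormalized to sum to 1 on
load (warning if off by > 1e−6); per-cancer weights `c_s` are taken as an
input column and renormalized to sum to 1, with a helper that builds
`c_s = (fraction of samples with the signature) × (mean contribution to
mutational load)` when only those ingredients are available. The mixture
`pSPM = Σ c_s·x_s` therefore always sums to 1 (conservation is asserted at
1e−9).

`relP` sums path contributions over *all* 1- and 2-base paths (a
`minimal_paths_only` switch restricts to minimum-length paths for
sensitivity analysis). For a two-base path both trinucleotide contexts are
read off the wild-type sequence by default; since the two events have no
defined order, an optional `sequential` mode recomputes the second context
after applying the first change and averages over both orderings (the two
modes differ only when the changes are adjacent). relP is a relative
quantity: rankings are invariant under rescaling the whole pSPM table, and
competition ranking breaks ties deterministically by (position, mut_aa).

When no signatures are reported for the relevant cancer type (the
`cancer_type: unavailable` setting), relP is a *missing value*, not zero:
hotspots are still identified and ranked by mutant count, but prioritized
mutations carry no relP rank and are listed alphabetically.

## Hotspots and prioritization

Hotspots use competition ranking on the surviving-mutant count (1, 2, 2,
4). Prioritization keeps every hotspot ranked ≤ k — residues tied at the
k-th rank are all included rather than truncated — and the top m mutations
per retained hotspot by relP. With k = m = 3 and three untied hotspots of
at least three mutations this reproduces the canonical shortlist of nine;
with ties at rank k the shortlist can exceed k·m (the cap is per hotspot).
Hotspot prevalence is not comparable across drug-target pairs and no such
comparison is computed.

## Synthetic data generator

`FixtureSpec` defaults define the study conditions: 20 evaluated interior
residues, 3 wild-type runs with the per-run log-ratio spread bounded by
0.3 log units (a typical replicate variation allowance for one input
structure), 5 planted resistant, 2 planted unfit and 1 planted
triple-point mutant, a plant margin of 1 log unit beyond the cutoff, and a
3-signature Dirichlet mixture over the 96 classes. Wild-type scores sit
near 100 with the drug score absorbing the drawn log-ratio. Planted
resistant (and TPM) mutants get ratios at `cutoff + margin + U(0, 0.5)`,
sensitive background mutants `cutoff − margin − U(0, 0.5)`, unfit mutants
an endogenous score of 0; TPM plants draw from the precomputed list of
(codon, amino acid) pairs at Hamming distance 3 (e.g. ATG → His) and carry
resistant-level scores so they are removed exactly at the triple-point
stage. One planted resistant His mutant (when feasible) is emitted in
three protonation variants. All sampling flows from a single
`numpy.random.default_rng(seed)`, so a seed reproduces the bundle byte for
byte.

What the generator does **not** emulate: realistic *K\** magnitudes or
structural energetics, correlated noise between positions, position-pair
runs, enrichment-score normalization of experimental screens, or real
signature profiles. Passing plant-and-recover therefore demonstrates the
correctness and determinism of the cascade logic under controlled
separation, not predictive accuracy on real affinity data.

## Benchmark evaluation

`evaluate_against_labels` compares binary predictions with binary
experimental labels keyed by (position, wt_aa, mut_aa); label sets are
expected to exclude Pro and triple-point mutants, matching how
deep-mutational-scanning sets are pruned before comparison. Besides the
confusion-matrix cells and accuracy it reports `tp_rate` (fraction of
predicted-resistant mutants confirmed by experiment) and
`residue_discovery_rate` (fraction of residues with ≥ 1 experimentally
resistant mutant at which ≥ 1 mutant is predicted resistant). Label
binarization thresholds are the caller's responsibility; the evaluator
consumes binary labels only.

## Numerical choices and problem sizes

- Strict `>` at the cutoff; a drug score of 0 for a fit clone gives a
  +inf log-ratio (resistant); an endogenous score of 0 makes the mutant
  unfit regardless of the drug score.
- Attrition fractions are exact rationals of the pool size; conservation
  is asserted at 1e−12.
- The acceptance script uses 20 fixture seeds of 20 positions each plus
  one 25-position bundle with a 5/4/3 resistant layout; the exhaustive
  codon oracle covers all 61 sense codons × 20 amino acids (1220 cases).
  These sizes keep a full verification run to a few seconds while
  exercising every branch of the cascade.

## Known limitations

- Only missense point mutations realized by 1–2 base exchanges are
  modeled: no indels, no splice or transcript-level effects, no
  non-standard codon tables.
- The affinity stage is entirely score-table driven; systematic errors of
  the upstream estimator propagate unchanged.
- relP ranks are relative within one pSPM table; no per-patient absolute
  mutation probabilities are produced.
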