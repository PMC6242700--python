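# resmut

Triage of drug-target binding-site mutations into likely clinical
resistance mutations.

Targeted cancer drugs (kinase inhibitors, therapeutic antibodies) select
for tumor sub-clones carrying target mutations that weaken drug binding
while preserving the protein's native function. `resmut` implements a
multi-stage computational cascade that narrows the pool of all possible
binding-site mutations (typically several hundred per drug) down to a
shortlist of mutations most likely to emerge under treatment, for use by
structure-based drug-discovery and translational teams.

## The method

Inputs are per-mutant affinity scores (*K\** scores: ensemble-based,
dimensionless binding estimates, one table per ligand; 0 = no predicted
binding), the target's coding sequence, and cancer-type mutational-signature
data. The cascade applies three filters, then ranks what survives:

1. **Affinity.** Because residue positions are scored individually or in
   pairs, the wild-type protein has several *K\** scores per ligand; their
   mean is `avwt` and the spread (max − min) of the per-run wild-type
   log-ratios is `range_wt`, the method's intrinsic variation allowance.
   A mutant confers resistance when its log *K\** ratio (endogenous ligand
   over drug) strictly exceeds

   ```
   cutoff = log10(avwt_endogenous / avwt_drug) + range_wt
   ```

   Only relative affinity matters: the classification is invariant under
   rescaling all scores by a common factor. Histidine mutants are scored
   in all protonation states and called resistant only if every state
   clears the cutoff; with several endogenous ligands every one must
   clear its cutoff.
2. **Fitness.** Mutants with a *K\** score of 0 for any endogenous ligand
   lose their native function and are discarded, never reported resistant.
3. **Codon feasibility.** Amino-acid exchanges requiring all three codon
   bases to change (triple-point mutations) are discarded; single- and
   double-point exchanges are kept.
4. **Hotspots and relP.** Survivors are grouped per residue; residues with
   many surviving mutants are *resistance hotspots*, ranked by mutant count
   with competition ranks (ties share a rank). Mutations at the top `k`
   hotspots are then prioritized by their relative probability of being
   generated in the relevant cancer type,

   ```
   pSPM(class) = Σ_s c_s · x_s(class)            (signature mixture)
   relP        = Σ_paths pSPM₁ [· pSPM₂]         (over all 1-/2-base codon paths)
   ```

   where `x_s` are the 96-class trinucleotide signature distributions and
   `c_s` the renormalized per-cancer signature weights. The default
   `k = 3` hotspots × `m = 3` top-relP mutations yields a shortlist of
   about nine candidates per drug — small enough for experimental
   follow-up.

## Worked example

The package ships a synthetic-bundle generator with planted ground truth
that emulates the full input stack (score tables, CDS, signatures):

```python
from resmut import FixtureSpec, generate_fixture, RunConfig, run_pipeline

spec = FixtureSpec(seed=21, resistant_layout=(5, 4, 3), n_positions=25)
outdir = generate_fixture(spec).write("demo")
result = run_pipeline(RunConfig.from_yaml("demo/config.yaml"))
```

which prints (via the summary fields):

```
pool 34: affinity 0.56, unfit 0.06, tpm 0.03, surviving 0.35
cutoff = -0.0155 + 0.1781 = 0.1626
rank 1: S6 with 5 mutants: S6G(relP rank 1), S6C(relP rank 2), S6F(relP rank 3), ...
rank 2: C12 with 4 mutants: C12S(relP rank 1), C12I(relP rank 2), ...
rank 3: N14 with 3 mutants: N14Y(relP rank 1), N14M(relP rank 2), N14A(relP rank 3)
prioritized: S6G, S6C, S6F, C12S, C12I, C12A, N14Y, N14M, N14A
```

Of 34 evaluated mutants, 56% fail the affinity cutoff, 6% abrogate
endogenous binding (unfit), 3% would require triple codon changes, and 35%
are predicted resistant; the three hotspots are the planted 5/4/3-mutant
residues and the default 3×3 prioritization shortlists nine mutations.

The same workflow is available from the shell:

```
resmut simulate --seed 7 --out demo
resmut run --config demo/config.yaml --out-dir demo/out
resmut evaluate --predictions demo/out/mutants.tsv --labels labels.tsv
```

`run` writes `mutants.tsv` (per-mutant verdicts and the filter stage that
removed each), `attrition.json`, `hotspots.json`/`hotspots.tsv`, and a
`manifest.json` with the configuration hash; identical configurations
produce byte-identical outputs.

## Scope

The package consumes affinity scores; it does not run the structure-based
estimator that produces them, prepare crystal structures, or curate
clinical mutation databases. Hotspot prevalence is comparable within one
drug-target pair, not across pairs. See `docs/methods.md` for model
details, parameter defaults, and limitations.
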