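# blockcoal

Blockwise-SFS demographic inference for a pair of diploid genomes (one
individual per species).

The pipeline:

1. **Tabulate** — partition intergenic regions (BED) into fixed-length
   blocks (default 200 bp), classify every biallelic VCF site into the four
   folded mutation types (heterozygous unique to either species, shared
   heterozygous, fixed difference), drop blocks violating the four-gamete
   criterion, and tally the blockwise joint site-frequency-spectrum (bSFS)
   configurations.
2. **Fit** — compute exact per-block configuration probabilities under 13
   divergence / isolation-with-migration / admixture-pulse scenarios via a
   count-augmented structured-coalescent Markov chain, maximise the
   linkage-corrected composite likelihood per model (seeded multi-start
   Nelder-Mead), and rank models by AIC.
3. **Scale** — convert dimensionless estimates to effective population
   sizes, split times and migration rates under mutation-rate /
   generation-time calibrations; compute genome-wide π, dxy and FST.
4. **Simulate** — a structured-coalescent simulator generates synthetic
   genotype fixtures (VCF/BED/FASTA) under known parameters and doubles as
   the Monte-Carlo oracle validating the analytic likelihood.

## Conventions

* Time is measured in units of `2·Ne_ref` generations with the ancestral
  population as the reference size class; deme sizes are relative
  (`c = Ne_deme / Ne_ref`, ancestor fixed at 1).
* `theta_block` is the expected number of mutations per block per unit
  branch length, i.e. `theta_block = 2·Ne_ref·mu·block_len`; the implied
  per-site diversity is `2·theta_block / block_len = 4·Ne_ref·mu`.
* Gene-flow directions are forward in time (`B->V` = gene flow from
  species B into species V); backwards in time this moves sampled lineages
  from V into B.
* Configurations are ordered `(het_b, het_v, shared_het, fixed_diff)`
  everywhere; probabilities are truncated at `k_max` (default 3) with a
  lumped `> k_max` category per class.

## CLI

```bash
# synthetic fixture under the best-model class (two sizes, IM B->V)
blockcoal simulate --model-id M3.3 --t-split 1.0 --c-x 0.4 --m 0.5 \
    --theta-block 0.6 --n-blocks 5000 --seed 1 --outdir out/sim

# tabulate the bSFS (four-gamete filter on by default)
blockcoal tabulate --vcf out/sim/fixture.vcf --bed out/sim/fixture.bed \
    --outdir out/tab

# fit models and rank by AIC; linkage correction: lnCL / 1000 by default,
# or fit a pre-thinned tally with --linkage-mode thin
blockcoal fit --tally out/tab/tally.tsv --models all --k-max 3 \
    --outdir out/fit

# genome-wide pi / dxy / FST
blockcoal summarize --vcf out/sim/fixture.vcf --bed out/sim/fixture.bed \
    --outdir out/sum
```

Every subcommand writes a `manifest.json` (resolved configuration, config
hash, package version) and a `run.log`; identical seeds and inputs
reproduce outputs bit-for-bit.  Exit codes: 0 success, 2 input/validation
error, 3 numerical failure.

## Layout

```
src/blockcoal/
  models.py      demographic scenarios (DIV / IM / ADM, size classes)
  simulate.py    structured-coalescent simulator + fixture writer
  tabulate.py    BED/VCF -> blocks -> folded mutation types -> tally
  likelihood.py  analytic configuration probabilities + MC oracle
  inference.py   13-model grid, composite-likelihood fits, AIC table
  summaries.py   pi/dxy/FST, unit scaling, generation length
  cli.py         simulate / tabulate / fit / summarize subcommands
```
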