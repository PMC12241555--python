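# demosmc

Simulation-based inference of out-of-Africa demographic history from
cross-population site frequency spectra (cSFS), with a focus on the Papua
New Guinean settlement models, plus relative cross-coalescent rate (RCCR)
curves computed from true simulated genealogies.

The pipeline:

1. **demography** — five competing demographic models (`A`, `O`, `M`,
   `AX`, `OX`: PNG as sister group of East Asians, as outgroup of
   Europeans+East Asians, and ghost-admixture variants), parameterized by
   24 quantities (12 effective sizes, 10 chained time intervals, 2 archaic
   admixture fractions; +2 ghost parameters for M/AX/OX), with uniform
   prior boxes and an interval→event chaining convention.
2. **simulate** — chunked msprime simulation and VCF export (AA-annotated,
   with a sample→population map).
3. **sfs** — 6-dimensional joint SFS (canonical shape 11×11×11×11×3×3 =
   131,769 cells) and the concatenated pairwise cSFS (15 pairs,
   6×121 + 8×33 + 9 = 999 entries), from simulated chunks or from VCF.
4. **inference** — a seedable NumPy MLP (256/128/64/32 ReLU, input noise +
   dropout, Adam/Nadam, log-cosh or cross-entropy) summarizing cSFS rows,
   with rejection ABC on the network outputs: model posteriors, Bayes
   factors, goodness-of-fit p-values, parameter posteriors with 95%
   credible intervals.
5. **smc** — sequential Monte Carlo refinement: each cycle simulates from
   the current prior box, retrains the regressor, runs ABC, and shrinks
   the box to the posterior range, while the simulated sequence length
   grows along a schedule (canonically 100 Mb → 500 Mb → 1.5 Gb → 3 Gb,
   desk-scalable).
6. **rccr** — time-binned pair-coalescence hazards (λ₀, λ₁, λ₀₁) from true
   genealogies and RCCR = 2λ₀₁/(λ₀+λ₁), including the minimal
   three-population bottleneck/growth grid.
7. **synthetic_data** — pseudo-observed cSFS replicates with known truth
   (three disjoint 5-diploid subsets of 15 simulated diploids per modern
   population), toy VCF fixtures, and classifier-confusion sweeps.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (one test per
criterion). Criteria 5 and 7 are stochastic/scaled-down experiments with
pre-registered seeds; their docstrings state the known caveats.

## CLI

```sh
demosmc simulate --model A --length 1000000 --seed 1 --out runs/sim
demosmc csfs --vcf runs/sim/simulated.vcf \
    --popmap runs/sim/simulated.popmap.txt \
    --callable-length 1000000 --out runs/csfs
demosmc fixtures --kind pseudo --length 5000000 --seed 2 --out runs/obs
demosmc train-classify --n-per-model 60 --length 1000000 --seed 3 --out runs/net
demosmc classify --observed runs/obs/pseudo_observed.tsv \
    --network-dir runs/net --out runs/choice
demosmc estimate --observed runs/obs/pseudo_observed.tsv \
    --observed-length 5000000 --scale 0.00002 --n-sims 200 \
    --seed 4 --out runs/est
demosmc rccr --length 20000000 --samples 10 --repetitions 3 --seed 5 \
    --out runs/rccr
```

Every command writes a JSON run manifest (seeds, config, paths) next to
its outputs.

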