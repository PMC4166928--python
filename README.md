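# mitoclock

Tools for calibrating the human mitochondrial molecular clock with ancient
genomes: a tested, desk-scale pipeline for comparing **root-, node- and
tip-based calibration** of Bayesian substitution-rate and divergence-time
estimates from heterochronous whole-mtDNA alignments.

## The problem

The human mtDNA substitution rate has been estimated with calibrations
anchored at very different places in the tree: the human–chimpanzee split at
the root, archaeologically dated colonization events at internal nodes, or —
since radiocarbon-dated ancient genomes became available — the sampling ages
of the tips themselves. These strategies disagree, and teasing apart why
requires running all of them through one statistical machine on one data
set. `mitoclock` implements that machine:

- **Synthetic heterochronous panels** (`mitoclock.simulate`): serial
  coalescent genealogies under constant-size or exponential-growth
  demography Ne(t) = N₀·e^(−g·t), partitioned sequence evolution
  (JC/HKY/GTR + discrete-Γ, per-partition rates mirroring the K = 4 mtDNA
  scheme PC1+PC2 / PC3 / HVS1+HVS2 / rRNA+tRNA), radiocarbon-style dating
  error, and postmortem deamination damage.
- **Ancient-sequence QC** (`mitoclock.qc`): deamination produces private
  C→T / G→A variants, so a damaged sequence shows an excess of
  deamination-consistent singletons. The screen classifies every singleton,
  estimates the expected fraction from the modern sequences, and applies an
  exact binomial test per ancient tip (Bonferroni-corrected), plus a
  per-class GC-content comparison.
- **Partitioned pruning likelihood** (`mitoclock.likelihood`): Felsenstein
  pruning with per-pattern scaling, strict or uncorrelated-lognormal (UCLN)
  relaxed clocks, and a postmortem-damage (PMD) correction in which the
  probability that a site of an ancient tip escaped damage decays
  exponentially with sample age: an observed T admits a true C with weight
  q = 1 − e^(−δ·age) (and A admits G).
- **Bayesian dating engine** (`mitoclock.mcmc`, `.calibration`,
  `.coalescent`, `.diagnostics`, `.marginal`): Metropolis–Hastings over
  rates, node ages, calibrated tip ages, demography and δ; tip priors
  normal(age, radiocarbon SE), node priors normal(mean, 20% of mean) on
  MRCA ages, an offset-lognormal root prior (offset 5 My, mean 6 My, 97.5%
  quantile 7.5 My), flat bounds elsewhere; HPD/ESS posterior summaries;
  path-sampling and stepping-stone marginal likelihoods for Bayes factors.
- **Comparison layer** (`mitoclock.compare`): scenario orchestration,
  individual-calibration sweeps with HPD-overlap and variance-ratio
  statistics, the date-randomization test of temporal signal, root-to-tip
  regression, the Penny–Hendy bipartition distance between topologies, and
  pairwise-TMRCA cross-comparisons (e.g. strict vs relaxed clock R²).

## Worked example

```python
import numpy as np
from mitoclock import (CalibrationSpec, DemographicModel, MCMCSettings,
                       SubstitutionModelSpec, mcmc_run)
from mitoclock.io import SiteAnnotation
from mitoclock.mcmc import default_partitions
from mitoclock.simulate import simulate_genealogy, simulate_alignment
from mitoclock.io import SampleClass, SampleRecord

# a 40-tip panel: 25 contemporary + 15 radiocarbon-dated ancient tips
panel = [SampleRecord(f"m{i}", 0, 0, SampleClass.modern) for i in range(25)]
panel += [SampleRecord(f"a{i}", age, 0.025 * age, SampleClass.ancient_AMH)
          for i, age in enumerate(np.linspace(2500, 40000, 15))]

demo = DemographicModel()                     # exp growth, N0=10,000, g=2.5e-5/y
tree = simulate_genealogy(panel, demo, seed=11)
hky = SubstitutionModelSpec(model="HKY", kappa=22.0,
                            pi=(0.309, 0.313, 0.131, 0.247))
ann = SiteAnnotation(["other"] * 4000)
aln = simulate_alignment(tree, ann, {"all": (hky, 2.143e-8)}, seed=2)

cal = CalibrationSpec(                        # tip calibration, point ages
    tip_priors={s.sample_id: s.age_mean for s in panel if s.is_ancient},
    node_age_bounds=(0.0, 50e6), bound_all_internal_nodes=False)
res = mcmc_run(aln, ann, panel, cal,
               MCMCSettings(steps=120_000, burn_in=24_000, thin=50, seed=3),
               partitions=default_partitions(2e-8, spec=hky),
               start_tree=tree, demography=demo)
p = res.summary["rate"]
print(f"rate mean {p.mean:.3g}, 95% HPD ({p.hpd_lower:.3g}, {p.hpd_upper:.3g})")
```

This prints (seeds as above):

```
rate mean 2.36e-08, 95% HPD (1.57e-08, 3.16e-08)
```

i.e. tip calibration alone recovers the simulation's whole-molecule rate of
2.143 × 10⁻⁸ substitutions/site/year inside the 95% highest-posterior-density
interval, with the precision a 4-kb, 40-tip panel supports.

A CLI wraps the same steps: `mitoclock simulate`, `qc`, `date`, `compare`,
`randomize`, `loglik` (every stochastic subcommand takes `--seed`).

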