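# endotraits

Functional-trait and phylogenetic-signal analysis of fungal culture
collections.

Culture-based studies of plant-associated fungi (e.g. foliar endophytes of
grasses) commonly phenotype hundreds of isolates on Biolog phenotype
microarrays — 95 carbon substrates plus a water control, read as optical
density (OD590) — and place the same isolates on a phylogeny from barcode
sequences. `endotraits` turns those two inputs into the standard analysis
chain for such collections:

1. **Plate scoring.** Standardized growth = well OD590 − water-control
   OD590; values below 0.005 (the photometric accuracy of plate readers)
   count as no growth. Derived per isolate: binary resource use, niche
   width (number of resources used), and mean standardized growth over the
   "common" resources (those used by ≥ 50% of isolates), over all
   resources, and over only the isolate's own resources (growth
   efficiency).
2. **Assemblage classification.** Mean growth in these collections is
   bimodal. A two-component Gaussian mixture (own EM, unequal variances)
   is fitted and the slow/fast cutoff is the equal-posterior point
   *w₁φ(x; μ₁, σ₁) = w₂φ(x; μ₂, σ₂)* between the component means.
3. **Group statistics.** Welch/Student t-tests, the Fligner–Killeen test
   for niche-width variance, per-taxon Fisher exact tests of slow/fast
   composition (row vs pooled remainder, Holm-adjusted, rows with n ≤ 5
   flagged NA), and OTU richness per leaf by isolation method.
4. **Phylogenetic signal.** Blomberg's K per resource,

   K = (MSE₀/MSE) / E_BM[MSE₀/MSE],  with
   MSE₀ = (x−â1)ᵀ(x−â1)/(n−1), MSE = (x−â1)ᵀC⁻¹(x−â1)/(n−1),
   E_BM = [tr C − n/(1ᵀC⁻¹1)]/(n−1), â = 1ᵀC⁻¹x / 1ᵀC⁻¹1,

   where C is the phylogenetic covariance matrix (shared root-to-MRCA
   path lengths). K = 1 under Brownian motion; K > 1 means the trait is
   more conserved than BM predicts. Significance comes from a one-tailed
   random-tips permutation null (default 999 shuffles,
   p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1)), run on the entire tree and
   on class/order subtrees (polytomies randomly resolved, pruning
   preserves patristic distances). BM trait simulation is included for
   calibration and synthesis.
5. **Synthetic data.** A generator produces a full study — Yule
   phylogeny, nested taxonomy, clade-structured slow/fast assemblages,
   plate readings, leaf/method metadata — with ground truth, so the whole
   chain is testable without any external data.

## Worked example

```python
from endotraits import (CommunitySpec, simulate_community,
                        build_trait_table, fit_mixture, assign)

com = simulate_community(CommunitySpec(seed=1))     # 240 isolates, 95 resources
values = build_trait_table(com.plate).summary["mean_sg_common"]
fit = fit_mixture(values, seed=0)
labels = assign(values, fit.cutoff).labels
```

prints (see `examples/03_classify_assemblages.py`):

```
slow component: mean 0.034 sd 0.032 weight 0.37
fast component: mean 0.273 sd 0.138 weight 0.63
cutoff (equal posterior): 0.094 OD590
assemblage counts: {'slow': 102, 'fast': 138}; accuracy vs truth 95.4%
```

The two component means sit at the generator's slow (0.04 ± 0.03) and
fast (0.29 ± 0.14) growth parameters, the cutoff falls in the valley
between the modes, and 95% of isolates are assigned to their generating
assemblage. `examples/` holds one short script per capability
(simulation, plate scoring, classification, phylogenetic signal, group
statistics, full pipeline); each prints the numbers it computes and what
they mean.

The same chain is available from the shell:

```sh
endotraits simulate --seed 1 --out-dir data/
endotraits all --plate data/plate.csv --metadata data/metadata.csv \
    --tree data/tree.nwk --taxonomy data/taxonomy.csv --out-dir results/
```

which writes the trait table, mixture report, assemblage assignments,
stats/Fisher/signal tables, and a manifest with seeds and input checksums.

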