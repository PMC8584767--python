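# climvuln

Tools for measuring population vulnerability to climate extremes at the
regional level, combining three stages that are usually studied apart:

1. **Extreme-climate indices** (`climvuln.climate`) — reduce daily
   tmax/tmin/precipitation series to seven Climdex-style indicators per
   region: TXx, TNx, TX90p, TN90p, DTR, CDD and R99p, then code each
   into cross-region quintile categories.
2. **Homoclimatic zoning** (`climvuln.gom`) — a Bayesian Grade of
   Membership (mixed-membership) model fit by Gibbs sampling groups
   regions into K latent extreme-climate profiles.  Each region i holds
   memberships g_ik on the simplex; each profile k has multinomial
   response probabilities λ_kjl over the L categories of index j, with
   cell probability P(Y_ijl = 1) = Σ_k g_ik λ_kjl and a Dirichlet
   membership prior reparameterized as (ξ, α₀), where ξ_k = α_k/α₀ are
   expected profile proportions and α₀ controls membership spread.
   Regions are classified into extreme (g ≥ 0.90), high-mixed
   (0.75 ≤ g < 0.90) and medium-mixed (0.50 ≤ g < 0.75) tiers, and
   mixed tiers are reclassified to their dominant extreme zone.
3. **Vulnerability index** (`climvuln.ecvi`) — a weighted Alkire-Foster
   dual-cutoff index over 18 indicators in three equally weighted
   dimensions (exposure, susceptibility, adaptive capacity).  With
   deprivation score c_i = Σ_j w_j · flag_ij and population weights,

       CH   = Σ_i pop_i · 1[c_i ≥ k_p] / Σ_i pop_i
       DI   = Σ_i pop_i · c_i · 1[c_i ≥ k_p] / Σ_i pop_i · 1[c_i ≥ k_p]
       ECVI = CH × DI

   with exact decompositions by subgroup (ECVI = Σ_g (n_g/n)·ECVI_g),
   by indicator (ECVI = Σ_j w_j·CH_j) and by dimension, bootstrap or
   linearization standard errors, and cutoff diagnostics
   (`climvuln.kp`): sensitivity/dominance curves over the k_p grid, a
   forward-local-variance optimum and a CH/DI intersection advisory.

A synthetic-study generator (`climvuln.synthetic`) produces daily
weather from two latent regimes (rain-extreme vs drought/heat-extreme),
regime-linked social indicators and Poisson disease counts with known
ground truth, so the whole pipeline is testable end to end.  The
`climvuln.pipeline` module and the `climvuln` CLI orchestrate all
stages, including stratification of regions by infectious-disease
hospitalization rates (quintile 1 = low incidence, quintiles 4–5 =
high).

## Worked example

```bash
climvuln run-all --profile fast --seed 7 --iters 1000 --burnin 500 --out demo/
```

runs the full pipeline on a small synthetic study (30 regions, 3 years
of daily weather) and prints

```
overall ECVI=0.2851 (CH=0.4835, DI=0.5896) at k_p=0.25; outputs in demo/
```

meaning 48.4% of the (population-weighted) regions are deprived in at
least 25% of the weighted indicators, those regions are deprived in
59.0% of the weighted indicators on average, and the adjusted index is
the product, 0.285.  `demo/ecvi.csv` holds the same statistics by
homoclimatic zone with bootstrap standard errors:

```
  group  k_p   ECVI     CH     DI  SE_ECVI  SE_CH  SE_DI
overall 0.25 0.2851 0.4835 0.5896   0.0651 0.1097 0.0278
  ED-HT 0.25 0.5354 0.9080 0.5896   0.0468 0.0707 0.0266
     ER 0.25 0.0000 0.0000 0.0000   0.0000 0.0000 0.0000
```

— the synthetic drought/heat zone is built worse-off, and the index
concentrates there.  `demo/decomposition_dimension.csv` splits the
index into dimension contributions (here 29.9% exposure, 40.6%
susceptibility, 29.5% adaptive capacity), `demo/kp_curves.csv` traces
ECVI/CH/DI over the cutoff grid, and `demo/kp_report.json` records the
forward-local-variance optimum (0.20 here) next to the chosen cutoff
and the vulnerable share at each.  Other subcommands (`make-synthetic`,
`climate-indices`, `fit-gom`, `compute-ecvi`, `kp-scan`) expose the
individual stages; every run writes a manifest so that config + seed
reproduce it byte for byte.

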