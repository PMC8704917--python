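# pollinet

Bipartite plant–pollinator network analysis centred on a mass-flowering
focal crop and its co-flowering community: who shares pollinators with the
crop, whether that sharing exceeds what abundance alone predicts, how the
network decomposes into modules, which species hold the network together,
and which species can indirectly influence which others through shared
visitors.

The package is written for community ecologists working with visitation
surveys: long-format records of who visited whom, where and when, pooled
into a plants × pollinators count matrix `α_ik` with row totals `R_i`,
column totals `C_k` and grand total `F`.

## What it computes

* **Composition distances** — Bray–Curtis dissimilarity between plants'
  pollinator faunas, `d = 1 − 2Σ_k min(x_k, y_k)/(Σx + Σy)`, and a one-way
  distance-based PERMANOVA (McArdle–Anderson pseudo-F with a seeded
  label-permutation p-value) across plant functional groups.
* **Abundance-resampling null for sharing** — each plant's `R_i` visitation
  events are redrawn from the community-wide pollinator abundance
  distribution `p_k = C_k/F`; 1000 replicates give a 95% percentile
  envelope of each plant's distance to the focal plant, classifying it as
  more similar than chance, within chance, or more dissimilar.
* **Modularity** — Barber's bipartite modularity
  `Q = (1/F) Σ_{i,k} (α_ik − R_i C_k/F) δ(m_i, m_k)`, optimized by weighted
  label propagation with Q-gain moves and module-merge refinement, best of
  N seeded restarts.
* **Species roles** — Olesen-style within-module degree `z` and
  among-module connectivity `c = 1 − Σ_t (k_st/k_s)²`, with thresholds set
  objectively as the 95% quantiles of c and z over fixed-margin (Patefield)
  null networks, classifying species as peripheral, connector, module hub
  or network hub.
* **Müller index** — potential indirect influence of acting species j on
  target species i of the same trophic level via shared partners,
  `d_ij = Σ_k (α_ik/R_i)(α_jk/C_k)`; each target row sums to 1 and the
  matrix is asymmetric.
* **Synthetic communities** — lognormal species abundances with multinomial
  visitation sampling, either neutral (abundance-driven pairing) or with
  planted trait-affinity modules, so every stage is testable with known
  ground truth.

## Worked example

```bash
python analysis/01_simulate.py 1
python analysis/02_network_summary.py
python analysis/04_sharing_null.py 1
python analysis/05_modules_roles.py 1
```

prints, among other lines:

```
neutral: 2000 interactions, 20 plants, 29 pollinators
  most visited plant: plant_011 (31.5%); most active pollinator: poll_015 (18.0%, visits 20 plant species)
neutral (focal plant_011): within_null = 19, more_dissimilar_than_null = 1
modular (focal plant_021): more_dissimilar_than_null = 28, within_null = 11, more_similar_than_null = 1
  plants outside the focal module flagged more dissimilar than chance: 93.3%
modularity Q = 0.676 with 4 modules (4 planted); NMI with planted modules = 1.000
role thresholds (0.95 quantile of 200 Patefield nulls): plants c = 0.831, z = 1.660; pollinators c = 0.828, z = 1.803
```

Reading this: on the neutral community — where visitation is driven purely
by abundance — 19 of 20 plants sit inside the 95% null envelope, i.e. their
similarity to the focal plant is what chance sampling of abundant
pollinators produces. On the trait-structured community the same test
flags 93% of the plants outside the focal plant's module as more dissimilar
than chance, the module detector recovers the four planted modules exactly
(NMI = 1), and the null-derived role thresholds sit near c ≈ 0.83, the
characteristic value for strongly skewed degree distributions.

The same stages are available as a CLI (`pollinet simulate|summarize|
compose|null-sharing|modules|roles|mueller|run`) and as a config-driven
pipeline (`pollinet run config.yaml`) that writes a JSON manifest with
per-stage derived seeds for bit-identical reruns.

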