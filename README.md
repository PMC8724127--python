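# hubrank

Rank-based, group-level hubness analysis of structural brain connectomes.

Network-neuroscience studies routinely ask which cortical regions are *hubs*
— highly connected, topologically central nodes — and how to aggregate the
connectomes of many subjects into one population-level answer. `hubrank`
implements a full pipeline for that question, aimed at researchers working
with tractography-derived connectivity matrices:

- **Sub-parcellation**: atlas parcels are split into similar-size, spatially
  compact ROIs by k-means on voxel coordinates, with `k = voxels // 400`
  (parcels under 400 voxels are not split), so node-by-node comparisons are
  not confounded by parcel size.
- **Network construction**: from a streamline endpoint table, edge weights
  are `w_ij = n_ij * (1/L_ij) * (2/(V_i + V_j))` where `n_ij` counts the
  streamlines ending in ROIs *i* and *j*, `L_ij` is their mean length (a
  correction for the long-fiber bias of deterministic tractography) and
  `V_i, V_j` are ROI sizes in voxels.
- **Node measures**: degree, strength, k-core coreness, betweenness (as a
  fraction of shortest paths, in [0, 1]) and closeness (reciprocal summed
  BFS distance); strength on the weighted graph, the rest on the binarized
  graph.
- **Ranking and hubness**: nodes are ranked per measure (rank 1 = top;
  degree values (50, 20, 30, 40, 10) rank as (1, 4, 3, 2, 5)); rankings are
  compared with Spearman's `rho = 1 - 6 Σd_i² / (n(n²-1))`; the composite
  **hubness** score of a node is the mean of its five measure ranks.
- **Group aggregation**: *aggregate-then-measure* (ATM: average the
  matrices, then measure and rank) versus *measure-then-aggregate* (MTA:
  rank within each subject, then average ranks per node), compared by
  *representation power* — the mean Spearman correlation of the group
  ranking with each subject's own.
- **Population analyses**: sample-size curves, consistent hubs (top 20% in
  all five measures), hemispheric asymmetry of homologous parcels (paired
  Wilcoxon, p < 0.01, plus a 5% rank margin) and intraparcel heterogeneity.
- **Synthetic populations**: a generator of subject-level connectomes with
  planted hubs, injectable left/right asymmetry and within-parcel
  gradients, so every stage is testable without imaging data.

## Worked example

```python
import hubrank as hr

# a synthetic population: 50 subjects, 200 nodes, planted hubs + noise
gen = hr.generate_population(hr.PopulationSpec(seed=1))
pop = gen.population

mta = hr.aggregate_mta(pop, "degree")
atm = hr.aggregate_atm(pop, "degree")
print(hr.representation_power(mta, pop).mean)  # 0.8263
print(hr.representation_power(atm, pop).mean)  # 0.1203

hubs = hr.top_consistent_hubs(pop, quantile=0.20, node_table=gen.node_table)
print(len(hubs["hub_rois"]), hubs["hemisphere_counts"])  # 27 {'L': 14, 'R': 13}
```

The MTA group ranking correlates with the individual subjects' degree
rankings far better (0.83) than the ATM ranking computed on the averaged
connectome (0.12): averaging matrices first unions each subject's spurious
edges into a densified aggregate whose ranking no longer resembles any
subject. The consistent-hub set (top 20% in all five measures) recovers the
planted hubs, split nearly evenly between the hemispheres.

The same pipeline runs from the shell:

```bash
hubrank simulate --subjects 50 --seed 1 --out-dir pop/
hubrank aggregate --pop-dir pop/ --method mta --measure hubness --out-prefix out/mta
hubrank asymmetry --pop-dir pop/ --out-prefix out/asym
```

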