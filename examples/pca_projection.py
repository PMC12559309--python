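"""PCA of a reference panel with least-squares projection of a heavily
missing pseudo-haploid sample.

Fits principal components on complete modern-like individuals and projects
a low-coverage target onto the PC1-PC2 plane, the standard way of placing
an ancient genome among reference populations without letting its
missingness distort the axes.
"""

import numpy as np

from paleoadmix import genodata, pcaproj, simulate

N_SNPS = 10_000
graph = simulate.three_source_graph(n_snps=N_SNPS)
snps = simulate.uniform_snp_map(N_SNPS, graph.chrom_lengths_m, seed=0)
freqs = simulate.simulate_frequencies(graph, seed=10)
panel = simulate.simulate_panel(
    graph, freqs, snps, n_per_pop=12, seed=11,
    populations=["Jomon_like", "Kamchatka_like", "Amur_like"],
)
model = pcaproj.fit_pca(panel, n_components=2)

# a 50/50 Jomon x Kamchatka pseudo-haploid target at 1x coverage
truth, pileups = simulate.simulate_target_calls(
    graph, freqs, snps, (0.5, 0.5), simulate.SOURCES[:2], 25.0, seed=12,
    mean_cov=1.0,
)
calls = genodata.pseudo_haploid_call_all(pileups, 13)
coords = pcaproj.project_sample(model, calls)

centroids = model.coordinates.groupby("population")[["PC1", "PC2"]].mean()
print("reference population centroids:")
print(centroids.round(2).to_string())
print(f"\nprojected target: PC1={coords[0]:.2f} PC2={coords[1]:.2f}")
print(
    "\nThe target lands between its two source centroids and far from the"
    "\nthird population, despite ~60% missing genotypes."
)
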