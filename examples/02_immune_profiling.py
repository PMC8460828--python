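"""Score the tumor-immune microenvironment and test group differences.

Simulates a cohort in which 9p21-loss tumors carry a depressed latent
infiltration factor, scores ten immune/stromal populations by marker-gene
means, and compares LOSS vs WT with Wilcoxon + Benjamini-Hochberg.
"""

from ninep21.profiling import (
    differential_abundance,
    marker_abundance_scores,
    ssgsea_scores,
    tcr_diversity,
)
from ninep21.simulate import SimulationConfig, bundled_gene_sets, generate_cohort

cohort = generate_cohort(SimulationConfig(n_samples=400, seed=2))
markers = bundled_gene_sets("markers")

scores = marker_abundance_scores(cohort.expression, markers)
diff = differential_abundance(
    scores, cohort.ground_truth["genotype"], ("LOSS", "WT"))
print(diff.round(4).to_string(index=False))
# log2_fc < 0 means the population is depleted in 9p21-loss tumors; with the
# default generator every immune population is driven by the latent factor,
# so all features show negative fold changes at small q.

pathways = bundled_gene_sets("pathways")
ssgsea = ssgsea_scores(cohort.expression, pathways)
print(ssgsea.scores.iloc[:, :3].round(3))
# per-sample rank-based enrichment of immune pathways (normalized by the
# global max-min); higher = more active pathway in that sample.

div = tcr_diversity(cohort.clonotypes)
truth = cohort.ground_truth
for g in ("WT", "LOSS"):
    ids = truth.index[truth["genotype"] == g]
    print(g, "mean TCR Shannon entropy:", round(div.loc[ids, "shannon"].mean(), 3))
# lower entropy in LOSS reflects the reduced repertoire diversity the
# generator couples to the infiltration factor.
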