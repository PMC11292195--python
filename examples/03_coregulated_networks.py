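"""Discover coregulated protein networks by consensus clustering.

Three latent programs induce three blocks in the protein-protein Pearson
similarity matrix; consensus clustering should choose k = 3, SigClust
should call the split significant, and the per-sample cluster scores
should associate with the clinical labels that drive the programs.
"""

from ecmnet.networks import (associate_scores, cluster_median_scores, consensus_cluster,
                             correlation_similarity, sigclust)
from ecmnet.synthetic import SyntheticCohortSpec, generate_cohort, synthetic_catalog
from ecmnet.annotations import filter_matrix

# annotated_background_fraction=0 keeps the filtered matrix to the three
# coregulated programs, so the network structure is clean three-block
spec = SyntheticCohortSpec(n_samples=200, seed=3, annotated_background_fraction=0.0)
matrix, clinical, truth = generate_cohort(spec)
filtered = filter_matrix(matrix, synthetic_catalog(spec))

sim = correlation_similarity(filtered)
result = consensus_cluster(sim, k_range=range(2, 7), n_resamples=200, seed=3)
print(f"chosen k = {result.chosen_k}  (PAC per k: "
      + ", ".join(f"{k}:{v:.3f}" for k, v in result.pac.items()) + ")")

sig = sigclust(filtered.data.T.fillna(filtered.data.T.mean()), n_sim=300, seed=3)
print(f"SigClust p = {sig['p_value']:.4f}  (cluster index {sig['cluster_index']:.3f})")

scores = cluster_median_scores(filtered, result.assignments)
assoc = associate_scores(scores, clinical)
print("\ngrade association (Mann-Whitney, grade 2 vs 3, DES excluded):")
print(assoc["grade"][["cluster", "direction", "p_value"]].to_string(index=False))
# A low PAC at k=3 plus a tiny SigClust p says the three coregulated
# networks are real structure, not noise; the grade test shows which
# network tracks tumor grade (the ECM-regulator-like program by design).
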