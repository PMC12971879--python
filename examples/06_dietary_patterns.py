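"""PCA of the dietary indices and k-means dietary-pattern clustering.

The first principal component separates the inflammatory index from the
three diet-quality indices; k-means on the PCA scores groups subjects into
dietary behaviour patterns, with the cluster count suggested by the elbow of
the within-cluster sum of squares.
"""

from diet2gut import (
    CohortConfig,
    generate_cohort,
    kmeans_fit,
    kmeans_scan,
    pca_decompose,
    score_all,
    select_k_elbow,
)

_, intake, groups, *_ = generate_cohort(CohortConfig(n_dyads=104, seed=7))
scores = score_all(intake, groups)

pca = pca_decompose(scores[["dii", "mmds", "hei", "dqi"]], standardize=True)
total = pca.variance_explained.sum()
print("variance explained:",
      [f"{v / total:.1%}" for v in pca.variance_explained])
print("\nPC1 loadings (note the DII sign opposing the quality indices):")
print(pca.loadings["PC1"].round(3).to_string())

wss = kmeans_scan(pca.scores, range(1, 11), seed=7)
k_elbow = select_k_elbow(wss)
clusters = kmeans_fit(pca.scores, 3, seed=7)
print(f"\nelbow suggests k = {k_elbow}; clustering with k = 3")
print("cluster sizes:", clusters.labels.value_counts().sort_index().to_dict())
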