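"""Build the geographic predictors for the downstream models.

Planar Euclidean distances between the 15 population coordinates (decimal
degrees), PCNM spatial eigenvectors of the truncated distance matrix, and
the population -> region lookup.  The first two PCNM axes serve as the
continuous "geographic distance" predictor in the per-feature models.
"""

from pathlib import Path

from plantmet import feature_table as ft
from plantmet import spatial

PRE = Path("results/preprocessed")
OUT = Path("results/spatial")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    leaf_meta = ft.read_metadata(PRE / "leaf_metadata.tsv")
    pops = leaf_meta.groupby("population")[["latitude", "longitude"]].first()
    dist = spatial.euclidean_distance(pops)
    axes = spatial.pcnm(dist)
    dist.to_frame().to_csv(OUT / "population_distances.tsv", sep="\t")
    axes.to_frame().to_csv(OUT / "pcnm_axes.tsv", sep="\t")
    regions = leaf_meta.groupby("population")["region"].first()
    regions.to_csv(OUT / "population_regions.tsv", sep="\t")
    print(f"{len(pops)} sites; truncation distance {axes.truncation:.4f} deg; "
          f"{axes.scores.shape[1]} positive PCNM axes "
          f"(eigenvalues {axes.eigenvalues[:2].round(3).tolist()} ...)")


if __name__ == "__main__":
    main()
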