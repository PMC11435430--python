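"""Quantify differentiation and diversity between the five predefined
populations: pairwise Weir–Cockerham Fst and Nei's unbiased distance with
10,000-permutation Bonferroni-corrected p-values, per-population allelic
richness / expected heterozygosity / PIC, and a PCA of all accessions.

Reads results/dataset/, writes tables (and a PC1-PC2 scatter) under
results/structure/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pearsnp import (
    diversity_table,
    filter_loci,
    pairwise_analysis,
    pca_genotypes,
    read_population_table,
    read_vcf,
)
from pearsnp.clustering import plot_pca


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", default="results/dataset")
    parser.add_argument("--outdir", default="results/structure")
    parser.add_argument("--n-perm", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    matrix = read_vcf(Path(args.data_dir) / "genotypes.vcf")
    populations = read_population_table(Path(args.data_dir) / "populations.csv")
    filtered, _ = filter_loci(matrix)

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    diversity = diversity_table(filtered, populations)
    diversity.to_csv(out / "diversity_by_population.csv", index=False)
    print("per-population diversity (A, He, PIC):")
    print(diversity.round(3).to_string(index=False))

    square, tidy = pairwise_analysis(
        filtered, populations, n_perm=args.n_perm, seed=args.seed
    )
    square.to_csv(out / "pairwise_fst_nei.csv")
    tidy.to_csv(out / "pairwise_tests.csv", index=False)
    print("\npairwise matrix (Fst upper triangle, Nei D lower triangle):")
    print(square.round(3).to_string())
    sig = tidy[tidy["p_bonferroni"] < 0.001]
    print(
        f"\n{len(sig)}/{len(tidy)} pairs significant at p < 0.001 "
        f"(Bonferroni, {args.n_perm} permutations)"
    )

    scores, explained = pca_genotypes(filtered)
    pd.DataFrame(
        {"accession_id": filtered.accessions, "PC1": scores[:, 0], "PC2": scores[:, 1]}
    ).to_csv(out / "pca_scores.csv", index=False)
    print(
        f"PCA: PC1 explains {100 * explained[0]:.1f}%, "
        f"PC2 {100 * explained[1]:.1f}% of total variance"
    )
    plot_pca(scores, explained, populations, filtered.accessions, str(out / "pca.png"))


if __name__ == "__main__":
    main()
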