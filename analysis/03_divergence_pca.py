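"""Differentiation and ordination of the simulated populations.

Computes the pairwise Hudson F_ST matrix between parental replicates at the
time of admixture and the PCA of parental allele frequencies across
generations, then tracks the movement of each mixture toward its immigrant
founder in PC space.  Writes results/divergence/.
"""

import argparse
import json
from pathlib import Path

from pleiocost import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--rundir", type=Path, default=Path("results/run"))
    ap.add_argument("--outdir", type=Path, default=Path("results/divergence"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    result = pipeline.analyze(args.rundir, pipeline.AnalysisParams(seed=args.seed))
    fst = result["fst_110"]
    fst.to_csv(args.outdir / "fst_parental_110.tsv", sep="\t")
    print("mean pairwise F_ST between parents at generation 110:")
    print(fst.round(3).to_string())

    pca = result["pca_parental"]
    pca.coordinates.to_csv(args.outdir / "pca_parental.tsv", sep="\t")
    evr = ", ".join(f"PC{i+1} {v:.1%}" for i, v in enumerate(pca.explained_variance_ratio))
    print(f"\nparental PCA explained variance: {evr}")

    moves = {}
    for label, pr in result["pairs"].items():
        d = pr["pca_dist_to_immigrant"]
        moves[label] = d
        pr["pca"].coordinates.to_csv(
            args.outdir / f"pca_{label.replace('->', '_')}.tsv", sep="\t")
        print(f"pair {label}: distance to immigrant founder "
              f"F1 {d['F1']:.2f} -> F20 {d['F20']:.2f} -> F29 {d['F29']:.2f}")
    (args.outdir / "pca_movement.json").write_text(json.dumps(moves, indent=1))


if __name__ == "__main__":
    main()
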