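#!/usr/bin/env python
"""Fit the chemometric models on the simulated metabolite table.

PCA for overview, OPLS-DA for the class-predictive axis, VIP scores,
S-plot statistics and label-permutation validation; writes scores, VIP and
S-plot tables under results/.
"""

from pathlib import Path

import pandas as pd

from macsnet.datatypes import MetaboliteTable
from macsnet.multivariate import (compute_vip, fit_oplsda, fit_pca,
                                  permutation_validate, s_plot)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 11


def main():
    table = MetaboliteTable.from_tsv(RESULTS / "inputs" / "metabolite_table.tsv")
    pca = fit_pca(table, 2)
    opls = fit_oplsda(table, n_orthogonal=1)
    vip = compute_vip(opls)
    perm = permutation_validate(table, n_permutations=100, seed=SEED)

    pd.DataFrame({
        "pca1": pca.scores[:, 0], "pca2": pca.scores[:, 1],
        "opls_predictive": opls.scores[:, 0],
        "opls_orthogonal": opls.ortho_scores[:, 0],
        "group": table.groups.to_numpy(),
    }, index=table.sample_ids).to_csv(RESULTS / "02_scores.tsv", sep="\t",
                                      index_label="sample_id")
    pd.Series(vip, name="vip").sort_values(ascending=False).to_csv(
        RESULTS / "02_vip.tsv", sep="\t", index_label="metabolite_id")
    pd.DataFrame(
        [(m, cv, cr) for m, (cv, cr) in s_plot(opls, table).items()],
        columns=["metabolite_id", "covariance", "correlation"],
    ).to_csv(RESULTS / "02_splot.tsv", sep="\t", index=False)

    print(f"PCA explained variance: {pca.explained_variance.round(3).tolist()}")
    print(f"OPLS-DA R2X={opls.r2x:.3f} R2Y={opls.r2y:.3f} Q2={opls.q2:.3f}")
    print(f"permutation validation ({perm.n_permutations} permutations): "
          f"valid={perm.valid} "
          f"(max permuted R2Y={perm.permuted_r2y.max():.3f}, "
          f"Q2={perm.permuted_q2.max():.3f})")


if __name__ == "__main__":
    main()
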