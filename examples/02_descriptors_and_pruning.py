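"""Compute physicochemical descriptors and prune the matrix for modeling.

Featurizes the embedded drug-like molecules (2D set only for speed),
removes near-zero-variance and highly correlated columns (|r| >= 0.85,
the lower-variance member of each pair goes), and standardizes for the
kernel-model path.
"""

from cypscreen import (
    compute_descriptors,
    fixture_records,
    prune_correlated,
    prune_low_variance,
    standardize,
)

records = fixture_records(druglike_only=True)
matrix, rejects = compute_descriptors(records, include_3d=False)
print(f"{matrix.data.shape[0]} molecules x {matrix.data.shape[1]} descriptors "
      f"({len(rejects)} rejected)")

matrix, nzv = prune_low_variance(matrix)
matrix, corr = prune_correlated(matrix, r_cut=0.85)
print(f"pruning: {len(nzv.removed)} near-zero-variance, "
      f"{len(corr.removed)} correlated columns removed -> "
      f"{matrix.data.shape[1]} survive")
ex = corr.removed[0]
print(f"example removal: {ex['column']} (r = {ex['r']:+.3f} with {ex['partner']})")

scaled, params = standardize(matrix)
print(f"standardized: column means ~ {scaled.data.mean().abs().max():.2e}, "
      f"sds ~ {scaled.data.std(ddof=1).mean():.6f}")
# Every surviving column pair now has |Pearson r| < 0.85; the scaling
# parameters (means/sds) are what an SVM bundle will carry along.
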