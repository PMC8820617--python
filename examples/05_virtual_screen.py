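"""Run the full virtual-screening cascade on a synthetic drug library.

Trains the RF + SVM pair on synthetic fixtures, then screens a library:
consensus prediction (both models must call "inhibitor"), the strict
-8.5 kcal/mol per-conformation IE filter, two-stage diversity clustering
of the surviving hits (structural keys at 0.80, then path fingerprints at
0.70 over stage-1 centroids), and per-cluster candidate selection.
"""

from cypscreen import (
    CompoundRecord,
    FixtureSpec,
    HyperGrid,
    fixture_records,
    gen_descriptor_table,
    gen_ie_profiles,
    run_screen,
    standardize,
    train_rf,
    train_svm_rbf,
)

spec = FixtureSpec(effect_size=3.0, seed=42)
matrix, labels = gen_descriptor_table(spec)
rf_bundle, _ = train_rf(matrix, labels, HyperGrid(ntree=(100,), mtry=(5,)),
                        cv=(5, 1), seed=42)
scaled, params = standardize(matrix)
svm_bundle, _ = train_svm_rbf(scaled, labels, params,
                              HyperGrid(costs=(1.0,), sigma_multipliers=(1.0,)),
                              cv=(5, 1), seed=42)

# screening library: fixture chemistry attached to the synthetic descriptor rows
mols = fixture_records(druglike_only=True)
library = [CompoundRecord(id=i, smiles=mols[k % len(mols)].smiles)
           for k, i in enumerate(matrix.ids)]
profiles = gen_ie_profiles(matrix.ids, labels, spec)

report = run_screen(library, matrix, rf_bundle, svm_bundle, profiles,
                    threshold=-8.5)
c = report.counts
print(f"cascade: {c['library']} library -> {c['consensus']} consensus "
      f"(RF AND SVM) -> {c['prioritized']} prioritized (IE < -8.5 in all 7) "
      f"-> {c['selected']} diverse candidates")
print(f"clustering: {report.clustering.get('stage1_clusters')} stage-1 clusters "
      f"@0.80 (MACCS), {report.clustering.get('stage2_clusters')} stage-2 "
      "clusters @0.70 (path)")
print(f"selected candidate ids: {report.selected_ids[:10]}"
      + (" ..." if len(report.selected_ids) > 10 else ""))
# Counts shrink monotonically along the cascade; the selected ids are one
# centroid per final cluster (plus extra maximally dissimilar picks from
# clusters with more than 10 members).
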