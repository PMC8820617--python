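"""Curate a raw activity table into a labeled, diverse modeling set.

Builds a small activity table from the embedded molecule set, assigns
inhibitor / non-inhibitor labels from AC50 and %-inhibition evidence,
applies the soft drug-like filter, deduplicates, keeps diversity-cluster
centroids at Tanimoto 0.85, and draws the stratified 80/20 split.
"""

import tempfile
from pathlib import Path

from cypscreen import (
    AMBIGUOUS,
    assign_label,
    centroid_records,
    deduplicate,
    diversity_cluster,
    fixture_molecules,
    parse_activity_table,
    soft_druglike_filter,
    stratified_split,
)

# synthesize an activity file: even rows get potent AC50s (inhibitors),
# odd rows get low %-inhibition at 50 uM (non-inhibitors)
rows = ["id,smiles,ac50_um,pct_inhib_at_50um,source"]
for i, (rid, smi) in enumerate(fixture_molecules()):
    if i % 2 == 0:
        rows.append(f"{rid},{smi},{0.5 + 0.4 * i},,pubchem")
    else:
        rows.append(f"{rid},{smi},,{i % 10},chembl")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "activities.csv"
    path.write_text("\n".join(rows) + "\n")
    records, rejects = parse_activity_table(path)

print(f"parsed {len(records)} records, {len(rejects)} rejects "
      f"({[r['reason'] for r in rejects]})")

labeled = [assign_label(r) for r in records]
labeled = [r for r in labeled if r.label != AMBIGUOUS]
kept, filtered = soft_druglike_filter(labeled)
print(f"labels: {sum(r.label == 'inhibitor' for r in labeled)} inhibitors / "
      f"{sum(r.label == 'non_inhibitor' for r in labeled)} non-inhibitors; "
      f"soft filter removed {len(filtered)}: "
      f"{[(r.id, r.filter_flags) for r in filtered]}")

unique, log = deduplicate(kept)
clusters = diversity_cluster(unique, cutoff=0.85)
centroids = centroid_records(unique, clusters)
split = stratified_split(centroids, fraction=0.8, seed=2022)
print(f"{len(unique)} unique structures -> {len(clusters)} diversity clusters "
      f"at 0.85 -> {len(centroids)} centroids")
print(f"split: {len(split.train_ids)} train / {len(split.test_ids)} test "
      "(per-class 80/20)")
# The reject reasons and filter flags show exactly why each molecule left
# the set; the centroid count is the size of the final modeling dataset.
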