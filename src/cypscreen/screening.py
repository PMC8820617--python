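"""Virtual-screening cascade: consensus prediction, IE filter, two-stage
diversity clustering and per-cluster candidate selection.

A library molecule is prioritized only when it survives the full cascade:
both the random-forest and the SVM model call it an inhibitor (consensus),
AND its docking score is strictly below the IE threshold for every receptor
conformation.  Prioritized hits are then clustered for chemical diversity
in two stages — structural keys at Tanimoto 0.80 over all hits, then a
path fingerprint at 0.70 over the stage-1 centroids — and experimental
candidates are drawn per final cluster, with extra maximally dissimilar
picks from unusually large clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .curation import INHIBITOR, CompoundRecord
from .errors import CypscreenError, EmptyInputError, IncompleteProfileError
from .fingerprints import ClusterAssignment, compute_fingerprint, leader_cluster, mol_from_smiles, tanimoto
from .interaction_energy import DEFAULT_IE_THRESHOLD, IEProfile, ie_pass_filter
from .training import ModelBundle, predict


@dataclass
class ScreenCandidate:
    """Per-molecule cascade flags.  Invariants: consensus = rf AND svm;
    prioritized = consensus AND ie_pass."""

    id: str
    rf_positive: bool
    svm_positive: bool
    consensus: bool = field(init=False)
    ie_pass: bool = False
    prioritized: bool = field(init=False, default=False)
    stage1_cluster: int | None = None
    stage2_cluster: int | None = None

    def __post_init__(self) -> None:
        self.consensus = self.rf_positive and self.svm_positive


@dataclass
class ScreenReport:
    candidates: list[ScreenCandidate]
    counts: dict[str, int]
    clustering: dict
    selected_ids: list[str]

    def __post_init__(self) -> None:
        c = self.counts
        order = ["library", "consensus", "prioritized"]
        vals = [c[k] for k in order if k in c]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"cascade counts must be non-increasing, got {c}")


def consensus_predict(
    rf_bundle: ModelBundle, svm_bundle: ModelBundle, matrix
) -> list[ScreenCandidate]:
    """Flag each molecule by both models; consensus = both say inhibitor."""
    rf_labels, _ = predict(rf_bundle, matrix)
    svm_labels, _ = predict(svm_bundle, matrix)
    ids = list(matrix.data.index) if hasattr(matrix, "data") else list(matrix.index)
    return [
        ScreenCandidate(id=str(i), rf_positive=r == INHIBITOR, svm_positive=s == INHIBITOR)
        for i, r, s in zip(ids, rf_labels, svm_labels)
    ]


def prioritize(
    candidates: list[ScreenCandidate],
    profiles: list[IEProfile],
    threshold: float = DEFAULT_IE_THRESHOLD,
) -> list[ScreenCandidate]:
    """Apply the per-conformation IE filter on top of the consensus.

    Every consensus candidate must have a complete IE profile — a missing
    docking run is surfaced as an error, never treated as a silent fail.
    Non-consensus molecules are never prioritized regardless of IE.
    """
    by_id = {p.molecule_id: p for p in profiles}
    for cand in candidates:
        profile = by_id.get(cand.id)
        if cand.consensus:
            if profile is None:
                raise IncompleteProfileError(f"no IE profile for consensus candidate {cand.id!r}")
            cand.ie_pass = ie_pass_filter(profile, threshold)
        else:
            cand.ie_pass = profile is not None and profile.complete and ie_pass_filter(profile, threshold)
        cand.prioritized = cand.consensus and cand.ie_pass
    return candidates


def cluster_hits(
    records: list[CompoundRecord],
    stage1_cutoff: float = 0.80,
    stage2_cutoff: float = 0.70,
    stage1_fingerprint: str = "maccs",
    stage2_fingerprint: str = "path",
) -> tuple[list[ClusterAssignment], list[ClusterAssignment]]:
    """Two-stage diversity clustering of prioritized hits.

    Stage 1 clusters all hits on structural keys; stage 2 re-clusters only
    the stage-1 centroids on a path fingerprint, yielding the final cluster
    structure candidates are drawn from.
    """
    if not records:
        raise EmptyInputError("no prioritized hits to cluster")
    by_id = {r.id: r for r in records}
    ids = [r.id for r in records]
    fps1 = [_fp(by_id[i], stage1_fingerprint) for i in ids]
    stage1 = leader_cluster(ids, fps1, stage1_cutoff, fingerprint_kind=stage1_fingerprint)
    centroid_ids = [c.centroid_id for c in stage1]
    fps2 = [_fp(by_id[i], stage2_fingerprint) for i in centroid_ids]
    stage2 = leader_cluster(centroid_ids, fps2, stage2_cutoff, fingerprint_kind=stage2_fingerprint)
    return stage1, stage2


def _fp(record: CompoundRecord, kind: str):
    mol = mol_from_smiles(record.smiles)
    if mol is None:
        raise CypscreenError(f"{record.id}: invalid structure in screening set")
    return compute_fingerprint(mol, kind)


def select_candidates(
    clusters: list[ClusterAssignment],
    records: list[CompoundRecord],
    large_cluster_min: int = 10,
    members_per_pick: int = 15,
    fingerprint: str = "path",
) -> list[str]:
    """One pick (the centroid) per cluster; large clusters yield extras.

    Clusters with more than ``large_cluster_min`` members contribute
    ceil(size / members_per_pick) picks; picks beyond the centroid are
    chosen greedily to maximize the minimum Tanimoto distance to the picks
    already made, spreading the selection over the cluster's chemistry.
    Set ``large_cluster_min`` to None for strictly one pick per cluster.
    """
    if not clusters:
        raise EmptyInputError("no clusters to select candidates from")
    by_id = {r.id: r for r in records}
    selected: list[str] = []
    for cluster in clusters:
        size = len(cluster.member_ids)
        if large_cluster_min is not None and size > large_cluster_min:
            n_picks = min(size, math.ceil(size / members_per_pick))
        else:
            n_picks = 1
        picks = [cluster.centroid_id]
        if n_picks > 1:
            fps = {i: _fp(by_id[i], fingerprint) for i in cluster.member_ids}
            pool = [i for i in cluster.member_ids if i != cluster.centroid_id]
            while len(picks) < n_picks and pool:
                # max-min: farthest remaining member from current picks
                best = max(
                    pool,
                    key=lambda i: (min(1 - tanimoto(fps[i], fps[p]) for p in picks), i),
                )
                picks.append(best)
                pool.remove(best)
        selected.extend(picks)
    return selected


def run_screen(
    library: list[CompoundRecord],
    matrix,
    rf_bundle: ModelBundle,
    svm_bundle: ModelBundle,
    profiles: list[IEProfile],
    threshold: float = DEFAULT_IE_THRESHOLD,
    exclude_ids: set[str] | None = None,
    stage1_cutoff: float = 0.80,
    stage2_cutoff: float = 0.70,
) -> ScreenReport:
    """Full cascade on a drug library; ``exclude_ids`` removes molecules
    already known to inhibit the target before prediction."""
    exclude = exclude_ids or set()
    library = [r for r in library if r.id not in exclude]
    keep_ids = [r.id for r in library]
    uncovered = [i for i in keep_ids if i not in matrix.data.index]
    if uncovered:
        raise CypscreenError(
            f"{len(uncovered)} library molecule(s) missing from the descriptor "
            f"matrix: {uncovered[:10]}"
        )
    sub = matrix.data.loc[keep_ids]
    candidates = consensus_predict(rf_bundle, svm_bundle, type(matrix)(data=sub))
    candidates = prioritize(candidates, profiles, threshold)
    hits = [c for c in candidates if c.prioritized]
    by_id = {r.id: r for r in library}
    selected: list[str] = []
    clustering: dict = {
        "stage1_cutoff": stage1_cutoff,
        "stage2_cutoff": stage2_cutoff,
        "stage1_fingerprint": "maccs",
        "stage2_fingerprint": "path",
    }
    if hits:
        hit_records = [by_id[c.id] for c in hits]
        stage1, stage2 = cluster_hits(hit_records, stage1_cutoff, stage2_cutoff)
        s1_of = {m: c.cluster_id for c in stage1 for m in c.member_ids}
        s2_of = {m: c.cluster_id for c in stage2 for m in c.member_ids}
        for c in hits:
            c.stage1_cluster = s1_of.get(c.id)
            c.stage2_cluster = s2_of.get(c.id)
        selected = select_candidates(stage2, hit_records)
        clustering["stage1_clusters"] = len(stage1)
        clustering["stage2_clusters"] = len(stage2)
    counts = {
        "library": len(candidates),
        "consensus": sum(c.consensus for c in candidates),
        "prioritized": len(hits),
        "selected": len(selected),
    }
    return ScreenReport(
        candidates=candidates, counts=counts, clustering=clustering, selected_ids=selected
    )


def write_screen_report(report: ScreenReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "rf_positive", "svm_positive", "consensus", "ie_pass", "prioritized",
             "stage1_cluster", "stage2_cluster", "picked"]
        )
        picked = set(report.selected_ids)
        for c in report.candidates:
            w.writerow(
                [c.id, int(c.rf_positive), int(c.svm_positive), int(c.consensus),
                 int(c.ie_pass), int(c.prioritized),
                 "" if c.stage1_cluster is None else c.stage1_cluster,
                 "" if c.stage2_cluster is None else c.stage2_cluster,
                 int(c.id in picked)]
            )
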