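"""Molecular fingerprints, Tanimoto similarity, and leader clustering.

Diversity clustering throughout the pipeline is sphere-exclusion (leader)
clustering on bit fingerprints: each cluster is the set of molecules within a
Tanimoto similarity cutoff of its centroid, and centroids are pairwise below
the cutoff.  The original curation workflow used a proprietary fragment
fingerprint; here the open stand-ins are an RDKit path fingerprint ("path"),
a Morgan circular fingerprint ("morgan"), and the 166-bit MACCS structural
keys ("maccs").  The fingerprint kind is recorded on every cluster assignment
so downstream reports stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import EmptyInputError

FINGERPRINT_KINDS = ("path", "morgan", "maccs")


@dataclass
class ClusterAssignment:
    """One sphere-exclusion cluster.

    Invariants: ``centroid_id`` is a member; every member has Tanimoto
    similarity >= ``similarity_cutoff`` to the centroid; clusters of one run
    partition the input ids.
    """

    cluster_id: int
    member_ids: list[str]
    centroid_id: str
    similarity_cutoff: float
    fingerprint: str = "path"

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its own cluster")


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse SMILES, returning None on failure (RDKit logs suppressed)."""
    return Chem.MolFromSmiles(smiles)


def compute_fingerprint(mol: Chem.Mol, kind: str = "path"):
    """Bit fingerprint of the requested kind for one molecule."""
    if kind == "path":
        gen = _path_generator()
    elif kind == "morgan":
        gen = _morgan_generator()
    elif kind == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}; expected one of {FINGERPRINT_KINDS}")
    return gen.GetFingerprint(mol)


_GENERATORS: dict[str, object] = {}


def _path_generator():
    if "path" not in _GENERATORS:
        _GENERATORS["path"] = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
    return _GENERATORS["path"]


def _morgan_generator():
    if "morgan" not in _GENERATORS:
        _GENERATORS["morgan"] = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return _GENERATORS["morgan"]


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def similarity_matrix(fps: list) -> list[list[float]]:
    """Dense symmetric pairwise Tanimoto matrix (small n only)."""
    n = len(fps)
    sim = [[1.0] * n for _ in range(n)]
    for i in range(n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        for k, s in enumerate(row):
            j = i + 1 + k
            sim[i][j] = s
            sim[j][i] = s
    return sim


def leader_cluster(
    ids: list[str],
    fps: list,
    cutoff: float,
    fingerprint_kind: str = "path",
    order: str = "neighbors",
) -> list[ClusterAssignment]:
    """Deterministic sphere-exclusion clustering.

    ``order`` controls centroid candidate order: "neighbors" processes
    molecules by descending count of neighbors at >= cutoff similarity (ties
    broken by ascending id), which favors centroids in dense regions;
    "input" keeps the given order.  Each unassigned candidate becomes a
    centroid and absorbs every still-unassigned molecule within the cutoff.
    """
    if not ids:
        raise EmptyInputError("cannot cluster an empty input set")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("similarity cutoff must lie strictly between 0 and 1")
    if len(ids) != len(fps):
        raise ValueError("ids and fingerprints differ in length")

    n = len(ids)
    sim = similarity_matrix(fps)
    if order == "neighbors":
        neigh = [sum(1 for j in range(n) if j != i and sim[i][j] >= cutoff) for i in range(n)]
        cand = sorted(range(n), key=lambda i: (-neigh[i], ids[i]))
    elif order == "input":
        cand = list(range(n))
    else:
        raise ValueError(f"unknown order policy {order!r}")

    assigned = [False] * n
    clusters: list[ClusterAssignment] = []
    for i in cand:
        if assigned[i]:
            continue
        members = [i] + [j for j in cand if j != i and not assigned[j] and sim[i][j] >= cutoff]
        for j in members:
            assigned[j] = True
        clusters.append(
            ClusterAssignment(
                cluster_id=len(clusters),
                member_ids=[ids[j] for j in members],
                centroid_id=ids[i],
                similarity_cutoff=cutoff,
                fingerprint=fingerprint_kind,
            )
        )
    return clusters
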