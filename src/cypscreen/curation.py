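"""Dataset curation: activity parsing, labeling, drug-like filtering,
deduplication, diversity clustering, and the stratified train/test split.

The curation path mirrors the standard assembly of a CYP inhibition QSAR
set: compounds with AC50 (or IC50) <= 10 uM are inhibitors, compounds with
less than 10% inhibition at 50 uM (and no qualifying AC50) are
non-inhibitors, everything else is ambiguous and excluded from modeling.
A deliberately "soft" physicochemical filter keeps diverse drug-like
chemistry (looser than Lipinski; PAINS/toxicophores are retained unless
asked otherwise, since reactive compounds can be genuine CYP inhibitors).
Duplicate structures are merged by canonical SMILES; structures duplicated
with conflicting labels are dropped outright rather than guessed at.
Finally sphere-exclusion clustering at Tanimoto 0.85 keeps only cluster
centroids, and a per-class 80/20 split yields train and external test sets.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger

from .errors import EmptyInputError, LabelConflictError, SchemaError
from .fingerprints import ClusterAssignment, compute_fingerprint, leader_cluster, mol_from_smiles

RDLogger.DisableLog("rdApp.*")

INHIBITOR = "inhibitor"
NON_INHIBITOR = "non_inhibitor"
AMBIGUOUS = "ambiguous"

AC50_INHIBITOR_MAX_UM = 10.0     # AC50/IC50 <= 10 uM -> inhibitor
PCT_INHIB_NONINHIBITOR_MAX = 10.0  # < 10% inhibition at 50 uM -> non-inhibitor


@dataclass
class CompoundRecord:
    """One molecule with structure, activity evidence and provenance."""

    id: str
    smiles: str
    source: str = "other"
    ac50_um: float | None = None
    pct_inhib_at_50um: float | None = None
    label: str = AMBIGUOUS
    filter_flags: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ac50_um is not None and not self.ac50_um > 0:
            raise ValueError(f"{self.id}: ac50_um must be positive, got {self.ac50_um}")
        if self.pct_inhib_at_50um is not None and not 0 <= self.pct_inhib_at_50um <= 100:
            raise ValueError(
                f"{self.id}: pct_inhib_at_50um must lie in [0, 100], got {self.pct_inhib_at_50um}"
            )
        if not self.sources:
            self.sources = [self.source]


@dataclass
class FilterConfig:
    """Bounds of the soft drug-like filter.  None disables a bound.

    Defaults are intentionally loose: the goal is to discard clearly
    non-drug-like chemistry (peptides, detergents, polymers) while keeping
    the broad chemical space CYP enzymes actually bind.
    """

    mw_min: float | None = 100.0
    mw_max: float | None = 800.0
    logp_min: float | None = -4.0
    logp_max: float | None = 8.0
    hbd_max: int | None = 7
    hba_max: int | None = 14
    rotatable_bonds_max: int | None = 20
    tpsa_max: float | None = 250.0
    remove_pains: bool = False

    def __post_init__(self) -> None:
        for lo, hi, name in ((self.mw_min, self.mw_max, "mw"), (self.logp_min, self.logp_max, "logp")):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{name}: min bound {lo} exceeds max bound {hi}")


@dataclass
class SplitSpec:
    """A reproducible stratified train/test partition."""

    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


# ---------------------------------------------------------------------------
# activity table parsing

_MANDATORY = ("id", "smiles")
_OPTIONAL = ("source", "ac50_um", "pct_inhib_at_50um")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def parse_activity_table(
    path: str | Path, schema: dict[str, str] | None = None
) -> tuple[list[CompoundRecord], list[dict]]:
    """Read a delimited activity table into compound records.

    ``schema`` maps logical field names (id, smiles, source, ac50_um,
    pct_inhib_at_50um) to column names in the file; by default the logical
    names themselves are expected as headers.  Rows that cannot become valid
    records are returned in a rejects list with a reason, never dropped
    silently.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path} is empty")
    schema = dict(schema or {})
    for k in _MANDATORY + _OPTIONAL:
        schema.setdefault(k, k)

    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    header = reader.fieldnames or []
    missing = [schema[k] for k in _MANDATORY if schema[k] not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}; header was {header}")

    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    for lineno, row in enumerate(reader, start=2):
        rid = (row.get(schema["id"]) or "").strip()
        smi = (row.get(schema["smiles"]) or "").strip()
        reason = None
        if not rid:
            reason = "missing_id"
        elif not smi or mol_from_smiles(smi) is None:
            reason = "smiles_parse"
        ac50 = pct = None
        if reason is None:
            try:
                ac50 = _opt_float(row.get(schema["ac50_um"]))
                pct = _opt_float(row.get(schema["pct_inhib_at_50um"]))
                rec = CompoundRecord(
                    id=rid,
                    smiles=smi,
                    source=(row.get(schema["source"]) or "other").strip() or "other",
                    ac50_um=ac50,
                    pct_inhib_at_50um=pct,
                )
            except ValueError as exc:
                reason = f"invalid_activity: {exc}"
        if reason is None:
            records.append(rec)
        else:
            rejects.append({"line": lineno, "id": rid, "smiles": smi, "reason": reason})
    return records, rejects


def _opt_float(raw: str | None) -> float | None:
    if raw is None or not str(raw).strip():
        return None
    return float(raw)


# ---------------------------------------------------------------------------
# labeling


def assign_label(record: CompoundRecord) -> CompoundRecord:
    """Assign inhibitor / non_inhibitor / ambiguous from activity evidence.

    Inhibitor iff AC50 <= 10 uM (boundary inclusive).  Non-inhibitor iff
    % inhibition at 50 uM is below 10 and no qualifying AC50 exists.  When
    both rules fire on the same record the evidence is contradictory and a
    LabelConflictError is raised rather than picking a side.
    """
    if record.ac50_um is None and record.pct_inhib_at_50um is None:
        raise ValueError(f"{record.id}: no activity evidence to label from")
    potent = record.ac50_um is not None and record.ac50_um <= AC50_INHIBITOR_MAX_UM
    inactive = (
        record.pct_inhib_at_50um is not None
        and record.pct_inhib_at_50um < PCT_INHIB_NONINHIBITOR_MAX
    )
    if potent and inactive:
        raise LabelConflictError(
            f"{record.id}: AC50 {record.ac50_um} uM implies inhibitor but "
            f"{record.pct_inhib_at_50um}% inhibition at 50 uM implies non-inhibitor"
        )
    if potent:
        label = INHIBITOR
    elif inactive:
        label = NON_INHIBITOR
    else:
        label = AMBIGUOUS
    return replace(record, label=label)


# ---------------------------------------------------------------------------
# soft drug-like filter

# loose PAINS-like electrophile/toxicophore alerts, applied only on request
_ALERT_SMARTS = {
    "alert_nitro": "[N+](=O)[O-]",
    "alert_acyl_halide": "C(=O)[Cl,Br,I]",
    "alert_michael_acceptor": "C=CC(=O)[C,c]",
    "alert_azo": "N=N",
}
_ALERT_PATTERNS = {k: Chem.MolFromSmarts(v) for k, v in _ALERT_SMARTS.items()}


def _violations(mol: Chem.Mol, cfg: FilterConfig) -> list[str]:
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    flags = []
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    checks = [
        ("mw_min", cfg.mw_min is not None and mw < cfg.mw_min),
        ("mw_max", cfg.mw_max is not None and mw > cfg.mw_max),
        ("logp_min", cfg.logp_min is not None and logp < cfg.logp_min),
        ("logp_max", cfg.logp_max is not None and logp > cfg.logp_max),
        ("hbd_max", cfg.hbd_max is not None and rdMolDescriptors.CalcNumHBD(mol) > cfg.hbd_max),
        ("hba_max", cfg.hba_max is not None and rdMolDescriptors.CalcNumHBA(mol) > cfg.hba_max),
        (
            "rotb_max",
            cfg.rotatable_bonds_max is not None
            and rdMolDescriptors.CalcNumRotatableBonds(mol) > cfg.rotatable_bonds_max,
        ),
        ("tpsa_max", cfg.tpsa_max is not None and rdMolDescriptors.CalcTPSA(mol) > cfg.tpsa_max),
    ]
    flags = [name for name, bad in checks if bad]
    if cfg.remove_pains:
        flags += [name for name, pat in _ALERT_PATTERNS.items() if mol.HasSubstructMatch(pat)]
    return flags


def soft_druglike_filter(
    records: list[CompoundRecord], config: FilterConfig | None = None
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Partition records into (kept, rejected) by the soft property bounds.

    Every reject carries *all* violated rule names in ``filter_flags``.
    """
    cfg = config or FilterConfig()
    kept, rejected = [], []
    for rec in records:
        mol = mol_from_smiles(rec.smiles)
        if mol is None:
            rejected.append(replace(rec, filter_flags=["smiles_parse"]))
            continue
        flags = _violations(mol, cfg)
        if flags:
            rejected.append(replace(rec, filter_flags=flags))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# deduplication


def canonical_smiles(smiles: str) -> str | None:
    mol = mol_from_smiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def deduplicate(records: list[CompoundRecord]) -> tuple[list[CompoundRecord], list[dict]]:
    """Collapse records sharing a canonical structure.

    Duplicates with the same label merge their provenance (sources and ids);
    duplicates with conflicting labels are dropped entirely — injecting a
    coin-flip label would poison training — and logged for audit.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = canonical_smiles(rec.smiles)
        if key is None:
            key = f"__unparseable__{rec.id}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    unique: list[CompoundRecord] = []
    log: list[dict] = []
    for key in order:
        grp = groups[key]
        labels = {r.label for r in grp}
        if len(labels) > 1:
            log.append(
                {
                    "action": "dropped_conflict",
                    "smiles": key,
                    "ids": [r.id for r in grp],
                    "labels": sorted(labels),
                }
            )
            continue
        first = grp[0]
        if len(grp) > 1:
            merged_sources = []
            for r in grp:
                for s in r.sources:
                    if s not in merged_sources:
                        merged_sources.append(s)
            first = replace(first, sources=merged_sources)
            log.append({"action": "merged", "smiles": key, "ids": [r.id for r in grp]})
        unique.append(first)
    return unique, log


# ---------------------------------------------------------------------------
# diversity clustering and splitting


def diversity_cluster(
    records: list[CompoundRecord],
    fingerprint: str = "path",
    cutoff: float = 0.85,
    order: str = "neighbors",
) -> list[ClusterAssignment]:
    """Sphere-exclusion clustering of compound structures at a Tanimoto cutoff."""
    if not records:
        raise EmptyInputError("no records to cluster")
    ids = [r.id for r in records]
    fps = []
    for r in records:
        mol = mol_from_smiles(r.smiles)
        if mol is None:
            raise ValueError(f"{r.id}: invalid structure reached clustering")
        fps.append(compute_fingerprint(mol, fingerprint))
    return leader_cluster(ids, fps, cutoff, fingerprint_kind=fingerprint, order=order)


def centroid_records(
    records: list[CompoundRecord], clusters: list[ClusterAssignment]
) -> list[CompoundRecord]:
    """Keep one representative (the centroid) per cluster, in cluster order."""
    by_id = {r.id: r for r in records}
    return [by_id[c.centroid_id] for c in clusters]


def stratified_split(
    records: list[CompoundRecord], fraction: float = 0.8, seed: int = 2022
) -> SplitSpec:
    """Per-class random split: round(fraction * class size) into training.

    Both classes must be present; the draw is reproducible from the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    by_class: dict[str, list[str]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r.id)
    if INHIBITOR not in by_class or NON_INHIBITOR not in by_class:
        raise ValueError("both inhibitor and non_inhibitor classes must be non-empty")

    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        n_train = int(np.floor(fraction * len(ids) + 0.5))
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return SplitSpec(train_ids=sorted(train), test_ids=sorted(test), fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str | Path) -> list[CompoundRecord]:
    """One molecule per line: ``SMILES [id]``; id defaults to MOL<n>."""
    records = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        rid = parts[1] if len(parts) > 1 else f"MOL{n}"
        records.append(CompoundRecord(id=rid, smiles=parts[0]))
    return records


def read_sdf(path: str | Path) -> list[CompoundRecord]:
    """Read a V2000 SDF; molecule name (or _Name) becomes the id."""
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for n, mol in enumerate(supplier, start=1):
        if mol is None:
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"MOL{n}"
        records.append(CompoundRecord(id=rid, smiles=Chem.MolToSmiles(mol)))
    return records


def write_curated(records: list[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label", "source", "filter_flags"])
        for r in records:
            w.writerow([r.id, r.smiles, r.label, ";".join(r.sources), ";".join(r.filter_flags)])


def write_rejects(rejects: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        if not rejects:
            fh.write("")
            return
        keys = sorted({k for r in rejects for k in r})
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for r in rejects:
            w.writerow({k: r.get(k, "") for k in keys})
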