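"""Seeded synthetic fixtures: descriptor tables with planted class signal,
matched interaction-energy profiles, an embedded drug-like molecule set,
and a mock docking scorer.

The generators emulate the statistical structure the pipeline assumes —
a minority of genuinely class-separating descriptors among pure noise, and
actives whose docking scores are shifted toward more negative (stronger)
values — so every stage is testable without any external download or
docking run.  Informative columns are drawn Normal(+/- effect_size/2, 1)
by class, noise columns Normal(0, 1) for everyone; column names carry the
planted ground truth (``inf.*`` vs ``noise.*``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import INHIBITOR, NON_INHIBITOR, CompoundRecord
from .descriptors import DescriptorMatrix
from .fingerprints import mol_from_smiles
from .interaction_energy import ConformationSet, IEProfile


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 300 actives + 300 inactives over 5 informative and 100 noise
    descriptors at a standardized class separation of 1.5 per informative
    descriptor; active IE profiles centered at -10 kcal/mol and inactive at
    -6 kcal/mol with 1 kcal/mol spread, which places the -8.5 kcal/mol
    screening threshold between the class modes.
    """

    n_active: int = 300
    n_inactive: int = 300
    n_informative: int = 5
    n_noise: int = 100
    effect_size: float = 1.5
    ie_active_mean: float = -10.0
    ie_inactive_mean: float = -6.0
    ie_sd: float = 1.0
    ie_correlation: float = 0.0  # molecule-level correlation across conformations
    seed: int = 2022

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_inactive, self.n_informative, self.n_noise) < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.ie_sd <= 0:
            raise ValueError("ie_sd must be positive")
        if not 0 <= self.ie_correlation <= 1:
            raise ValueError("ie_correlation must lie in [0, 1]")


def gen_descriptor_table(spec: FixtureSpec) -> tuple[DescriptorMatrix, list[str]]:
    """Two-class descriptor table with planted informative columns."""
    n = spec.n_active + spec.n_inactive
    p = spec.n_informative + spec.n_noise
    if n < 4 or p < 1:
        raise ValueError("need at least 4 molecules and 1 descriptor")
    rng = np.random.default_rng(spec.seed)
    labels = [INHIBITOR] * spec.n_active + [NON_INHIBITOR] * spec.n_inactive
    shift = np.array([+spec.effect_size / 2] * spec.n_active + [-spec.effect_size / 2] * spec.n_inactive)
    X = rng.standard_normal((n, p))
    X[:, : spec.n_informative] += shift[:, None]
    cols = [f"inf.{i+1}" for i in range(spec.n_informative)] + [
        f"noise.{i+1}" for i in range(spec.n_noise)
    ]
    ids = [f"act{i+1:04d}" for i in range(spec.n_active)] + [
        f"inact{i+1:04d}" for i in range(spec.n_inactive)
    ]
    df = pd.DataFrame(X, index=ids, columns=cols)
    df.index.name = "id"
    return DescriptorMatrix(data=df), labels


def gen_ie_profiles(
    ids: list[str], labels: list[str], spec: FixtureSpec
) -> list[IEProfile]:
    """Matched IE profiles: actives shifted toward stronger (more negative)
    docking scores, independently per conformation by default."""
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    confs = ConformationSet()
    rng = np.random.default_rng(spec.seed + 1)
    rho = spec.ie_correlation
    profiles = []
    for mol_id, label in zip(ids, labels):
        mean = spec.ie_active_mean if label == INHIBITOR else spec.ie_inactive_mean
        z_mol = rng.standard_normal()
        z = np.sqrt(rho) * z_mol + np.sqrt(1 - rho) * rng.standard_normal(len(confs.names))
        scores = {c: float(mean + spec.ie_sd * z[k]) for k, c in enumerate(confs.names)}
        profiles.append(IEProfile(molecule_id=mol_id, scores=scores, conformations=confs))
    return profiles


# ---------------------------------------------------------------------------
# embedded molecules

# Generic public-domain drug-like structures spanning the soft-filter bounds.
# The last three entries are deliberate negative-test cases: a long alkane
# (violates MW/rotatable-bond/logP bounds), ethanol (below the MW floor),
# and one invalid SMILES string.
_FIXTURE_SMILES: tuple[tuple[str, str], ...] = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("diclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("flurbiprofen", "CC(C(=O)O)c1ccc(cc1F)-c1ccccc1"),
    ("celecoxib", "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F"),
    ("fluconazole", "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F"),
    ("omeprazole", "COc1ccc2[nH]c(nc2c1)S(=O)Cc1ncc(C)c(OC)c1C"),
    ("losartan", "CCCCc1nc(Cl)c(CO)n1Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1"),
    ("alprazolam", "Cc1nnc2CN=C(c3ccccc3)c3cc(Cl)ccc3-n12"),
    ("haloperidol", "OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1"),
    ("risperidone", "Cc1nc2CCCCn2c(=O)c1CCN1CCC(CC1)c1noc2cc(F)ccc12"),
    ("sertraline", "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc12"),
    ("fluoxetine", "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1"),
    ("citalopram", "CN(C)CCCC1(OCc2cc(ccc21)C#N)c1ccc(F)cc1"),
    ("venlafaxine", "COc1ccc(cc1)C(CN(C)C)C1(O)CCCCC1"),
    ("bupropion", "CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1"),
    ("metoprolol", "COCCc1ccc(OCC(O)CNC(C)C)cc1"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("amlodipine", "CCOC(=O)C1=C(COCCN)NC(C)=C(C1c1ccccc1Cl)C(=O)OC"),
    ("nifedipine", "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]"),
    ("verapamil", "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC"),
    ("simvastatin", "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12"),
    ("gemfibrozil", "Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1"),
    ("glipizide", "Cc1cnc(cn1)C(=O)NCCc1ccc(cc1)S(=O)(=O)NC(=O)NC1CCCCC1"),
    ("sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"),
    ("trimethoprim", "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC"),
    ("ciprofloxacin", "OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"),
    ("chloramphenicol", "OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]"),
    ("isoniazid", "NNC(=O)c1ccncc1"),
    ("theophylline", "Cn1c2[nH]cnc2c(=O)n(C)c1=O"),
    ("zidovudine", "Cc1cn(C2CC(C2CO)N=[N+]=[N-])c(=O)[nH]c1=O"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("ketoconazole_frag", "Clc1ccc(cc1Cl)C1(Cn2ccnc2)OCCO1"),
    ("tolbutamide", "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1"),
    ("phenytoin", "O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1"),
    ("carbamazepine", "NC(=O)N1c2ccccc2C=Cc2ccccc21"),
    ("oob_long_alkane", "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC"),
    ("oob_ethanol", "CCO"),
    ("bad_smiles", "not_a_molecule"),
)


def fixture_molecules() -> list[tuple[str, str]]:
    """The embedded (id, SMILES) list; byte-stable across calls."""
    return [tuple(entry) for entry in _FIXTURE_SMILES]


def fixture_records(valid_only: bool = True, druglike_only: bool = False) -> list[CompoundRecord]:
    """Fixture molecules as compound records, optionally only the parseable
    (and in-bounds) ones."""
    records = []
    for rid, smi in fixture_molecules():
        if valid_only and mol_from_smiles(smi) is None:
            continue
        if druglike_only and rid.startswith("oob_"):
            continue
        records.append(CompoundRecord(id=rid, smiles=smi))
    return records


# ---------------------------------------------------------------------------
# mock docking


def mock_docking_scorer(record: CompoundRecord | str, conformation: str, seed: int = 2022) -> float:
    """Deterministic stand-in for a docking run: a hash-seeded score in
    [-12, -4] kcal/mol, independent-looking across conformations."""
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure {smiles!r}")
    from rdkit import Chem

    key = f"{Chem.MolToSmiles(mol)}|{conformation}|{seed}".encode()
    digest = hashlib.sha256(key).digest()
    frac = int.from_bytes(digest[:8], "big") / 2**64
    return -12.0 + 8.0 * frac


def mock_ie_profiles(records: list[CompoundRecord], seed: int = 2022) -> list[IEProfile]:
    """Complete IE profiles for a record set via the mock scorer."""
    confs = ConformationSet()
    return [
        IEProfile(
            molecule_id=r.id,
            scores={c: mock_docking_scorer(r, c, seed) for c in confs.names},
            conformations=confs,
        )
        for r in records
    ]
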