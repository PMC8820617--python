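"""Physicochemical descriptor computation, pruning and standardization.

The modeling matrix is built from an open 2D descriptor set (constitution,
lipophilicity, topology, partial-charge and surface-area terms, including
the PEOE/SlogP/SMR/EState VSA series that capture charged and hydrophobic
surface area) plus a small 3D set (inertia-moment shape descriptors and the
radius of gyration from a single embedded conformer).  Column names are
namespaced ``d2.<name>`` / ``d3.<name>``.

Before modeling, the matrix is pruned: of any column pair with
|Pearson r| >= 0.85 the lower-variance column is removed, and near-zero
variance columns (dominated by a single value) are dropped.  Kernel models
additionally require standardization to zero mean / unit variance; the
fitted means and standard deviations travel with the model so test and
screening data are transformed with the training parameters, never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Descriptors3D, GraphDescriptors, rdMolDescriptors

from .curation import CompoundRecord
from .errors import CypscreenError


@dataclass
class DescriptorMatrix:
    """Named molecules x named numeric descriptors with transform provenance.

    ``data`` is a DataFrame indexed by molecule id; values are finite reals.
    ``provenance`` records every transform applied since computation, so the
    processed matrix can be reproduced by replaying it on the raw one.
    """

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate molecule ids in descriptor matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate descriptor names")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("descriptor matrix contains NaN or infinite values")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PruneReport:
    """Columns removed by a pruning pass and why."""

    removed: list[dict] = field(default_factory=list)

    def removed_names(self) -> list[str]:
        return [r["column"] for r in self.removed]


@dataclass
class ScalingParams:
    """Per-column mean and standard deviation (ddof=1) for standardization."""

    means: pd.Series
    sds: pd.Series

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise ValueError(f"non-positive standard deviation for column(s) {bad}")


# ---------------------------------------------------------------------------
# descriptor list

_SIMPLE_2D = {
    "mw": Descriptors.MolWt,
    "heavy_atoms": Descriptors.HeavyAtomCount,
    "logp": Crippen.MolLogP,
    "mr": Crippen.MolMR,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "hbd": rdMolDescriptors.CalcNumHBD,
    "hba": rdMolDescriptors.CalcNumHBA,
    "rotb": rdMolDescriptors.CalcNumRotatableBonds,
    "rings": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "aromatic_bonds": lambda m: sum(1 for b in m.GetBonds() if b.GetIsAromatic()),
    "frac_csp3": rdMolDescriptors.CalcFractionCSP3,
    "num_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "balaban_j": GraphDescriptors.BalabanJ,
    "bertz_ct": GraphDescriptors.BertzCT,
    "hall_kier_alpha": GraphDescriptors.HallKierAlpha,
    "kappa1": GraphDescriptors.Kappa1,
    "kappa2": GraphDescriptors.Kappa2,
    "kappa3": GraphDescriptors.Kappa3,
    "chi0v": GraphDescriptors.Chi0v,
    "chi1v": GraphDescriptors.Chi1v,
    "chi2v": GraphDescriptors.Chi2v,
    "chi3v": GraphDescriptors.Chi3v,
    "chi4v": GraphDescriptors.Chi4v,
    "max_partial_charge": Descriptors.MaxPartialCharge,
    "min_partial_charge": Descriptors.MinPartialCharge,
    "max_abs_partial_charge": Descriptors.MaxAbsPartialCharge,
    "min_abs_partial_charge": Descriptors.MinAbsPartialCharge,
}

# surface-area series partitioned by partial charge / logP / MR / E-state
_SERIES_2D = (
    [f"peoe_vsa{i}" for i in range(1, 15)]
    + [f"slogp_vsa{i}" for i in range(1, 13)]
    + [f"smr_vsa{i}" for i in range(1, 11)]
    + [f"estate_vsa{i}" for i in range(1, 12)]
    + [f"vsa_estate{i}" for i in range(1, 11)]
)

_3D = {
    "pmi1": Descriptors3D.PMI1,
    "pmi2": Descriptors3D.PMI2,
    "pmi3": Descriptors3D.PMI3,
    "npr1": Descriptors3D.NPR1,
    "npr2": Descriptors3D.NPR2,
    "asphericity": Descriptors3D.Asphericity,
    "eccentricity": Descriptors3D.Eccentricity,
    "inertial_shape_factor": Descriptors3D.InertialShapeFactor,
    "radius_of_gyration": Descriptors3D.RadiusOfGyration,
    "spherocity": Descriptors3D.SpherocityIndex,
    "pbf": rdMolDescriptors.CalcPBF,
}


def descriptor_names(include_3d: bool = True) -> list[str]:
    """The fixed, ordered column set for a configuration."""
    names = [f"d2.{n}" for n in _SIMPLE_2D] + [f"d2.{n}" for n in _SERIES_2D]
    if include_3d:
        names += [f"d3.{n}" for n in _3D]
    return names


def _series_value(mol: Chem.Mol, name: str) -> float:
    base, idx = name.rstrip("0123456789"), int(name[len(name.rstrip("0123456789")):])
    fn = {
        "peoe_vsa": rdMolDescriptors.PEOE_VSA_,
        "slogp_vsa": rdMolDescriptors.SlogP_VSA_,
        "smr_vsa": rdMolDescriptors.SMR_VSA_,
    }.get(base)
    if fn is not None:
        return fn(mol)[idx - 1]
    if base == "estate_vsa":
        return getattr(Descriptors, f"EState_VSA{idx}")(mol)
    if base == "vsa_estate":
        return getattr(Descriptors, f"VSA_EState{idx}")(mol)
    raise KeyError(name)


def compute_descriptors(
    records: list[CompoundRecord],
    include_3d: bool = True,
    conformer_seed: int = 2022,
) -> tuple[DescriptorMatrix, list[dict]]:
    """Compute the full named descriptor set for every molecule.

    A molecule either yields every column or is moved to the rejects list
    (reasons: ``embed_fail`` for 3D embedding failures, ``descriptor_nan``
    when a descriptor is undefined for the structure).  Column order is
    fixed for a configuration; values are deterministic given the
    conformer seed.
    """
    cols = descriptor_names(include_3d)
    rows: dict[str, list[float]] = {}
    rejects: list[dict] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rejects.append({"id": rec.id, "reason": "smiles_parse"})
            continue
        values: list[float] = []
        try:
            for name in _SIMPLE_2D.values():
                values.append(float(name(mol)))
            for name in _SERIES_2D:
                values.append(float(_series_value(mol, name)))
        except Exception:
            rejects.append({"id": rec.id, "reason": "descriptor_error"})
            continue
        if include_3d:
            mol3d = Chem.AddHs(mol)
            params = AllChem.ETKDGv3()
            params.randomSeed = conformer_seed
            if AllChem.EmbedMolecule(mol3d, params) != 0:
                rejects.append({"id": rec.id, "reason": "embed_fail"})
                continue
            try:
                values += [float(fn(mol3d)) for fn in _3D.values()]
            except Exception:
                rejects.append({"id": rec.id, "reason": "descriptor_error"})
                continue
        if not np.isfinite(values).all():
            rejects.append({"id": rec.id, "reason": "descriptor_nan"})
            continue
        rows[rec.id] = values
    data = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    data.index.name = "id"
    return DescriptorMatrix(data=data), rejects


# ---------------------------------------------------------------------------
# pruning


def prune_correlated(
    matrix: DescriptorMatrix, r_cut: float = 0.85
) -> tuple[DescriptorMatrix, PruneReport]:
    """Remove one column of every pair with |Pearson r| >= ``r_cut``.

    Column pairs are scanned left-to-right in matrix order; when a pair of
    still-surviving columns violates the cutoff, the lower-variance member
    is removed (variance tie: the later name alphabetically).  A single pass
    guarantees the post-condition: every pair was examined while both
    members survived, so no surviving pair can violate the cutoff.
    """
    df = matrix.data
    if len(df) < 2:
        raise CypscreenError("Pearson correlation undefined for fewer than 2 rows")
    cols = list(df.columns)
    corr = df.corr().to_numpy()
    variances = df.var(ddof=1)
    alive = {c: True for c in cols}
    removed: list[dict] = []
    for i in range(len(cols)):
        if not alive[cols[i]]:
            continue
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            if not alive[a]:
                break
            if not alive[b]:
                continue
            r = corr[i, j]
            if np.isnan(r) or abs(r) < r_cut:
                continue
            va, vb = variances[a], variances[b]
            if va < vb:
                victim, partner = a, b
            elif vb < va:
                victim, partner = b, a
            else:
                victim, partner = max(a, b), min(a, b)
            alive[victim] = False
            removed.append(
                {"column": victim, "reason": "correlation", "partner": partner, "r": float(r)}
            )
    keep = [c for c in cols if alive[c]]
    out = DescriptorMatrix(
        data=df[keep].copy(),
        provenance=matrix.provenance + [{"transform": "prune_correlated", "r_cut": r_cut, "kept": keep}],
    )
    return out, PruneReport(removed=removed)


def prune_low_variance(
    matrix: DescriptorMatrix, freq_ratio: float = 19.0, unique_cut: float = 0.10
) -> tuple[DescriptorMatrix, PruneReport]:
    """Drop near-zero-variance columns.

    A column is removed when it is constant, or when the ratio of the most
    frequent to the second most frequent value exceeds ``freq_ratio`` AND
    the fraction of distinct values is below ``unique_cut`` — the
    conventional two-part near-zero-variance rule.
    """
    df = matrix.data
    if len(df) < 2:
        raise CypscreenError("variance undefined for fewer than 2 rows")
    removed = []
    keep = []
    for c in df.columns:
        col = df[c]
        counts = col.value_counts()
        if len(counts) == 1:
            removed.append({"column": c, "reason": "near_zero_variance"})
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        unique_frac = len(counts) / len(col)
        if ratio > freq_ratio and unique_frac < unique_cut:
            removed.append({"column": c, "reason": "near_zero_variance"})
        else:
            keep.append(c)
    out = DescriptorMatrix(
        data=df[keep].copy(),
        provenance=matrix.provenance
        + [
            {
                "transform": "prune_low_variance",
                "freq_ratio": freq_ratio,
                "unique_cut": unique_cut,
                "kept": keep,
            }
        ],
    )
    return out, PruneReport(removed=removed)


# ---------------------------------------------------------------------------
# standardization


def standardize(
    matrix: DescriptorMatrix, params: ScalingParams | None = None
) -> tuple[DescriptorMatrix, ScalingParams]:
    """Center to mean 0 and scale to unit variance (ddof=1).

    With ``params`` given (test or screening data) the stored training
    means/sds are applied unchanged — never refit — so a distribution shift
    in new data stays visible to the model.
    """
    df = matrix.data
    if params is None:
        sds = df.std(ddof=1)
        if (sds <= 0).any():
            bad = list(sds.index[sds <= 0])
            raise CypscreenError(f"constant column(s) {bad} must be pruned before standardization")
        params = ScalingParams(means=df.mean(), sds=sds)
    else:
        missing = [c for c in df.columns if c not in params.means.index]
        if missing:
            raise CypscreenError(f"scaling parameters missing for column(s) {missing}")
    scaled = (df - params.means[df.columns]) / params.sds[df.columns]
    out = DescriptorMatrix(
        data=scaled, provenance=matrix.provenance + [{"transform": "standardize"}]
    )
    return out, params


def replay_provenance(raw: DescriptorMatrix, provenance: list[dict]) -> DescriptorMatrix:
    """Re-apply a recorded transform chain to a raw matrix.

    The surviving column list of each pruning step is stored in the
    provenance entry, so replay reproduces the processed matrix exactly.
    """
    out = DescriptorMatrix(data=raw.data.copy(), provenance=list(raw.provenance))
    for step in provenance:
        t = step["transform"]
        if t in ("prune_correlated", "prune_low_variance"):
            out = DescriptorMatrix(
                data=out.data[step["kept"]].copy(), provenance=out.provenance + [step]
            )
        elif t == "standardize":
            out, _ = standardize(out)
        else:
            raise CypscreenError(f"unknown transform {t!r} in provenance")
    return out


# ---------------------------------------------------------------------------
# serialization


def write_matrix(matrix: DescriptorMatrix, path) -> None:
    matrix.data.to_csv(path, index_label="id")


def read_matrix(path) -> DescriptorMatrix:
    df = pd.read_csv(path, index_col="id")
    df.index = df.index.astype(str)
    return DescriptorMatrix(data=df)
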