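"""Interaction-energy (IE) descriptors over an ensemble of CYP2C9 conformations.

Ensemble docking scores each ligand against seven receptor conformations:
two crystal structures (1R9O, 5XXI) and five snapshots from molecular
dynamics (MD1-MD5), keeping the best (most negative) docking score per
conformation in kcal/mol.  These seven scores join the physicochemical
descriptor matrix as structure-based descriptors, and double as a screening
filter: a strong candidate binds every conformation below a threshold
(default -8.5 kcal/mol, the 75% quantile of the training inhibitors'
pooled scores).

Docking itself is external; this module parses engine output, manages the
grid bookkeeping, and assembles/merges/filters IE profiles.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .errors import CypscreenError, EmptyInputError, IncompleteProfileError, ParseError, SchemaError

DEFAULT_CONFORMATIONS = ("1R9O", "5XXI", "MD1", "MD2", "MD3", "MD4", "MD5")
DEFAULT_IE_THRESHOLD = -8.5  # kcal/mol
ENERGY_UNIT = "kcal/mol"


@dataclass(frozen=True)
class ConformationSet:
    """Ordered receptor conformations of the docking ensemble."""

    names: tuple[str, ...] = DEFAULT_CONFORMATIONS

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("conformation names must be unique")

    def origin(self, name: str) -> str:
        self._check(name)
        return "crystal" if name in ("1R9O", "5XXI") else "md"

    def _check(self, name: str) -> None:
        if name not in self.names:
            raise CypscreenError(f"unknown conformation {name!r}; expected one of {self.names}")


@dataclass
class IEProfile:
    """Best docking score per conformation for one molecule (kcal/mol)."""

    molecule_id: str
    scores: dict[str, float]
    conformations: ConformationSet = field(default_factory=ConformationSet)

    def __post_init__(self) -> None:
        for name, s in self.scores.items():
            self.conformations._check(name)
            if not np.isfinite(s):
                raise ValueError(f"{self.molecule_id}: non-finite score for {name}")

    @property
    def complete(self) -> bool:
        return set(self.scores) == set(self.conformations.names)


@dataclass
class DockingJobSpec:
    """Grid and search settings for one receptor conformation."""

    receptor: str
    grid_center: tuple[float, float, float] = (8.208, 32.219, -1.923)
    box_size: tuple[float, float, float] = (25.0, 25.0, 25.0)
    exhaustiveness: int = 8
    max_modes: int = 10
    grid_resolution: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box sizes must be positive")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


def default_job_spec(
    conformation: str, conformations: ConformationSet | None = None, **overrides
) -> DockingJobSpec:
    """The ensemble's standard grid: one 25 A cube centered on the binding
    pocket, shared across all seven conformations."""
    (conformations or ConformationSet())._check(conformation)
    return DockingJobSpec(receptor=conformation, **overrides)


# ---------------------------------------------------------------------------
# docking-output parsing

# "REMARK VINA RESULT:   -9.1   0.000   0.000" (pdbqt) or bare "RESULT: -9.1"
_RESULT_LINE = re.compile(r"RESULT:\s+(-?\d+(?:\.\d+)?)")
# score-table rows: "   1       -9.1      0.000      0.000"
_TABLE_ROW = re.compile(r"^\s*\d+\s+(-?\d+\.\d+)\s+\d+\.\d+\s+\d+\.\d+\s*$")
# generic two-column "mode,score"
_CSV_ROW = re.compile(r"^\s*\d+\s*,\s*(-?\d+(?:\.\d+)?)\s*$")


def parse_docking_output(text: str) -> float:
    """Extract the best (minimum) mode score from docking-engine output.

    Accepts the RESULT-line dialect, the console score table, and a generic
    ``mode,score`` two-column form; tolerant of 1-10 modes.
    """
    scores = [float(m.group(1)) for m in _RESULT_LINE.finditer(text)]
    if not scores:
        for line in text.splitlines():
            m = _TABLE_ROW.match(line) or _CSV_ROW.match(line)
            if m:
                scores.append(float(m.group(1)))
    if not scores:
        raise ParseError("no docking result lines found in output")
    return min(scores)


# ---------------------------------------------------------------------------
# IE tables


def read_ie_table(
    path: str | Path, conformations: ConformationSet | None = None
) -> list[IEProfile]:
    """Read a delimited IE table: id column plus one column per conformation.

    Missing cells are allowed; the profile is flagged incomplete.  A missing
    conformation *column* is a schema error naming the absent conformations.
    """
    confs = conformations or ConformationSet()
    df = pd.read_csv(path, dtype={0: str})
    if "id" not in df.columns:
        raise SchemaError(f"{path}: missing 'id' column")
    absent = [c for c in confs.names if c not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing conformation column(s) {absent}")
    profiles = []
    for _, row in df.iterrows():
        scores = {c: float(row[c]) for c in confs.names if pd.notna(row[c])}
        profiles.append(IEProfile(molecule_id=str(row["id"]), scores=scores, conformations=confs))
    return profiles


def write_ie_table(profiles: list[IEProfile], path: str | Path) -> None:
    confs = profiles[0].conformations if profiles else ConformationSet()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *confs.names])
        for p in profiles:
            w.writerow([p.molecule_id] + [p.scores.get(c, "") for c in confs.names])


def merge_ie_descriptors(
    matrix: DescriptorMatrix, profiles: list[IEProfile], drop_incomplete: bool = False
) -> tuple[DescriptorMatrix, list[str]]:
    """Append one ``ie.<conformation>`` column per ensemble member.

    Every matrix row needs a complete profile; with ``drop_incomplete`` the
    uncovered rows are dropped and their ids returned, otherwise missing or
    incomplete coverage is an error listing the offending ids.
    """
    seen: dict[str, IEProfile] = {}
    for p in profiles:
        if p.molecule_id in seen:
            raise CypscreenError(f"duplicate IE profile for id {p.molecule_id!r}")
        seen[p.molecule_id] = p
    confs = profiles[0].conformations.names if profiles else DEFAULT_CONFORMATIONS

    missing = [
        rid for rid in matrix.ids if rid not in seen or not seen[rid].complete
    ]
    if missing and not drop_incomplete:
        raise IncompleteProfileError(
            f"{len(missing)} molecule(s) lack a complete IE profile: {missing[:10]}"
        )
    keep = [rid for rid in matrix.ids if rid not in missing]
    ie = pd.DataFrame(
        [[seen[rid].scores[c] for c in confs] for rid in keep],
        index=keep,
        columns=[f"ie.{c}" for c in confs],
    )
    data = pd.concat([matrix.data.loc[keep], ie], axis=1)
    out = DescriptorMatrix(
        data=data,
        provenance=matrix.provenance + [{"transform": "merge_ie", "conformations": list(confs)}],
    )
    return out, missing


# ---------------------------------------------------------------------------
# thresholding and the screen filter


def ie_threshold_from_inhibitors(profiles: list[IEProfile], q: float = 0.75) -> float:
    """Quantile-based IE threshold from training inhibitors.

    Pools all (molecule x conformation) scores of the given inhibitor
    profiles and returns the q-quantile of the pooled distribution: the
    value below which (i.e. more negative than which) a fraction q of the
    inhibitors' scores lie.
    """
    pooled = [s for p in profiles for s in p.scores.values()]
    if not pooled:
        raise EmptyInputError("no inhibitor scores to derive a threshold from")
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(pooled, q))


def ie_pass_filter(profile: IEProfile, threshold: float = DEFAULT_IE_THRESHOLD) -> bool:
    """True iff the score is strictly below the threshold for EVERY
    conformation; a score exactly at the threshold fails."""
    if not profile.complete:
        raise IncompleteProfileError(
            f"{profile.molecule_id}: profile incomplete, cannot apply the IE filter"
        )
    return all(s < threshold for s in profile.scores.values())
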