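"""Physico-chemical annotation of natural products.

Covers the map color-code properties: molecular weight, sp3-carbon
fraction, hydrogen-bond acceptor/donor counts, Crippen AlogP, topological
polar surface area, the Joback group-contribution boiling point, a
rule-of-five flag, and the peptide/glycoside substructure class defined by
two fixed SMARTS patterns. Continuous properties can additionally be
average-ranked and clamped to the display bounds used for coloring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski as RDLipinski
from rdkit.rdBase import BlockLogs
from scipy.stats import rankdata

from .records import Dataset, InvalidStructureError

logger = logging.getLogger(__name__)

#: constant term of the Joback boiling-point model, Kelvin
JOBACK_INTERCEPT = 198.2

#: dipeptide backbone pattern (two consecutive amide-linked alpha carbons
#: ending in acid or amide), applied verbatim
DIPEPTIDE_SMARTS = "[NX3,NX4+][CH1,CH2][CX3](=[OX1])[NX3,NX4+][CH1,CH2][CX3](=[OX1])[O,N]"
#: O-/N-glycoside pattern: anomeric ring CH flanked by ring oxygen and an
#: exocyclic O/N, applied verbatim
GLYCOSIDE_SMARTS = "[CR][OR][CHR]([OR0,NR0])[CR]"

SUBSTRUCTURE_CLASSES = ("peptide", "glycoside", "glycopeptide", "none")

#: display clamp bounds per property: (lower, upper); None = unbounded
DISPLAY_CLAMPS: dict[str, tuple[float | None, float | None]] = {
    "mw": (None, 1000.0),
    "t_joback": (None, 2000.0),
    "hbd": (None, 10.0),
    "alogp": (-2.0, 8.0),
    "tpsa": (None, 500.0),
}

CONTINUOUS_PROPERTIES = ("mw", "fsp3c", "hba", "hbd", "alogp", "tpsa", "t_joback")


@dataclass
class PropertyVector:
    """All per-molecule annotation values used as map color codes."""

    mw: float
    fsp3c: float
    hba: int
    hbd: int
    alogp: float
    tpsa: float
    t_joback: float
    lipinski_ok: bool
    substructure_class: str

    def as_dict(self) -> dict:
        return {
            "mw": self.mw,
            "fsp3c": self.fsp3c,
            "hba": self.hba,
            "hbd": self.hbd,
            "alogp": self.alogp,
            "tpsa": self.tpsa,
            "t_joback": self.t_joback,
            "lipinski_ok": self.lipinski_ok,
            "substructure_class": self.substructure_class,
        }


@dataclass(frozen=True)
class JobackGroup:
    name: str
    smarts: str
    pattern: Chem.Mol
    tb: float


class JobackGroupTable:
    """Ordered Joback-Reid group table with boiling-point contributions.

    Groups are assigned most-specific-first: walking the rows in order, a
    substructure match is counted only if none of its atoms was claimed by
    an earlier match, and it then claims all its atoms. This makes the
    assignment exhaustive and non-overlapping.
    """

    def __init__(self, groups: Sequence[JobackGroup], source: str):
        self.groups = list(groups)
        self.source = source

    @classmethod
    def load(cls, path: str | Path | None = None) -> "JobackGroupTable":
        if path is None:
            ref = resources.files("npmap4.data").joinpath("joback_tb.tsv")
            text = ref.read_text(encoding="utf-8")
            source = "packaged joback_tb.tsv"
        else:
            text = Path(path).read_text(encoding="utf-8")
            source = str(path)
        groups = []
        header_seen = False
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            name, smarts, tb = line.split("\t")
            pattern = Chem.MolFromSmarts(smarts)
            if pattern is None:
                raise ValueError(f"invalid SMARTS for Joback group {name}: {smarts}")
            groups.append(JobackGroup(name=name, smarts=smarts, pattern=pattern, tb=float(tb)))
        return cls(groups, source)

    def count_groups(self, mol: Chem.Mol) -> tuple[dict[str, int], int]:
        """Occurrence count per group plus the number of unclaimed heavy atoms."""
        claimed: set[int] = set()
        counts: dict[str, int] = {}
        for grp in self.groups:
            n = 0
            for match in mol.GetSubstructMatches(grp.pattern, uniquify=True):
                atoms = set(match)
                if atoms & claimed:
                    continue
                claimed |= atoms
                n += 1
            if n:
                counts[grp.name] = n
        unclaimed = mol.GetNumHeavyAtoms() - len(claimed)
        return counts, unclaimed


_DEFAULT_TABLE: JobackGroupTable | None = None


def default_joback_table() -> JobackGroupTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = JobackGroupTable.load()
    return _DEFAULT_TABLE


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    with BlockLogs():
        parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise InvalidStructureError(f"unparseable SMILES: {mol!r}")
    return parsed


def joback_boiling_point(
    mol: Chem.Mol | str, table: JobackGroupTable | None = None
) -> float:
    """Joback group-contribution boiling point, Kelvin.

    T = 198.2 + sum_i N_i * t_bi over the group occurrence counts N_i. Atoms
    covered by no group contribute nothing; incomplete coverage is logged as
    a warning, never hidden.
    """
    mol = _as_mol(mol)
    table = table or default_joback_table()
    counts, unclaimed = table.count_groups(mol)
    if unclaimed:
        logger.warning(
            "Joback coverage incomplete: %d heavy atoms matched no group in %s",
            unclaimed,
            Chem.MolToSmiles(mol),
        )
    return JOBACK_INTERCEPT + sum(
        n * next(g.tb for g in table.groups if g.name == name) for name, n in counts.items()
    )


def lipinski_flag(mw: float, alogp: float, hbd: int, hba: int) -> bool:
    """Rule-of-five flag: False only when more than one rule is violated
    (MW > 500, AlogP > 5, HBD > 5, HBA > 10)."""
    violations = sum([mw > 500.0, alogp > 5.0, hbd > 5, hba > 10])
    return violations <= 1


_DIPEPTIDE = Chem.MolFromSmarts(DIPEPTIDE_SMARTS)
_GLYCOSIDE = Chem.MolFromSmarts(GLYCOSIDE_SMARTS)


def classify_substructure(mol: Chem.Mol | str) -> str:
    """Substructure class from the two fixed SMARTS: ``peptide`` if only the
    dipeptide pattern matches, ``glycoside`` if only the glycoside pattern
    matches, ``glycopeptide`` if both, ``none`` otherwise."""
    mol = _as_mol(mol)
    is_pep = mol.HasSubstructMatch(_DIPEPTIDE)
    is_gly = mol.HasSubstructMatch(_GLYCOSIDE)
    if is_pep and is_gly:
        return "glycopeptide"
    if is_pep:
        return "peptide"
    if is_gly:
        return "glycoside"
    return "none"


def compute_descriptors(
    mol: Chem.Mol | str, table: JobackGroupTable | None = None
) -> PropertyVector:
    """Full property vector for one molecule."""
    mol = _as_mol(mol)
    mw = float(Descriptors.MolWt(mol))
    fsp3c = float(RDLipinski.FractionCSP3(mol))
    hba = int(RDLipinski.NumHAcceptors(mol))
    hbd = int(RDLipinski.NumHDonors(mol))
    alogp = float(Crippen.MolLogP(mol))
    tpsa = float(Descriptors.TPSA(mol))
    t_joback = joback_boiling_point(mol, table)
    return PropertyVector(
        mw=mw,
        fsp3c=fsp3c,
        hba=hba,
        hbd=hbd,
        alogp=alogp,
        tpsa=tpsa,
        t_joback=t_joback,
        lipinski_ok=lipinski_flag(mw, alogp, hbd, hba),
        substructure_class=classify_substructure(mol),
    )


def clamp_for_display(name: str, value: float) -> float:
    """Clamp a property value to its display bounds for coloring; values of
    properties without bounds pass through unchanged. Idempotent."""
    lo, hi = DISPLAY_CLAMPS.get(name, (None, None))
    if lo is not None and value < lo:
        return lo
    if hi is not None and value > hi:
        return hi
    return value


def average_rank(values: Iterable[float]) -> np.ndarray:
    """Fractional (average) ranks, 1-based; ties share the mean of the ranks
    they span."""
    return rankdata(np.asarray(list(values), dtype=float), method="average")


PROPERTY_COLUMNS = [
    "compound_id",
    "mw",
    "fsp3c",
    "hba",
    "hbd",
    "alogp",
    "tpsa",
    "t_joback",
    "lipinski_ok",
    "substructure_class",
]


def annotate_dataset(
    ds: Dataset, ranks: bool = True, table: JobackGroupTable | None = None
) -> pd.DataFrame:
    """Property table for a dataset: one row per molecule, raw values plus
    (optionally) an average-rank column per continuous property."""
    table = table or default_joback_table()
    rows = []
    for rec in ds:
        pv = compute_descriptors(rec.smiles_canonical, table)
        rows.append({"compound_id": rec.id, **pv.as_dict()})
    df = pd.DataFrame(rows, columns=PROPERTY_COLUMNS)
    if ranks and len(df):
        for col in CONTINUOUS_PROPERTIES:
            df[f"{col}_rank"] = average_rank(df[col].to_numpy())
    return df


def write_properties(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
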