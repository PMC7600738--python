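"""Molecule tables: reading, canonicalization, deduplication, splitting.

A dataset is an ordered collection of :class:`MoleculeRecord`. All structures
are stored twice: as the raw input SMILES and as a canonical, stereo-free
SMILES, which is the representation every downstream step (fingerprints,
descriptors, SMARTS classes) operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.rdBase import BlockLogs

logger = logging.getLogger(__name__)

ORIGINS = ("bacterium", "fungus", "unknown")

#: default column names for delimited molecule tables
DEFAULT_COLUMNS = {
    "id": "compound_id",
    "smiles": "smiles",
    "origin": "origin",
    "doi": "doi",
}

TABLE_COLUMNS = ["compound_id", "smiles_raw", "smiles_canonical", "origin", "doi"]


class InvalidStructureError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


class ConfigurationError(ValueError):
    """Raised for unusable inputs: missing columns, empty files, bad fractions."""


@dataclass
class MoleculeRecord:
    """One structure with its identity, canonical form and origin label."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    origin: str = "unknown"
    doi: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {self.origin!r}")


@dataclass
class Dataset:
    """Ordered collection of molecule records plus a provenance note.

    ``rejects`` carries rows that failed SMILES parsing during reading; they
    are reported, never silently dropped.
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    provenance: str = ""
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "compound_id", "smiles", "reason"])
    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MoleculeRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]

    @property
    def origins(self) -> list[str]:
        return [r.origin for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": r.id,
                    "smiles_raw": r.smiles_raw,
                    "smiles_canonical": r.smiles_canonical,
                    "origin": r.origin,
                    "doi": r.doi if r.doi is not None else "",
                }
                for r in self.records
            ],
            columns=TABLE_COLUMNS,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the dataset as UTF-8, LF-terminated TSV with fixed columns."""
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path, provenance: str = "") -> "Dataset":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"dataset TSV missing columns: {sorted(missing)}")
        records = [
            MoleculeRecord(
                id=row.compound_id,
                smiles_raw=row.smiles_raw,
                smiles_canonical=row.smiles_canonical,
                origin=row.origin,
                doi=row.doi or None,
            )
            for row in df.itertuples()
        ]
        return cls(records=records, provenance=provenance or str(path))


def canonicalize_strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereochemistry removed.

    Stereocenters and double-bond configuration are erased before writing the
    canonical form, so enantiomers and E/Z isomers collapse to one string.
    Idempotent: applying it to its own output is a fixed point.
    """
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)


def largest_fragment(smiles: str) -> str:
    """Keep only the largest covalent fragment (optional salt stripping)."""
    frags = smiles.split(".")
    if len(frags) == 1:
        return smiles

    def heavy(s: str) -> int:
        with BlockLogs():
            m = Chem.MolFromSmiles(s)
        return m.GetNumHeavyAtoms() if m is not None else -1

    return max(frags, key=lambda s: (heavy(s), s))


def read_molecule_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strip_salts: bool = False,
) -> Dataset:
    """Read a delimited molecule table (CSV/TSV by extension, or .smi).

    Each row becomes a :class:`MoleculeRecord` with a canonical stereo-free
    SMILES; rows whose SMILES does not parse go to ``dataset.rejects`` with a
    reason. Column names default to ``compound_id``/``smiles``/``origin``/
    ``doi`` and can be remapped via ``column_map``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if path.suffix.lower() == ".smi":
        rows = []
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
            parts = line.split()
            if not parts:
                continue
            rows.append({cols["smiles"]: parts[0], cols["id"]: parts[1] if len(parts) > 1 else f"MOL-{i + 1}"})
        df = pd.DataFrame(rows)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if df.empty:
        raise ConfigurationError(f"empty molecule table: {path}")
    if cols["smiles"] not in df.columns:
        raise ConfigurationError(
            f"SMILES column {cols['smiles']!r} not in header {list(df.columns)}"
        )

    records: list[MoleculeRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        smiles = str(row_d[cols["smiles"]]).strip()
        mol_id = str(row_d.get(cols["id"], "") or f"MOL-{i + 1}")
        origin = str(row_d.get(cols["origin"], "") or "unknown").strip().lower()
        if origin not in ORIGINS:
            origin = "unknown"
        doi = str(row_d.get(cols["doi"], "") or "") or None
        try:
            smi_in = largest_fragment(smiles) if strip_salts else smiles
            canonical = canonicalize_strip_stereo(smi_in)
        except InvalidStructureError as exc:
            rejects.append({"row": i, "compound_id": mol_id, "smiles": smiles, "reason": str(exc)})
            continue
        records.append(
            MoleculeRecord(id=mol_id, smiles_raw=smiles, smiles_canonical=canonical, origin=origin, doi=doi)
        )
    ds = Dataset(records=records, provenance=str(path))
    ds.rejects = pd.DataFrame(rejects, columns=["row", "compound_id", "smiles", "reason"])
    return ds


def deduplicate(ds: Dataset, conflict_policy: str = "random", seed: int = 0) -> Dataset:
    """Collapse records sharing a canonical SMILES to one record each.

    Records that agree on origin keep it; records with conflicting origins
    ("dual-origin" structures reported from both a bacterium and a fungus)
    are assigned one of their origins uniformly at random under ``seed``, and
    each such assignment is logged.
    """
    if conflict_policy != "random":
        raise ConfigurationError(f"unknown conflict policy: {conflict_policy!r}")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in ds.records:
        if rec.smiles_canonical not in groups:
            groups[rec.smiles_canonical] = []
            order.append(rec.smiles_canonical)
        groups[rec.smiles_canonical].append(rec)

    out: list[MoleculeRecord] = []
    for smi in order:
        recs = groups[smi]
        origins = sorted({r.origin for r in recs if r.origin != "unknown"})
        first = recs[0]
        if len(origins) <= 1:
            origin = origins[0] if origins else first.origin
        else:
            origin = origins[int(rng.integers(len(origins)))]
            logger.info(
                "dual-origin SMILES %s (%s): assigned origin=%s", first.id, smi, origin
            )
        out.append(replace(first, origin=origin))
    return Dataset(records=out, provenance=ds.provenance + " [deduplicated]")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition request: a train fraction and a shuffle seed."""

    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def split_train_test(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Random disjoint train/test partition, reproducible under the seed."""
    n = len(ds)
    idx = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(spec.train_fraction * n))
    train_idx = sorted(idx[:n_train].tolist())
    test_idx = sorted(idx[n_train:].tolist())
    train = Dataset([ds.records[i] for i in train_idx], ds.provenance + " [train]")
    test = Dataset([ds.records[i] for i in test_idx], ds.provenance + " [test]")
    return train, test


def from_smiles(
    smiles: Sequence[str],
    origins: Iterable[str] | None = None,
    ids: Iterable[str] | None = None,
    provenance: str = "in-memory",
) -> Dataset:
    """Build a canonicalized Dataset directly from SMILES strings."""
    origins = list(origins) if origins is not None else ["unknown"] * len(smiles)
    ids = list(ids) if ids is not None else [f"MOL-{i + 1}" for i in range(len(smiles))]
    records = [
        MoleculeRecord(
            id=i, smiles_raw=s, smiles_canonical=canonicalize_strip_stereo(s), origin=o
        )
        for i, s, o in zip(ids, smiles, origins)
    ]
    return Dataset(records=records, provenance=provenance)
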