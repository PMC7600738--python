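"""Synthetic molecule generator for download-free testing.

Molecules are assembled from a fragment grammar: chain units are SMILES
fragments whose first and last atoms accept one more single bond each, so
any concatenation ``start + unit_1 + ... + unit_m + end`` is a valid SMILES
by construction (ring-closure digits are reused only after closure). This
emulates the statistical shape of a microbial natural-product collection —
two origin classes, a broad size range, peptide and glycoside chemotypes —
without any claim to biosynthetic plausibility.

Class signal is configurable:

* ``substructure`` — bacteria carry oligopeptide backbones, fungi carry
  polyketide/aromatic chains, with shared decoration units and identical
  size distributions; the classes differ in substructure only.
* ``property`` — both classes share one unit vocabulary and mixing ratio;
  only their target-mass distributions differ (defaults: means 550 vs 650
  Da, sd 100 — a modest, heavily overlapping size shift of the kind real
  origin classes exhibit). Setting ``mw_means=None`` switches to a
  polarity-ratio shift at matched size: every molecule carries the full
  vocabulary once and the classes differ only in how often polar vs.
  apolar units repeat (shifting AlogP/TPSA/HBD instead of MW).
* ``none`` — both classes draw from the same pool and size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.rdBase import BlockLogs

from .records import Dataset, MoleculeRecord, canonicalize_strip_stereo

#: amino-acid-like residues (alpha carbon + side chain + amide link)
PEPTIDE_UNITS = (
    "NCC(=O)",          # glycine
    "NC(C)C(=O)",       # alanine
    "NC(CC(C)C)C(=O)",  # leucine
    "NC(CO)C(=O)",      # serine
    "NC(CCS)C(=O)",     # homocysteine-like
    "NC(Cc1ccccc1)C(=O)",  # phenylalanine
    "NC(CCC)C(=O)",     # norvaline
)

#: polyketide / aromatic chain extenders
POLYKETIDE_UNITS = (
    "CC(=O)",           # ketide
    "CC(O)",            # reduced ketide
    "C=CC",             # enoyl
    "c1ccc(cc1)",       # phenylene
    "c1cc(O)cc(c1)",    # hydroxy-phenylene
    "CC(=O)O",          # ester linkage
    "COC",              # ether
)

#: decoration units shared by both classes
SHARED_UNITS = ("CC", "CC(C)", "CCO")

#: polarity split of one small shared vocabulary (property-signal mode);
#: kept small so every molecule can carry the full vocabulary
POLAR_UNITS = ("CC(O)", "COC", "CC(=O)")
APOLAR_UNITS = ("CC(C)", "C=CC", "CC")

#: substitution decoys for the calibration pair panel (distinct shingles)
DECOY_UNITS = (
    "CC(F)",
    "CC(Cl)",
    "CC(Br)",
    "CSC",
    "CC(N)",
    "C(=S)C",
    "c1ccc(N)c(c1)",
)

#: terminal O-glycoside (pyranose) decoration
SUGAR_TERMINAL = "OC1OC(CO)C(O)C(O)C1O"

_unit_mass_cache: dict[str, float] = {}


def _unit_mass(unit: str) -> float:
    if unit not in _unit_mass_cache:
        with BlockLogs():
            m = Chem.MolFromSmiles(unit)
        _unit_mass_cache[unit] = Descriptors.MolWt(m) - 2.016  # two open valences
    return _unit_mass_cache[unit]


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic two-class molecule set."""

    n_per_class: int = 200
    seed: int = 0
    signal: str = "substructure"
    size_range: tuple[float, float] = (70.0, 2900.0)
    class_motifs: dict[str, Sequence[str]] | None = None
    sugar_probability: float = 0.15
    #: property mode: per-class target-mass means in Da (bacterium, fungus);
    #: None switches to the polarity-ratio variant at matched size
    mw_means: tuple[float, float] | None = (550.0, 650.0)
    mw_sd: float = 100.0
    #: polarity variant: fraction of polar units per class (bacterium, fungus)
    polar_fraction: tuple[float, float] = (0.8, 0.2)

    def __post_init__(self) -> None:
        if self.signal not in ("substructure", "property", "none"):
            raise ValueError(f"unknown signal kind: {self.signal!r}")
        lo, hi = self.size_range
        if not (0 < lo < hi):
            raise ValueError(f"unreachable size bounds: {self.size_range}")


def _assemble(
    rng: np.random.Generator,
    pool: Sequence[str],
    weights: np.ndarray | None,
    target_mw: float,
    sugar_probability: float,
) -> str:
    units: list[str] = []
    mass = 13.0  # start carbon
    while mass < target_mw - 30.0:
        if weights is None:
            unit = pool[int(rng.integers(len(pool)))]
        else:
            unit = pool[int(rng.choice(len(pool), p=weights))]
        units.append(unit)
        mass += _unit_mass(unit)
    end = SUGAR_TERMINAL if rng.random() < sugar_probability else "O"
    return "C" + "".join(units) + end


def _target_sampler(cfg: GeneratorConfig, origin: str):
    lo, hi = cfg.size_range
    if cfg.signal == "property":
        if cfg.mw_means is not None:
            mean = cfg.mw_means[0] if origin == "bacterium" else cfg.mw_means[1]
            return lambda rng: float(np.clip(rng.normal(mean, cfg.mw_sd), lo, hi))
        # matched sizes, large enough to express the mixing ratio
        return lambda rng: float(np.clip(rng.lognormal(np.log(900.0), 0.3), lo, hi))
    # broad, right-skewed size distribution shared by both classes
    return lambda rng: float(np.clip(rng.lognormal(np.log(450.0), 0.55), lo, hi))


def _assemble_property(
    rng: np.random.Generator,
    polar_p: float,
    target_mw: float,
    sugar_probability: float,
) -> str:
    """Property-signal assembly: the full vocabulary once, then class-biased
    repeats, in shuffled order."""
    units = list(POLAR_UNITS + APOLAR_UNITS)
    mass = 13.0 + sum(_unit_mass(u) for u in units)
    while mass < target_mw - 30.0:
        group = POLAR_UNITS if rng.random() < polar_p else APOLAR_UNITS
        unit = group[int(rng.integers(len(group)))]
        units.append(unit)
        mass += _unit_mass(unit)
    units = [units[i] for i in rng.permutation(len(units))]
    end = SUGAR_TERMINAL if rng.random() < sugar_probability else "O"
    return "C" + "".join(units) + end


def _pool(cfg: GeneratorConfig, origin: str) -> tuple[tuple[str, ...], np.ndarray | None]:
    if cfg.class_motifs is not None:
        return tuple(cfg.class_motifs[origin]) + SHARED_UNITS, None
    if cfg.signal == "substructure":
        base = PEPTIDE_UNITS if origin == "bacterium" else POLYKETIDE_UNITS
        return base + SHARED_UNITS, None
    if cfg.signal == "property":
        return POLAR_UNITS + APOLAR_UNITS, None
    return PEPTIDE_UNITS + POLYKETIDE_UNITS + SHARED_UNITS, None


def generate_dataset(cfg: GeneratorConfig) -> Dataset:
    """Deterministic two-class dataset of valid molecules.

    Exactly ``n_per_class`` molecules per origin; every SMILES parses, has
    at least two heavy atoms, and its molecular weight lies inside
    ``size_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.size_range
    records: list[MoleculeRecord] = []
    for origin, tag in (("bacterium", "BACT"), ("fungus", "FUNG")):
        pool, weights = _pool(cfg, origin)
        sample_target = _target_sampler(cfg, origin)
        polarity_mode = cfg.signal == "property" and cfg.mw_means is None
        polar_p = cfg.polar_fraction[0] if origin == "bacterium" else cfg.polar_fraction[1]
        for i in range(cfg.n_per_class):
            for _ in range(50):
                if polarity_mode:
                    smiles = _assemble_property(
                        rng, polar_p, sample_target(rng), cfg.sugar_probability
                    )
                else:
                    smiles = _assemble(rng, pool, weights, sample_target(rng), cfg.sugar_probability)
                with BlockLogs():
                    mol = Chem.MolFromSmiles(smiles)
                if mol is not None and lo <= Descriptors.MolWt(mol) <= hi:
                    break
            else:  # pragma: no cover - grammar guarantees validity
                raise RuntimeError(f"could not assemble a molecule in {cfg.size_range}")
            records.append(
                MoleculeRecord(
                    id=f"{tag}-{i + 1:04d}",
                    smiles_raw=smiles,
                    smiles_canonical=canonicalize_strip_stereo(smiles),
                    origin=origin,
                )
            )
    return Dataset(records=records, provenance=f"synthetic ({cfg.signal} signal, seed {cfg.seed})")


@dataclass
class MoleculePair:
    smiles_a: str
    smiles_b: str
    substitution_fraction: float


def generate_pair_panel(n_pairs: int = 200, seed: int = 0) -> list[MoleculePair]:
    """Molecule pairs whose exact shingle-set Jaccard similarities span
    [0, ~0.9] roughly uniformly.

    Pair b is pair a with a fraction f of its chain units replaced by decoy
    units; f is laid out so the resulting Jaccard values cover the range
    (shingles pair up atoms, so similarity falls roughly like (1 - f)^2 and
    f is spaced as 1 - sqrt(u) over a uniform grid u).
    """
    rng = np.random.default_rng(seed)
    pool = PEPTIDE_UNITS + POLYKETIDE_UNITS + SHARED_UNITS
    pairs: list[MoleculePair] = []
    for i in range(n_pairs):
        u = i / max(1, n_pairs - 1)
        f = 1.0 - np.sqrt(u)
        m = int(rng.integers(8, 17))
        units = [pool[int(rng.integers(len(pool)))] for _ in range(m)]
        n_sub = int(round(f * m))
        positions = rng.choice(m, size=n_sub, replace=False)
        variant = list(units)
        for p in positions:
            variant[p] = DECOY_UNITS[int(rng.integers(len(DECOY_UNITS)))]
        a = "C" + "".join(units) + "O"
        b = "C" + "".join(variant) + "O"
        pairs.append(MoleculePair(a, b, float(n_sub) / m))
    return pairs
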