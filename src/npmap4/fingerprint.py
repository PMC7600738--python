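"""MinHashed atom-pair (MAP4) fingerprints.

A molecule is decomposed into *shingles*: one text token per unordered pair
of heavy atoms and per radius r in {1, 2}, combining the canonical SMILES of
the circular substructure of radius r around each atom with the shortest
bond-path distance between them. The shingle set is MinHashed into a
1024-position signature; the fraction of positions at which two signatures
agree estimates the Jaccard similarity of the underlying shingle sets.

Token encoding (frozen, version ``MAP4-NPM4-1``)::

    envA|d|envB

with ``envA <= envB`` lexicographically so the token is symmetric in the two
atoms, ``d`` the shortest-path distance in bonds. Environments that exceed
the molecule fall back to the largest available radius, so every molecule
with at least two bonded heavy atoms has a non-empty shingle set.

The base integer for a token is taken from the SHA-1 digest of its UTF-8
bytes; the 1024 MinHash functions are independent universal-hash transforms
``(a_i * x + b_i) mod p`` with ``p = 2^31 - 1`` and coefficients drawn once
from a fixed seed, so signatures are bit-identical across runs and
platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .records import InvalidStructureError, canonicalize_strip_stereo

#: signature length (number of MinHash permutations)
N_PERMUTATIONS = 1024
#: Mersenne prime bounding the universal-hash range; signature values < PRIME
PRIME = (1 << 31) - 1
#: seed for drawing the hash-family coefficients (fixed; part of the format)
HASH_FAMILY_SEED = 42
#: encoding version written next to signature files
ENCODING_VERSION = "MAP4-NPM4-1"

RADII = (1, 2)


class TooSmallMoleculeError(ValueError):
    """Molecule has fewer than two bonded heavy atoms: no atom pairs exist."""


@dataclass(frozen=True)
class HashFamily:
    """1024 universal hash functions over SHA-1 token digests.

    ``values[i] = (a[i] * x + b[i]) mod p`` with x the token's base hash
    reduced mod p. Construction is deterministic given the seed.
    """

    a: np.ndarray
    b: np.ndarray
    seed: int

    @classmethod
    def build(cls, seed: int = HASH_FAMILY_SEED, n: int = N_PERMUTATIONS) -> "HashFamily":
        rng = np.random.default_rng(seed)
        a = rng.integers(1, PRIME, size=n, dtype=np.uint64)
        b = rng.integers(0, PRIME, size=n, dtype=np.uint64)
        return cls(a=a, b=b, seed=seed)


_DEFAULT_FAMILY: HashFamily | None = None


def default_hash_family() -> HashFamily:
    global _DEFAULT_FAMILY
    if _DEFAULT_FAMILY is None:
        _DEFAULT_FAMILY = HashFamily.build()
    return _DEFAULT_FAMILY


def token_base_hash(token: str) -> int:
    """Base integer for a shingle: first 8 bytes of its SHA-1 digest, mod p."""
    digest = hashlib.sha1(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % PRIME


def _atom_environment(mol: Chem.Mol, idx: int, radius: int) -> str:
    """Canonical SMILES of the circular substructure of ``radius`` bonds
    around atom ``idx``, rooted at that atom; falls back to the largest
    available environment for atoms near the molecule boundary."""
    for r in range(radius, 0, -1):
        env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
        if not env:
            continue
        amap: dict[int, int] = {}
        submol = Chem.PathToSubmol(mol, env, atomMap=amap)
        if idx in amap:
            return Chem.MolToSmiles(
                submol, rootedAtAtom=amap[idx], canonical=True, isomericSmiles=False
            )
    # isolated atom (no bonds at all within the fragment)
    return mol.GetAtomWithIdx(idx).GetSmarts()


def extract_shingles(smiles: str) -> frozenset[str]:
    """Shingle set of a molecule given as canonical stereo-free SMILES.

    One token per unordered heavy-atom pair and radius in {1, 2}; pairs in
    different fragments (no bond path) are skipped. Deduplicated set.
    """
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumHeavyAtoms()
    if n < 2:
        raise TooSmallMoleculeError(
            f"need >= 2 heavy atoms for atom pairs, got {n} in {smiles!r}"
        )
    dist = Chem.GetDistanceMatrix(mol)
    envs = {
        r: [_atom_environment(mol, i, r) for i in range(n)] for r in RADII
    }
    tokens: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if not np.isfinite(d) or d > n:  # disconnected pair
                continue
            d = int(d)
            for r in RADII:
                ea, eb = sorted((envs[r][i], envs[r][j]))
                tokens.add(f"{ea}|{d}|{eb}")
    if not tokens:
        raise TooSmallMoleculeError(
            f"no bonded atom pairs in {smiles!r} (single-atom fragments only)"
        )
    return frozenset(tokens)


def minhash(shingles: Iterable[str], family: HashFamily | None = None) -> np.ndarray:
    """1024-position MinHash signature of a shingle set.

    ``values[i] = min over tokens of hash_i(token)``; deterministic, dtype
    uint32, each value in [0, p).
    """
    family = family or default_hash_family()
    base = np.array(sorted(token_base_hash(t) for t in shingles), dtype=np.uint64)
    if base.size == 0:
        raise ValueError("cannot MinHash an empty shingle set")
    sig = np.full(family.a.shape[0], PRIME, dtype=np.uint64)
    # chunked so very large molecules stay within a bounded working set
    for start in range(0, base.size, 2048):
        x = base[start : start + 2048]
        h = (x[:, None] * family.a[None, :] + family.b[None, :]) % np.uint64(PRIME)
        np.minimum(sig, h.min(axis=0), out=sig)
    return sig.astype(np.uint32)


def map4_fingerprint(smiles: str, family: HashFamily | None = None) -> np.ndarray:
    """MAP4 signature of any SMILES: canonicalize and strip stereochemistry,
    extract shingles, MinHash."""
    canonical = canonicalize_strip_stereo(smiles)
    return minhash(extract_shingles(canonical), family)


def estimate_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Estimated Jaccard similarity: fraction of signature positions at which
    the two signatures hold the same value."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"signature shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a == b))


def estimate_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Estimated Jaccard distance: 1 - estimated similarity."""
    return 1.0 - estimate_similarity(a, b)


def exact_jaccard(s1: Iterable[str], s2: Iterable[str]) -> float:
    """Exact Jaccard similarity |s1 n s2| / |s1 u s2| of two shingle sets."""
    s1, s2 = set(s1), set(s2)
    if not s1 and not s2:
        return 1.0
    return len(s1 & s2) / len(s1 | s2)


def signatures_for(smiles: Sequence[str], family: HashFamily | None = None) -> np.ndarray:
    """Stack of signatures, shape (n, 1024) uint32, one row per molecule."""
    family = family or default_hash_family()
    return np.vstack([map4_fingerprint(s, family) for s in smiles])


def similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise estimated-Jaccard similarities, shape (len(A), len(B)).

    Row-chunked so the boolean comparison tensor stays small.
    """
    A = np.atleast_2d(np.asarray(A))
    B = np.atleast_2d(np.asarray(B))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"signature length mismatch: {A.shape[1]} vs {B.shape[1]}")
    out = np.empty((A.shape[0], B.shape[0]), dtype=np.float64)
    step = max(1, int(4e7 // (B.shape[0] * B.shape[1] + 1)))
    for start in range(0, A.shape[0], step):
        block = A[start : start + step]
        out[start : start + step] = (block[:, None, :] == B[None, :, :]).mean(axis=2)
    return out


class Map4Fingerprinter:
    """Sklearn-style transformer: SMILES sequences to (n, 1024) signatures.

    Stateless apart from the hash family; ``fit`` exists for pipeline
    compatibility and returns self.
    """

    def __init__(self, hash_seed: int = HASH_FAMILY_SEED):
        self.hash_seed = hash_seed

    def get_params(self, deep: bool = True) -> dict:
        return {"hash_seed": self.hash_seed}

    def set_params(self, **params) -> "Map4Fingerprinter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[str], y=None) -> "Map4Fingerprinter":
        self.family_ = HashFamily.build(self.hash_seed)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "family_"):
            self.fit(X)
        return signatures_for(list(X), self.family_)

    def fit_transform(self, X: Sequence[str], y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def write_signatures(
    path: str | Path, ids: Sequence[str], signatures: np.ndarray
) -> None:
    """Write signatures as TSV (id + 1024 integers per row) with a JSON
    sidecar header recording the hash-family seed and encoding version."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for mol_id, sig in zip(ids, signatures):
            fh.write(mol_id + "\t" + "\t".join(map(str, sig.tolist())) + "\n")
    header = {
        "encoding_version": ENCODING_VERSION,
        "hash_family_seed": HASH_FAMILY_SEED,
        "n_permutations": int(signatures.shape[1]),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(header, indent=1) + "\n", encoding="utf-8"
    )


def read_signatures(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a signature TSV; refuses files from an incompatible encoding."""
    path = Path(path)
    header_path = path.with_suffix(path.suffix + ".json")
    if header_path.exists():
        header = json.loads(header_path.read_text(encoding="utf-8"))
        if header.get("encoding_version") != ENCODING_VERSION:
            raise ValueError(
                f"signature file encoding {header.get('encoding_version')!r} "
                f"does not match this build ({ENCODING_VERSION})"
            )
    ids: list[str] = []
    rows: list[list[int]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([int(v) for v in parts[1:]])
    return ids, np.asarray(rows, dtype=np.uint32)
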