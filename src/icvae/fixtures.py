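"""Seeded synthetic SMILES corpus emulating a drug-like training set.

Molecules are assembled from a small fragment grammar (alkyl runs, benzene
and pyridine rings, ether / hydroxyl / amine / carbonyl / ester / thioether
/ halogen units) by string composition, so every string is valid by
construction and the hydrogen-bond acceptor and donor counts are steerable.
The generator fills explicit descriptor bins — every HBA level 0..6 and
HBD level 0..4 represented, molecular weights spanning at least [60, 350]
— so the corpus exercises the full condition range of the model the way a
ZINC-style training subset would, at a fraction of the size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .codec import tokenize
from .properties import PROPERTY_NAMES, compute_properties

# every token the grammar can emit; tests pin the corpus to this set
FIXTURE_TOKENS = frozenset(
    {"C", "c", "O", "N", "n", "S", "F", "Cl", "(", ")", "=", "1"}
)

HBA_LEVELS = range(0, 7)
HBD_LEVELS = range(0, 5)

# infix units: (smiles fragment, ~HBA contribution, ~HBD contribution)
_ACCEPTOR_UNITS = [("O", 1, 0), ("C(=O)", 1, 0), ("C(=O)O", 2, 0)]
_DONOR_UNITS = [("C(O)", 1, 1), ("C(N)", 1, 1)]
_NEUTRAL_UNITS = [("S", 0, 0), ("C(F)", 0, 0), ("C(Cl)", 0, 0)]
_RINGS = [("c1ccccc1", 0, 0), ("c1ccncc1", 1, 0)]

# anchors guaranteeing the MW span regardless of random assembly
_ANCHORS = ["CCO", "CCCCO", "C" * 25, "C" * 26]


@dataclass(frozen=True)
class FixtureSpec:
    n: int = 2000
    seed: int = 42
    max_tokens: int = 40
    min_bin_fraction: float = 1 / 50
    hba_levels: tuple[int, ...] = tuple(HBA_LEVELS)
    hbd_levels: tuple[int, ...] = tuple(HBD_LEVELS)

    def __post_init__(self):
        if self.n < 100:
            raise ValueError("fixture corpus needs n >= 100")


def _assemble(rng: np.random.Generator, hba_target: int, hbd_target: int,
              size_class: int, max_tokens: int) -> str:
    """Compose one chain-of-fragments SMILES aiming at the given HBA/HBD."""
    units: list[str] = []
    d = min(hbd_target, hba_target)
    for _ in range(d):
        units.append(_DONOR_UNITS[rng.integers(len(_DONOR_UNITS))][0])
    remaining = hba_target - d
    use_pyridine = remaining > 0 and rng.random() < 0.3
    if use_pyridine:
        remaining -= 1
    while remaining > 0:
        frag, a, _ = _ACCEPTOR_UNITS[rng.integers(len(_ACCEPTOR_UNITS))]
        if a <= remaining:
            units.append(frag)
            remaining -= a
    # carbon bulk sets the MW class; occasional neutral decoration
    n_alkyl = 1 + size_class + int(rng.integers(0, 3))
    units.extend("C" * int(rng.integers(1, 4)) for _ in range(n_alkyl))
    if rng.random() < 0.25:
        units.append(_NEUTRAL_UNITS[rng.integers(len(_NEUTRAL_UNITS))][0])
    if rng.random() < 0.45 or use_pyridine:
        ring = "c1ccncc1" if use_pyridine else "c1ccccc1"
        units.append(ring)
    perm = rng.permutation(len(units))
    smiles = "".join(units[i] for i in perm)
    if len(tokenize(smiles)) > max_tokens:
        return ""
    return smiles


def _canonical_valid(smiles: str) -> str | None:
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def generate_corpus(spec: FixtureSpec) -> tuple[list[str], pd.DataFrame]:
    """Deterministic corpus of `spec.n` unique valid SMILES + property table.

    Raises if a required HBA/HBD bin cannot be filled.
    """
    rng = np.random.default_rng(spec.seed)
    min_per_bin = max(1, math.ceil(spec.n * spec.min_bin_fraction))
    seen: set[str] = set()
    corpus: list[str] = []
    records: list[dict] = []
    hba_counts = {h: 0 for h in spec.hba_levels}
    hbd_counts = {d: 0 for d in spec.hbd_levels}

    def admit(original: str) -> bool:
        canon = _canonical_valid(original)
        if canon is None or canon in seen:
            return False
        if len(tokenize(original)) > spec.max_tokens:
            return False
        props = compute_properties(original)
        seen.add(canon)
        corpus.append(original)
        records.append({"smiles": original, **props})
        h, d = int(props["HBA"]), int(props["HBD"])
        if h in hba_counts:
            hba_counts[h] += 1
        if d in hbd_counts:
            hbd_counts[d] += 1
        return True

    for s in _ANCHORS:
        admit(s)

    levels = list(spec.hba_levels)
    attempts = 0
    max_attempts = 200 * spec.n
    while len(corpus) < spec.n and attempts < max_attempts:
        attempts += 1
        deficient = [h for h in spec.hba_levels if hba_counts[h] < min_per_bin]
        if deficient:
            hba_t = deficient[int(rng.integers(len(deficient)))]
        else:
            hba_t = levels[int(rng.integers(len(levels)))]
        deficient_d = [
            d for d in spec.hbd_levels if d <= hba_t and hbd_counts[d] < min_per_bin
        ]
        if deficient_d:
            hbd_t = deficient_d[int(rng.integers(len(deficient_d)))]
        else:
            hbd_t = int(rng.integers(0, min(hba_t, max(spec.hbd_levels)) + 1))
        size_class = int(rng.integers(0, 7))
        admit(_assemble(rng, hba_t, hbd_t, size_class, spec.max_tokens))

    if len(corpus) < spec.n:
        missing = [h for h in spec.hba_levels if hba_counts[h] < min_per_bin]
        raise RuntimeError(
            f"could not assemble {spec.n} unique molecules "
            f"(deficient HBA bins: {missing})"
        )
    for h in spec.hba_levels:
        if hba_counts[h] < min_per_bin:
            raise RuntimeError(f"HBA bin {h} underfilled: {hba_counts[h]}")
    for d in spec.hbd_levels:
        if hbd_counts[d] < 1:
            raise RuntimeError(f"HBD bin {d} empty")

    table = pd.DataFrame(records, columns=["smiles", *PROPERTY_NAMES])
    return corpus, table


def write_corpus(corpus: list[str], table: pd.DataFrame, smiles_path, csv_path) -> None:
    with open(smiles_path, "w") as fh:
        fh.write("# synthetic fixture corpus\n")
        for s in corpus:
            fh.write(s + "\n")
    table.to_csv(csv_path, index=False)


def read_corpus(smiles_path, csv_path=None) -> tuple[list[str], pd.DataFrame | None]:
    corpus = []
    with open(smiles_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if any(ch.isspace() for ch in line):
                raise ValueError(f"{smiles_path}:{lineno}: malformed line {line!r}")
            corpus.append(line)
    table = pd.read_csv(csv_path) if csv_path is not None else None
    return corpus, table
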