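"""Generative-chemistry evaluation metrics (MOSES-style).

Valid, Unique@1k, Novelty, SNN, Frag and IntDiv as used to benchmark
SMILES generators: fingerprints are Morgan (circular) radius 2, 1024 bits;
fragment similarity is the cosine between BRICS fragment frequency
vectors; internal diversity is one minus the mean pairwise Tanimoto over
unordered distinct pairs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import BRICS, rdFingerprintGenerator

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass(frozen=True)
class MetricsReport:
    valid: float
    unique_at_1k: float
    novelty: float
    snn: float
    frag: float
    intdiv: float
    n_generated: int
    n_valid: int

    def to_dict(self) -> dict:
        return asdict(self)


def canonicalize(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def validity(smiles_list: Sequence[str]) -> tuple[float, list[str]]:
    """Fraction of parseable+sanitizable strings and the canonical subset."""
    if len(smiles_list) == 0:
        raise ValueError("empty SMILES list")
    valid = []
    for s in smiles_list:
        c = canonicalize(s) if s else None
        if c is not None:
            valid.append(c)
    return len(valid) / len(smiles_list), valid


def uniqueness_at_k(canonical: Sequence[str], k: int = 1000) -> float:
    """Distinct fraction among the first min(k, len) molecules."""
    if len(canonical) == 0:
        raise ValueError("empty list")
    head = canonical[: min(k, len(canonical))]
    return len(set(head)) / len(head)


def novelty(canonical: Sequence[str], training: set[str] | Sequence[str]) -> float:
    """Fraction of generated canonical SMILES absent from the training set."""
    if len(canonical) == 0 or len(training) == 0:
        raise ValueError("empty input")
    train_set = set(training)
    return sum(s not in train_set for s in canonical) / len(canonical)


def _fingerprints(canonical: Sequence[str]):
    fps, kept = [], []
    for s in canonical:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            warnings.warn(f"skipping unfingerprintable SMILES {s!r}", stacklevel=2)
            continue
        fps.append(_FP_GEN.GetFingerprint(mol))
        kept.append(s)
    return fps, kept


def snn(generated: Sequence[str], reference: Sequence[str]) -> float:
    """Mean over generated molecules of the max Tanimoto to the reference set."""
    if len(generated) == 0 or len(reference) == 0:
        raise ValueError("empty input")
    gen_fps, _ = _fingerprints(generated)
    ref_fps, _ = _fingerprints(reference)
    if not gen_fps or not ref_fps:
        raise ValueError("no fingerprintable molecules")
    best = [
        max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)) for fp in gen_fps
    ]
    return float(np.mean(best))


def _brics_counts(canonical: Sequence[str]) -> Counter:
    counts: Counter = Counter()
    for s in canonical:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        counts.update(BRICS.BRICSDecompose(mol))
    return counts


def fragment_similarity(generated: Sequence[str], reference: Sequence[str]) -> float:
    """Cosine similarity of BRICS fragment frequency vectors.

    Returns 1.0 when neither set yields fragments, 0.0 when exactly one
    does.
    """
    if len(generated) == 0 or len(reference) == 0:
        raise ValueError("empty input")
    cg, cr = _brics_counts(generated), _brics_counts(reference)
    if not cg and not cr:
        return 1.0
    if not cg or not cr:
        return 0.0
    keys = sorted(set(cg) | set(cr))
    a = np.array([cg.get(k, 0) for k in keys], dtype=float)
    b = np.array([cr.get(k, 0) for k in keys], dtype=float)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def internal_diversity(generated: Sequence[str]) -> float:
    """1 - mean Tanimoto over unordered distinct pairs of the generated set."""
    if len(generated) < 2:
        raise ValueError("internal diversity needs at least 2 molecules")
    fps, _ = _fingerprints(generated)
    if len(fps) < 2:
        raise ValueError("fewer than 2 fingerprintable molecules")
    sims = []
    for i in range(1, len(fps)):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i]))
    return float(1.0 - np.mean(sims))


def moses_report(
    generated: Sequence[str],
    training: Sequence[str],
    reference: Sequence[str],
    k: int = 1000,
) -> MetricsReport:
    """Full metric bundle; SNN and Frag are computed against the reference
    (test) set, Novelty against the training set."""
    if not generated or not training or not reference:
        raise ValueError("empty input list")
    valid_frac, valid_canonical = validity(generated)
    train_canonical = {c for c in (canonicalize(s) for s in training) if c}
    ref_canonical = [c for c in (canonicalize(s) for s in reference) if c]
    if not valid_canonical:
        return MetricsReport(
            valid=0.0, unique_at_1k=0.0, novelty=0.0, snn=0.0, frag=0.0,
            intdiv=0.0, n_generated=len(generated), n_valid=0,
        )
    return MetricsReport(
        valid=valid_frac,
        unique_at_1k=uniqueness_at_k(valid_canonical, k),
        novelty=novelty(valid_canonical, train_canonical),
        snn=snn(valid_canonical, ref_canonical),
        frag=fragment_similarity(valid_canonical, ref_canonical),
        intdiv=(
            internal_diversity(valid_canonical) if len(valid_canonical) >= 2 else 0.0
        ),
        n_generated=len(generated),
        n_valid=len(valid_canonical),
    )
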