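"""Molecular descriptors and the tau-scaled condition labels.

Seven drug-design descriptors (MW, logP, HBA, HBD, TPSA, QED, SAS) are
computed with RDKit. Each conditioned property is mapped onto the condition
label range [0, 500] by an affine scale

    s = tau * (v - v_min),   tau = 500 / (v_max - v_min),

so that v_min -> 0 and v_max -> 500. The wide range lets the model resolve
the distance between neighbouring property values; the same scaled label is
used both as the conditional network input and as the latent prior mean.
For HBA on its native 0-10 range this gives tau = 50.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

RDLogger.DisableLog("rdApp.*")  # parse errors are expected on generated SMILES

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, needs the path hack above)

LATENT_RANGE = 500.0
PROPERTY_NAMES = ("MW", "logP", "HBA", "HBD", "TPSA", "QED", "SAS")
DISCRETE_PROPERTIES = frozenset({"HBA", "HBD"})


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES does not parse/sanitize."""


_DESCRIPTOR_FNS = {
    "MW": Descriptors.MolWt,
    "logP": Crippen.MolLogP,
    "HBA": Lipinski.NumHAcceptors,
    "HBD": Lipinski.NumHDonors,
    "TPSA": Descriptors.TPSA,
    "QED": QED.qed,
    "SAS": sascorer.calculateScore,
}


def compute_properties(
    smiles: str, names: Sequence[str] = PROPERTY_NAMES
) -> dict[str, float]:
    """Compute the named descriptors for one molecule.

    HBA/HBD are returned as non-negative integers (as floats); all values
    are finite.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"cannot parse/sanitize SMILES: {smiles!r}")
    out: dict[str, float] = {}
    for name in names:
        try:
            fn = _DESCRIPTOR_FNS[name]
        except KeyError:
            raise KeyError(f"unknown property {name!r}; choose from {PROPERTY_NAMES}")
        out[name] = float(fn(mol))
    return out


def property_table(
    corpus: Iterable[str], names: Sequence[str] = PROPERTY_NAMES
) -> pd.DataFrame:
    """Descriptor table with fixed column order smiles,MW,logP,HBA,HBD,TPSA,QED,SAS."""
    rows = []
    for s in corpus:
        rows.append({"smiles": s, **compute_properties(s, names)})
    return pd.DataFrame(rows, columns=["smiles", *names])


@dataclass(frozen=True)
class PropertySpec:
    """Value range and scale factor for one conditioned property."""

    name: str
    v_min: float
    v_max: float
    tau: float
    discrete: bool

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "v_min": self.v_min,
            "v_max": self.v_max,
            "tau": self.tau,
            "discrete": self.discrete,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PropertySpec":
        return cls(
            name=d["name"],
            v_min=float(d["v_min"]),
            v_max=float(d["v_max"]),
            tau=float(d["tau"]),
            discrete=bool(d["discrete"]),
        )


def fit_spec(name: str, v_min: float, v_max: float) -> PropertySpec:
    """Build a PropertySpec with tau = 500 / (v_max - v_min)."""
    if not np.isfinite(v_min) or not np.isfinite(v_max):
        raise ValueError("non-finite range bounds")
    if v_max <= v_min:
        raise ValueError(f"degenerate range for {name}: [{v_min}, {v_max}]")
    tau = LATENT_RANGE / (v_max - v_min)
    return PropertySpec(
        name=name,
        v_min=float(v_min),
        v_max=float(v_max),
        tau=tau,
        discrete=name in DISCRETE_PROPERTIES,
    )


def fit_specs_from_table(
    table: pd.DataFrame, names: Sequence[str]
) -> list[PropertySpec]:
    """Fit per-property specs from corpus min/max (default range source)."""
    return [fit_spec(n, table[n].min(), table[n].max()) for n in names]


def scale(value: float, spec: PropertySpec) -> float:
    """Property value -> condition label in [0, 500]; out-of-range clamps."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite {spec.name} value: {value}")
    label = spec.tau * (value - spec.v_min)
    if label < 0.0 or label > LATENT_RANGE:
        warnings.warn(
            f"{spec.name} value {value} outside [{spec.v_min}, {spec.v_max}]; "
            "clamping scaled label",
            stacklevel=2,
        )
        label = float(np.clip(label, 0.0, LATENT_RANGE))
    return float(label)


def unscale(label: float, spec: PropertySpec) -> float:
    """Condition label -> property value; callers may round discrete specs."""
    if not np.isfinite(label):
        raise ValueError(f"non-finite label: {label}")
    return float(spec.v_min + label / spec.tau)


def unscale_nearest(label: float, spec: PropertySpec) -> float:
    v = unscale(label, spec)
    return float(round(v)) if spec.discrete else v


def condition_vector(
    values: Mapping[str, float], specs: Sequence[PropertySpec]
) -> np.ndarray:
    """Ordered scaled labels, one entry per conditioned property."""
    return np.array([scale(values[sp.name], sp) for sp in specs], dtype=np.float64)
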