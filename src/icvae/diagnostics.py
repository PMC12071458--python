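"""Latent-space interpretability diagnostics.

The claim these tools quantify: after training with the shifted prior,
the posterior mean of latent coordinate i is (approximately) a linear
function of the scaled label of property i. `embed_corpus` collects the
posterior means over a corpus, `linearity_report` regresses a latent
coordinate on a scaled label, and `pair_map` exports the normalized
two-property view with the latent module length sqrt(x^2 + y^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ICVAE
from .codec import TokenVocabulary, encode_one_hot
from .properties import PropertySpec, condition_vector


def embed_corpus(
    model: ICVAE,
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    smiles: Sequence[str],
    table: pd.DataFrame,
    batch_size: int = 256,
) -> pd.DataFrame:
    """Posterior means over a corpus (deterministic: uses mu, no sampling).

    Returns one row per molecule: smiles, the property values, the scaled
    labels (label_<name>) and the K latent mean coordinates (mu_0..).
    """
    lookup = table.set_index("smiles")
    K, P = model.config.K, model.config.P
    X = np.zeros((len(smiles), vocab.size, model.config.max_len))
    C = np.zeros((len(smiles), P))
    for i, s in enumerate(smiles):
        X[i] = encode_one_hot(s, vocab, model.config.max_len).matrix
        row = lookup.loc[s]
        C[i] = condition_vector({sp.name: float(row[sp.name]) for sp in specs}, specs)
    mus = np.zeros((len(smiles), K))
    for start in range(0, len(smiles), batch_size):
        mu, _ = model.encode(X[start : start + batch_size],
                             C[start : start + batch_size])
        mus[start : start + len(mu)] = mu
    if not np.all(np.isfinite(mus)):
        raise ValueError("non-finite latent means")
    out = {"smiles": list(smiles)}
    for j, sp in enumerate(specs):
        out[sp.name] = [float(lookup.loc[s][sp.name]) for s in smiles]
        out[f"label_{sp.name}"] = C[:, j]
    for k in range(K):
        out[f"mu_{k}"] = mus[:, k]
    return pd.DataFrame(out)


@dataclass(frozen=True)
class LinearityReport:
    property_name: str
    latent_dim: int
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float


def linearity_report(
    table: pd.DataFrame, property_name: str, latent_dim: int
) -> LinearityReport:
    """OLS of mu_<dim> on the scaled label of the property."""
    label = table[f"label_{property_name}"].to_numpy(dtype=float)
    mu = table[f"mu_{latent_dim}"].to_numpy(dtype=float)
    if len(np.unique(label)) < 3:
        raise ValueError(
            f"need >= 3 distinct {property_name} label values for a regression"
        )
    fit = stats.linregress(label, mu)
    return LinearityReport(
        property_name=property_name,
        latent_dim=latent_dim,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
    )


def level_variance_ratio(
    table: pd.DataFrame, property_name: str, latent_dim: int
) -> float:
    """Between-level / within-level variance of mu for a discrete property.

    An ANOVA-style F: large values mean the latent coordinate clusters
    into the discrete line segments seen for HBA/HBD.
    """
    df = table[[property_name, f"mu_{latent_dim}"]].dropna()
    groups = [g.to_numpy() for _, g in df.groupby(property_name)[f"mu_{latent_dim}"]]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 property levels with >= 2 members")
    f_stat, _ = stats.f_oneway(*groups)
    return float(f_stat)


def pair_map(
    table: pd.DataFrame, property_x: str, property_y: str,
    dim_x: int | None = None, dim_y: int | None = None,
    specs: Sequence[PropertySpec] | None = None,
) -> pd.DataFrame:
    """Two-property latent view: min-max normalized coordinates + module length.

    By default property i is read from its conditioned coordinate (the
    position of the property in the checkpoint's spec list).
    """
    for p in (property_x, property_y):
        if f"label_{p}" not in table.columns:
            raise KeyError(f"property {p!r} is not conditioned in this table")
    if dim_x is None or dim_y is None:
        names = [c[len("label_"):] for c in table.columns if c.startswith("label_")]
        if dim_x is None:
            dim_x = names.index(property_x)
        if dim_y is None:
            dim_y = names.index(property_y)
    x = table[f"mu_{dim_x}"].to_numpy(dtype=float)
    y = table[f"mu_{dim_y}"].to_numpy(dtype=float)

    def _minmax(a):
        lo, hi = a.min(), a.max()
        if hi == lo:
            return np.zeros_like(a)
        return (a - lo) / (hi - lo)

    xn, yn = _minmax(x), _minmax(y)
    return pd.DataFrame(
        {
            "smiles": table["smiles"],
            property_x: table[property_x],
            property_y: table[property_y],
            "x": xn,
            "y": yn,
            "module_length": np.sqrt(xn**2 + yn**2),
        }
    )


def module_length(x: float, y: float) -> float:
    """sqrt(x^2 + y^2) of a normalized latent point."""
    return float(np.hypot(x, y))
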