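"""Controlled generation by direct latent coordinate setting.

Because training centres the latent prior for coordinate i at the scaled
label of property i, a molecule with a desired property value is generated
by building z = tau*c + eps — conditioned coordinates set to the scaled
targets (plus optional Gaussian noise), remaining coordinates drawn from
the standard normal — and decoding. Property grids sweep a target range at
equal sampling size per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codec import TokenVocabulary, decode_one_hot
from .model import ICVAE
from .properties import (
    InvalidMoleculeError,
    PropertySpec,
    compute_properties,
    scale,
)


@dataclass(frozen=True)
class GenerationRequest:
    targets: Mapping[str, float]
    n: int = 100
    noise_scale: float = 1.0
    decode_mode: str = "greedy"
    seed: int = 0
    temperature: float = 1.0
    resample_invalid: bool = False
    max_resample_rounds: int = 10

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _check_targets(targets: Mapping[str, float], specs: Sequence[PropertySpec]):
    known = {sp.name for sp in specs}
    unknown = set(targets) - known
    if unknown:
        raise KeyError(
            f"model is not conditioned on {sorted(unknown)}; "
            f"conditioned properties are {sorted(known)}"
        )


def make_latent(
    request: GenerationRequest,
    specs: Sequence[PropertySpec],
    K: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent batch (n, K) and matching condition labels (n, P).

    Conditioned coordinate i is scale(target_i) + N(0, noise_scale^2);
    unspecified conditioned properties default to the middle of their
    range; unconditioned coordinates are standard normal.
    """
    _check_targets(request.targets, specs)
    P = len(specs)
    labels = np.empty(P)
    for i, sp in enumerate(specs):
        if sp.name in request.targets:
            labels[i] = scale(float(request.targets[sp.name]), sp)
        else:
            labels[i] = scale(0.5 * (sp.v_min + sp.v_max), sp)
    z = rng.standard_normal((request.n, K))
    z[:, :P] = labels[None, :] + request.noise_scale * rng.standard_normal(
        (request.n, P)
    )
    C = np.tile(labels, (request.n, 1))
    return z, C


def generate(
    model: ICVAE,
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    request: GenerationRequest,
) -> pd.DataFrame:
    """Generate n molecules for one target; returns a record table.

    Columns: smiles, valid, and achieved_<prop> for each conditioned
    property (NaN for invalid decodes). Invalid decodes are kept unless
    resample_invalid is set.
    """
    rng = np.random.default_rng(request.seed)
    prop_names = [sp.name for sp in specs]
    rows: list[dict] = []
    rounds = 0
    needed = request.n
    while needed > 0:
        sub = GenerationRequest(**{**request.__dict__, "n": needed})
        z, C = make_latent(sub, specs, model.config.K, rng)
        probs = model.decode(z, C)
        for i in range(needed):
            seed_i = int(rng.integers(2**31))
            smiles = decode_one_hot(
                probs[i],
                vocab,
                mode=request.decode_mode,
                temperature=request.temperature,
                rng_seed=seed_i,
            )
            record: dict = {"smiles": smiles}
            try:
                achieved = compute_properties(smiles, prop_names) if smiles else None
            except InvalidMoleculeError:
                achieved = None
            record["valid"] = achieved is not None
            for name in prop_names:
                record[f"achieved_{name}"] = (
                    achieved[name] if achieved is not None else np.nan
                )
            rows.append(record)
        if not request.resample_invalid:
            break
        kept = sum(r["valid"] for r in rows)
        rows = [r for r in rows if r["valid"]]
        needed = request.n - kept
        rounds += 1
        if rounds >= request.max_resample_rounds:
            break
    return pd.DataFrame(rows[: request.n] if request.resample_invalid else rows)


def grid_steps(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid; start + k*step for k = 0..(stop-start)/step."""
    if step <= 0:
        raise ValueError("step must be positive")
    count = int(round((stop - start) / step)) + 1
    if count < 1:
        raise ValueError("empty grid")
    return start + step * np.arange(count)


def property_sweep(
    model: ICVAE,
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    grid: Mapping[str, tuple[float, float, float]],
    n_per_step: int = 10,
    noise_scale: float = 1.0,
    seed: int = 0,
    decode_mode: str = "greedy",
    temperature: float = 1.0,
    resample_invalid: bool = False,
) -> pd.DataFrame:
    """Sweep one or two properties over target grids, equal n per step.

    For a single property the steps are its own arithmetic grid. For
    multiple properties varied simultaneously, each property's grid is
    resampled (linearly) to the length of the longest grid and the values
    are paired position-by-position, so a sweep of MW 170-350/10 with TPSA
    10-90/10 yields 19 paired steps.

    Returns a long table: one row per generated molecule with target and
    achieved values and absolute errors. The table is unfiltered; pass the
    result to `apply_error_bound` to keep only near-target molecules.
    """
    if not grid:
        raise ValueError("empty grid")
    _check_targets(dict.fromkeys(grid, 0.0), specs)
    grids = {name: grid_steps(*spec3) for name, spec3 in grid.items()}
    m = max(len(g) for g in grids.values())
    paired = {
        name: (g if len(g) == m else np.linspace(g[0], g[-1], m))
        for name, g in grids.items()
    }
    frames = []
    rng = np.random.default_rng(seed)
    for k in range(m):
        targets = {name: float(paired[name][k]) for name in paired}
        req = GenerationRequest(
            targets=targets,
            n=n_per_step,
            noise_scale=noise_scale,
            seed=int(rng.integers(2**31)),
            decode_mode=decode_mode,
            temperature=temperature,
            resample_invalid=resample_invalid,
        )
        out = generate(model, vocab, specs, req)
        out.insert(0, "step", k)
        for name, value in targets.items():
            out[f"target_{name}"] = value
            out[f"abs_error_{name}"] = (out[f"achieved_{name}"] - value).abs()
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def apply_error_bound(
    table: pd.DataFrame, bounds: Mapping[str, float]
) -> pd.DataFrame:
    """Keep valid rows whose absolute error is within the bound, per property."""
    mask = table["valid"].astype(bool)
    for name, bound in bounds.items():
        mask &= table[f"abs_error_{name}"] <= bound
    return table[mask].reset_index(drop=True)
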