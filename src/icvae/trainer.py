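"""Seeded training loop, 70/30 corpus split, loss logging and K-sweeps.

All randomness — the corpus split, weight initialization, reparameterization
noise — flows from one config seed through named child seeds, so a run is
fully reproducible. Test-set loss is evaluated at the posterior mean
(eps = 0), making evaluation deterministic given a checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codec import MAX_LEN, TokenVocabulary, build_vocabulary, encode_one_hot
from .model import Adam, ICVAE, LossBreakdown, ModelConfig, save_checkpoint
from .properties import (
    PropertySpec,
    condition_vector,
    fit_specs_from_table,
    property_table,
)


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    train_fraction: float = 0.7
    conditioned_properties: tuple[str, ...] = ("HBA",)
    K: int = 128
    beta: float = 1.0
    hidden_dim: int = 292
    max_len: int = MAX_LEN
    clip_norm: float = 5.0
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    model: ICVAE
    vocab: TokenVocabulary
    specs: list[PropertySpec]
    losses: pd.DataFrame  # epoch, train_recon, train_kl, test_total
    train_smiles: list[str]
    test_smiles: list[str]


def split_corpus(
    corpus: Sequence[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic shuffle-split; train gets floor(n * fraction)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if len(corpus) < 2:
        raise ValueError("corpus must have at least 2 molecules")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(corpus))
    n_train = int(np.floor(len(corpus) * train_fraction))
    train = [corpus[i] for i in perm[:n_train]]
    test = [corpus[i] for i in perm[n_train:]]
    return train, test


def _encode_set(
    smiles: Sequence[str],
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    table: pd.DataFrame,
    max_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot tensor (n, V, L) and scaled-label matrix (n, P)."""
    lookup = table.set_index("smiles")
    X = np.zeros((len(smiles), vocab.size, max_len))
    C = np.zeros((len(smiles), len(specs)))
    for i, s in enumerate(smiles):
        X[i] = encode_one_hot(s, vocab, max_len).matrix
        row = lookup.loc[s]
        C[i] = condition_vector({sp.name: float(row[sp.name]) for sp in specs}, specs)
    return X, C


def train(
    config: TrainConfig,
    corpus: Sequence[str],
    table: pd.DataFrame | None = None,
) -> TrainResult:
    """Fit the model on a SMILES corpus; returns model, split and loss log.

    The vocabulary is built from the full corpus; property ranges (hence
    tau) come from the full corpus descriptor table. Aborts with a
    diagnostic if any loss turns non-finite.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    split_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    init_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    eps_rng = np.random.default_rng(seeds[2])

    if table is None:
        table = property_table(corpus)
    vocab = build_vocabulary(corpus)
    specs = fit_specs_from_table(table, config.conditioned_properties)

    train_smiles, test_smiles = split_corpus(
        corpus, config.train_fraction, split_seed
    )
    Xtr, Ctr = _encode_set(train_smiles, vocab, specs, table, config.max_len)
    Xte, Cte = _encode_set(test_smiles, vocab, specs, table, config.max_len)

    model_config = ModelConfig(
        vocab_size=vocab.size,
        P=len(specs),
        K=config.K,
        hidden_dim=config.hidden_dim,
        max_len=config.max_len,
        beta=config.beta,
    )
    model = ICVAE(model_config, seed=init_seed)
    opt = Adam(model, lr=config.learning_rate, clip_norm=config.clip_norm)

    rows = []
    n_train = len(train_smiles)
    for epoch in range(1, config.epochs + 1):
        order = eps_rng.permutation(n_train)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            lb = model.loss(Xtr[idx], Ctr[idx], rng=eps_rng, backward=True)
            if not (np.isfinite(lb.recon) and np.isfinite(lb.kl)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"recon={lb.recon}, kl={lb.kl}"
                )
            opt.step()
            recon_sum += lb.recon
            kl_sum += lb.kl
            n_batches += 1
        test_lb = _evaluate(model, Xte, Cte)
        rows.append(
            {
                "epoch": epoch,
                "train_recon": recon_sum / n_batches,
                "train_kl": kl_sum / n_batches,
                "test_total": test_lb.total,
            }
        )

    losses = pd.DataFrame(rows)
    if config.log_path:
        losses.to_csv(config.log_path, index=False)
    if config.checkpoint_path:
        save_checkpoint(
            config.checkpoint_path,
            model,
            vocab,
            specs,
            extra={"train_config": {**config.__dict__,
                                    "conditioned_properties":
                                        list(config.conditioned_properties)}},
        )
    return TrainResult(
        model=model,
        vocab=vocab,
        specs=specs,
        losses=losses,
        train_smiles=train_smiles,
        test_smiles=test_smiles,
    )


def _evaluate(model: ICVAE, X: np.ndarray, C: np.ndarray,
              batch_size: int = 256) -> LossBreakdown:
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    recon = kl = 0.0
    for start in range(0, len(X), batch_size):
        xb, cb = X[start : start + batch_size], C[start : start + batch_size]
        lb = model.loss(xb, cb, eps=np.zeros((len(xb), model.config.K)))
        w = len(xb) / len(X)
        recon += lb.recon * w
        kl += lb.kl * w
    return LossBreakdown(recon=recon, kl=kl, beta=model.config.beta)


def evaluate_loss(
    model: ICVAE,
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    smiles: Sequence[str],
    table: pd.DataFrame | None = None,
) -> LossBreakdown:
    """Deterministic (posterior-mean) loss of a checkpointed model on a set."""
    if len(smiles) == 0:
        raise ValueError("empty evaluation set")
    if table is None:
        table = property_table(smiles)
    X, C = _encode_set(smiles, vocab, specs, table, model.config.max_len)
    return _evaluate(model, X, C)


def k_sweep(
    base: TrainConfig,
    corpus: Sequence[str],
    k_values: Sequence[int],
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Train one model per latent dimensionality K; tabulate final test loss."""
    if table is None:
        table = property_table(corpus)
    rows = []
    for K in k_values:
        cfg = TrainConfig(**{**base.__dict__, "K": K,
                             "checkpoint_path": None, "log_path": None})
        result = train(cfg, corpus, table)
        final = result.losses.iloc[-1]
        rows.append({"K": K, "test_total": final["test_total"],
                     "train_recon": final["train_recon"],
                     "train_kl": final["train_kl"]})
    return pd.DataFrame(rows)
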