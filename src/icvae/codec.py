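"""SMILES tokenization and fixed-size one-hot encoding.

Molecules enter the model as one-hot matrices of shape
``(vocab_size, max_len)`` — one column per string position. Each SMILES is
wrapped in a terminal token ``'E'`` at both ends and padded to ``max_len``
with a dedicated pad token, so a 118-token SMILES fills the full 120
columns. The drug-like vocabulary this produces on a ZINC-style corpus has
around 33 tokens, giving the canonical 33 x 120 layout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MAX_LEN = 120
PAD_TOKEN = "<pad>"
TERMINAL_TOKEN = "E"

# Two-character organic-subset halogens and bracket atoms are single tokens;
# everything else is one character. %nn ring closures kept as one token.
_TOKEN_RE = re.compile(r"(\[[^\[\]]*\]|Br|Cl|%\d{2}|.)")


class MalformedSmilesError(ValueError):
    """Raised for structurally broken SMILES text (e.g. unbalanced brackets)."""


class UnknownTokenError(KeyError):
    """Raised when a token is not a member of a closed vocabulary."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:  # KeyError repr-quotes; we want the bare token
        return f"token not in vocabulary: {self.token!r}"


class LengthExceededError(ValueError):
    """Raised when a SMILES has too many tokens for the fixed-width encoding."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Cl and Br are single tokens, every bracketed atom expression ``[...]``
    is one token, and all other characters stand alone. The concatenation
    of the returned tokens always reproduces the input.

    Raises
    ------
    MalformedSmilesError
        If the string is empty, non-ASCII, or has unbalanced ``[]``.
    """
    if not smiles:
        raise MalformedSmilesError("empty SMILES string")
    if not smiles.isascii():
        raise MalformedSmilesError(f"non-ASCII SMILES: {smiles!r}")
    depth = 0
    for ch in smiles:
        if ch == "[":
            depth += 1
            if depth > 1:
                raise MalformedSmilesError(f"nested '[' in {smiles!r}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise MalformedSmilesError(f"unmatched ']' in {smiles!r}")
    if depth != 0:
        raise MalformedSmilesError(f"unclosed '[' in {smiles!r}")
    return _TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set defining the rows of the one-hot encoding."""

    tokens: tuple[str, ...]
    pad_token: str = PAD_TOKEN
    terminal_token: str = TERMINAL_TOKEN
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (self.pad_token, self.terminal_token):
            if special not in self.tokens:
                raise ValueError(f"special token {special!r} missing from vocabulary")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index_of[self.pad_token]

    @property
    def terminal_index(self) -> int:
        return self.index_of[self.terminal_token]

    def __getitem__(self, token: str) -> int:
        try:
            return self.index_of[token]
        except KeyError:
            raise UnknownTokenError(token) from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "tokens": list(self.tokens),
                "pad_token": self.pad_token,
                "terminal_token": self.terminal_token,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        d = json.loads(text)
        return cls(
            tokens=tuple(d["tokens"]),
            pad_token=d["pad_token"],
            terminal_token=d["terminal_token"],
        )


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Build a deterministic (sorted) vocabulary from a corpus.

    The result contains every token observed in the corpus plus the pad and
    terminal tokens; permuting the corpus cannot change it.
    """
    observed: set[str] = set()
    n = 0
    for smiles in corpus:
        observed.update(tokenize(smiles))
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    observed.discard(PAD_TOKEN)
    observed.discard(TERMINAL_TOKEN)
    # pad first, terminal second, then sorted corpus tokens: stable rows
    tokens = (PAD_TOKEN, TERMINAL_TOKEN, *sorted(observed))
    return TokenVocabulary(tokens=tokens)


@dataclass(frozen=True)
class EncodedSmiles:
    """One-hot matrix ``(vocab_size, max_len)`` for a single SMILES.

    ``length`` counts real columns including the two terminal tokens;
    columns beyond it hold the pad token's one-hot.
    """

    matrix: np.ndarray
    length: int
    source: str


def encode_one_hot(
    smiles: str, vocab: TokenVocabulary, max_len: int = MAX_LEN
) -> EncodedSmiles:
    """Encode as ``[terminal, tokens..., terminal, pad...]`` one-hot columns."""
    toks = tokenize(smiles)
    if len(toks) > max_len - 2:
        raise LengthExceededError(
            f"SMILES has {len(toks)} tokens; at most {max_len - 2} fit "
            f"in {max_len} columns with two terminal tokens"
        )
    indices = [vocab.terminal_index]
    for t in toks:
        indices.append(vocab[t])
    indices.append(vocab.terminal_index)
    length = len(indices)
    rows = np.full(max_len, vocab.pad_index, dtype=np.int64)
    rows[:length] = indices
    matrix = np.zeros((vocab.size, max_len), dtype=np.float64)
    matrix[rows, np.arange(max_len)] = 1.0
    return EncodedSmiles(matrix=matrix, length=length, source=smiles)


def encode_indices(
    smiles: str, vocab: TokenVocabulary, max_len: int = MAX_LEN
) -> np.ndarray:
    """Token-index row vector (max_len,) — the compact form of the one-hot."""
    enc = encode_one_hot(smiles, vocab, max_len)
    return np.argmax(enc.matrix, axis=0)


def decode_one_hot(
    columns: np.ndarray,
    vocab: TokenVocabulary,
    mode: str = "greedy",
    temperature: float = 1.0,
    rng_seed: int | None = None,
) -> str:
    """Decode a per-position score matrix back to a SMILES string.

    Greedy mode takes the arg-max token per column (ties: lowest vocabulary
    index). Sample mode draws per column from temperature-scaled normalized
    scores. Reading stops at the first terminal token after position 0; pad
    tokens are dropped.
    """
    if columns.shape[0] != vocab.size:
        raise ValueError(
            f"score matrix has {columns.shape[0]} rows, vocabulary has {vocab.size}"
        )
    if not np.all(np.isfinite(columns)):
        raise ValueError("non-finite scores")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if mode == "greedy":
        picks = np.argmax(columns, axis=0)
    elif mode == "sample":
        # Gumbel-max: argmax(log p / T + G) draws from the tempered softmax
        rng = np.random.default_rng(rng_seed)
        logits = np.log(np.clip(columns, 1e-300, None)) / temperature
        gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=columns.shape)))
        picks = np.argmax(logits + gumbel, axis=0)
    else:
        raise ValueError(f"unknown decode mode {mode!r}")
    out: list[str] = []
    for j, idx in enumerate(picks):
        tok = vocab.tokens[idx]
        if j == 0:
            continue  # leading terminal position
        if tok == vocab.terminal_token:
            break
        if tok == vocab.pad_token:
            continue
        out.append(tok)
    return "".join(out)


def read_smiles_file(path) -> list[str]:
    """Read a SMILES-per-line text file; '#' comment lines and blanks skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def write_smiles_file(smiles: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
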