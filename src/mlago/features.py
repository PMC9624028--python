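"""Hierarchical one-hot feature encoding for K_m prediction.

An EC number is encoded as four concatenated one-hot blocks — for its
first digit, first two digits, first three digits, and full four digits —
so that enzymes sharing a classification prefix share hot bits. Compound
and organism identifiers each get one conventional one-hot block. The six
blocks are concatenated (EC level 1..4, compound, organism); a record
with all six categories known therefore has exactly six ones.

Positions reported to users are 1-based; internal storage is 0-based
numpy indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from mlago.km_dataset import KmRecord, KmTable

logger = logging.getLogger(__name__)

BLOCK_NAMES = ("ec1", "ec12", "ec123", "ec1234", "compound", "organism")


def ec_prefixes(ec_number: str) -> tuple[str, str, str, str]:
    """The four hierarchical prefixes of an EC number.

    >>> ec_prefixes("1.2.3.4")
    ('1', '1.2', '1.2.3', '1.2.3.4')
    """
    parts = ec_number.split(".")
    if len(parts) != 4:
        raise ValueError(f"EC number must have four components, got {ec_number!r}")
    return (parts[0], ".".join(parts[:2]), ".".join(parts[:3]), ec_number)


@dataclass(frozen=True)
class LevelVocabulary:
    """Ordered category list for one one-hot block with 1-based lookup."""

    categories: tuple[str, ...]
    index_of: Mapping[str, int] = field(default=None, repr=False, compare=False)  # category -> 1-based rank

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate categories in vocabulary")
        object.__setattr__(
            self, "index_of", {c: i + 1 for i, c in enumerate(self.categories)}
        )

    @classmethod
    def from_values(cls, values: Iterable[str]) -> "LevelVocabulary":
        """Sorted vocabulary of the distinct values observed."""
        return cls(tuple(sorted(set(values))))

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class EncodingScheme:
    """Six concatenated one-hot vocabularies: EC levels 1-4, compound, organism."""

    ec_level_vocabs: tuple[LevelVocabulary, LevelVocabulary, LevelVocabulary, LevelVocabulary]
    compound_vocab: LevelVocabulary
    organism_vocab: LevelVocabulary

    @property
    def vocabularies(self) -> tuple[LevelVocabulary, ...]:
        return (*self.ec_level_vocabs, self.compound_vocab, self.organism_vocab)

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.vocabularies)

    @property
    def total_dim(self) -> int:
        return sum(self.block_sizes)

    @property
    def block_offsets(self) -> tuple[int, ...]:
        """0-based start offset of each block in concatenation order."""
        offs, acc = [], 0
        for s in self.block_sizes:
            offs.append(acc)
            acc += s
        return tuple(offs)

    def block_slices(self) -> dict[str, slice]:
        """Named 0-based column ranges, e.g. for grouped permutation importance."""
        return {
            name: slice(off, off + size)
            for name, off, size in zip(BLOCK_NAMES, self.block_offsets, self.block_sizes)
        }

    def hot_positions(self, record) -> list[int]:
        """1-based hot-bit positions in the full concatenated vector.

        Unknown categories contribute no position (their block stays
        all-zero).
        """
        cats = _record_categories(record)
        positions = []
        for vocab, off, cat in zip(self.vocabularies, self.block_offsets, cats):
            rank = vocab.index_of.get(cat)
            if rank is not None:
                positions.append(off + rank)  # off is 0-based, rank 1-based
        return positions


def _record_categories(record) -> tuple[str, ...]:
    """The six category strings of a record or (ec, compound, organism) triple."""
    if isinstance(record, (tuple, list)):
        ec, compound, organism = record[0], record[1], record[2]
    else:
        ec, compound, organism = record.ec_number, record.compound_id, record.organism_id
    return (*ec_prefixes(ec), compound, organism)


def build_scheme(training: KmTable) -> EncodingScheme:
    """Vocabularies of the categories present in a training table, sorted.

    Raises ``ValueError`` on an empty table.
    """
    if len(training) == 0:
        raise ValueError("cannot build an encoding scheme from an empty table")
    df = training.df
    prefixes = df["ec_number"].map(ec_prefixes)
    levels = tuple(
        LevelVocabulary.from_values(prefixes.map(lambda p, i=i: p[i])) for i in range(4)
    )
    return EncodingScheme(
        ec_level_vocabs=levels,
        compound_vocab=LevelVocabulary.from_values(df["compound_id"]),
        organism_vocab=LevelVocabulary.from_values(df["organism_id"]),
    )


def encode_record(scheme: EncodingScheme, record) -> np.ndarray:
    """Binary feature vector of length ``scheme.total_dim``.

    Categories unknown to the scheme leave their block all-zero (logged at
    debug level); prediction proceeds with graceful degradation.
    """
    x = np.zeros(scheme.total_dim, dtype=np.float64)
    cats = _record_categories(record)
    for name, vocab, off, cat in zip(BLOCK_NAMES, scheme.vocabularies, scheme.block_offsets, cats):
        rank = vocab.index_of.get(cat)
        if rank is None:
            logger.debug("unknown %s category %r: block left all-zero", name, cat)
        else:
            x[off + rank - 1] = 1.0
    return x


def encode_table(scheme: EncodingScheme, table: KmTable) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record; targets are log10(K_m / mM).

    Returns ``(X, y)`` with ``X`` of shape (n, total_dim) and ``y = log10 km_mM``.
    """
    X = np.zeros((len(table), scheme.total_dim), dtype=np.float64)
    df = table.df
    n_unknown = 0
    for i, rec in enumerate(df.itertuples(index=False)):
        cats = _record_categories((rec.ec_number, rec.compound_id, rec.organism_id))
        for vocab, off, cat in zip(scheme.vocabularies, scheme.block_offsets, cats):
            rank = vocab.index_of.get(cat)
            if rank is None:
                n_unknown += 1
            else:
                X[i, off + rank - 1] = 1.0
    if n_unknown:
        logger.warning("encode_table: %d category lookups failed (zero blocks)", n_unknown)
    y = np.log10(df["km_mM"].to_numpy())
    return X, y


def encode_queries(scheme: EncodingScheme, queries: Sequence) -> np.ndarray:
    """Encode (EC, compound, organism) queries without K_m values."""
    return np.vstack([encode_record(scheme, q) for q in queries]) if len(queries) else \
        np.zeros((0, scheme.total_dim))


# ---------------------------------------------------------------------------
# permutation importance

def grouped_permutation_importance(
    predictor,
    table: KmTable,
    groups: Mapping[str, Sequence[int] | slice] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance of feature groups, scored by RMSE increase.

    Each group's columns are permuted jointly (one shuffle of row indices
    per group per repeat); importance is the mean over repeats of
    (RMSE after permutation − baseline RMSE). ``groups`` defaults to the
    six encoding blocks and must partition the feature indices.
    """
    from mlago.predictor import rmse  # local import to avoid a cycle

    scheme = predictor.scheme
    if groups is None:
        groups = scheme.block_slices()
    # validate partition
    cover = np.zeros(scheme.total_dim, dtype=int)
    resolved: dict[str, np.ndarray] = {}
    for name, g in groups.items():
        idx = np.arange(scheme.total_dim)[g] if isinstance(g, slice) else np.asarray(list(g), dtype=int)
        resolved[name] = idx
        cover[idx] += 1
    if not np.all(cover == 1):
        raise ValueError("groups must partition the feature indices exactly once")

    X, y = encode_table(scheme, table)
    baseline = rmse(predictor.model.predict(X), y)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for name, idx in resolved.items():
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(X))
            Xp = X.copy()
            Xp[:, idx] = X[perm][:, idx]
            deltas.append(rmse(predictor.model.predict(Xp), y) - baseline)
        out[name] = float(np.mean(deltas))
    return out


def per_feature_permutation_importance(
    predictor, table: KmTable, n_repeats: int = 10, seed: int = 0, top_k: int | None = None
) -> list[tuple[int, float]]:
    """Per-feature variant for top-k rankings.

    Returns (1-based feature position, importance) pairs sorted by
    decreasing importance; only columns with at least one nonzero entry in
    ``table`` are permuted (all-zero columns have importance 0 exactly).
    """
    from mlago.predictor import rmse

    scheme = predictor.scheme
    X, y = encode_table(scheme, table)
    baseline = rmse(predictor.model.predict(X), y)
    rng = np.random.default_rng(seed)
    active = np.flatnonzero(X.any(axis=0))
    scores: dict[int, float] = {}
    for j in active:
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(X))
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            deltas.append(rmse(predictor.model.predict(Xp), y) - baseline)
        scores[int(j)] = float(np.mean(deltas))
    ranked = sorted(((j + 1, s) for j, s in scores.items()), key=lambda t: -t[1])
    return ranked[:top_k] if top_k else ranked


# ---------------------------------------------------------------------------
# scheme serialization: human-readable sidecar, one category per line

_SCHEME_HEADER = "# mlago encoding scheme v1"


def save_scheme(scheme: EncodingScheme, path: str | Path) -> None:
    lines = [_SCHEME_HEADER]
    for name, vocab in zip(BLOCK_NAMES, scheme.vocabularies):
        lines.append(f"[{name}]")
        lines.extend(vocab.categories)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_scheme(path: str | Path) -> EncodingScheme:
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or text[0].strip() != _SCHEME_HEADER:
        raise ValueError(f"{path}: not a v1 encoding-scheme file")
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text[1:]:
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            blocks[current] = []
        elif line.strip() and current is not None:
            blocks[current].append(line)
    missing = [n for n in BLOCK_NAMES if n not in blocks]
    if missing:
        raise ValueError(f"{path}: missing blocks {missing}")
    vocabs = {n: LevelVocabulary(tuple(blocks[n])) for n in BLOCK_NAMES}
    return EncodingScheme(
        ec_level_vocabs=(vocabs["ec1"], vocabs["ec12"], vocabs["ec123"], vocabs["ec1234"]),
        compound_vocab=vocabs["compound"],
        organism_vocab=vocabs["organism"],
    )
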