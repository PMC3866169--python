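"""Kimura 2-parameter (K2P) pairwise distances with pairwise deletion.

For each sequence pair, only positions where both sequences carry an
unambiguous nucleotide (A/C/G/T) are compared; gaps and IUPAC ambiguity
codes are removed per pair ("pairwise deletion"). With P the transition
proportion (A<->G, C<->T) and Q the transversion proportion over the n
compared sites, the K2P distance is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

The correction is undefined (saturation) when 1 - 2P - Q <= 0 or
1 - 2Q <= 0; such pairs are reported as undefined rather than clamped, so
that downstream means are not biased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .records import BarcodeDataset

logger = logging.getLogger(__name__)

# nucleotide codes: A=0, C=1, G=2, T=3; anything else (gap, ambiguity) = 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _base in enumerate("ACGT"):
    _CODE[ord(_base)] = _i
    _CODE[ord(_base.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3  # RNA uracil read as T

#: purine (A/G) vs pyrimidine (C/T) class per code; differences within a
#: class are transitions, across classes transversions.
_IS_PURINE = np.array([True, False, True, False], dtype=bool)


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 code matrix."""
    if not sequences:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one aligned length, got {sorted(lengths)}")
    buf = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(sequences), lengths.pop())


@dataclass(frozen=True)
class PairwiseComparison:
    """Site counts and distances for one aligned sequence pair.

    ``d_k2p`` is ``nan`` when the comparison is invalid (no comparable
    sites) or saturated (log argument non-positive).
    """

    n_sites: int
    n_transitions: int
    n_transversions: int

    @property
    def valid(self) -> bool:
        return self.n_sites > 0

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites if self.n_sites else math.nan

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites if self.n_sites else math.nan

    @property
    def d_p(self) -> float:
        """Uncorrected p-distance: proportion of differing compared sites."""
        return self.P + self.Q if self.n_sites else math.nan

    @property
    def saturated(self) -> bool:
        if not self.valid:
            return False
        return (1.0 - 2.0 * self.P - self.Q) <= 0.0 or (1.0 - 2.0 * self.Q) <= 0.0

    @property
    def d_k2p(self) -> float:
        if not self.valid or self.saturated:
            return math.nan
        return (
            -0.5 * math.log((1.0 - 2.0 * self.P - self.Q) * math.sqrt(1.0 - 2.0 * self.Q))
        ) + 0.0


def compare_pair(seq_a: str, seq_b: str) -> PairwiseComparison:
    """Compare two aligned sequences under pairwise deletion.

    Raises ``ValueError`` when the aligned lengths differ.
    """
    codes = encode_sequences([seq_a, seq_b])
    a, b = codes[0], codes[1]
    both = (a < 4) & (b < 4)
    n_sites = int(both.sum())
    if n_sites == 0:
        return PairwiseComparison(0, 0, 0)
    diff = both & (a != b)
    # clip codes so _IS_PURINE indexing is safe at masked positions
    same_class = _IS_PURINE[np.minimum(a, 3)] == _IS_PURINE[np.minimum(b, 3)]
    n_ts = int((diff & same_class).sum())
    n_tv = int(diff.sum()) - n_ts
    return PairwiseComparison(n_sites, n_ts, n_tv)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair compared-site counts.

    ``d`` holds ``nan`` for undefined entries (saturated or invalid pairs);
    the diagonal is zero. ``undefined_pairs`` lists saturated id pairs,
    ``invalid_pairs`` those with no comparable sites.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    undefined_pairs: set[frozenset] = field(default_factory=set)
    invalid_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shapes must match number of ids")
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in distance matrix")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def distance(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids], dtype=int)
        keep = set(ids)
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            n_sites=self.n_sites[np.ix_(idx, idx)].copy(),
            undefined_pairs={p for p in self.undefined_pairs if p <= keep},
            invalid_pairs={p for p in self.invalid_pairs if p <= keep},
        )


def _pairwise_k2p(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs K2P. Returns (d, n_sites, d_p) square arrays."""
    n = codes.shape[0]
    valid = codes < 4
    purine = _IS_PURINE[np.minimum(codes, 3)]
    d = np.zeros((n, n))
    dp = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(ns, valid.sum(axis=1))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = both & (codes[i] != codes[i + 1 :])
        same_class = purine[i] == purine[i + 1 :]
        n_sites = both.sum(axis=1)
        n_ts = (diff & same_class).sum(axis=1)
        n_tv = diff.sum(axis=1) - n_ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = n_ts / n_sites
            Q = n_tv / n_sites
            arg1 = 1.0 - 2.0 * P - Q
            arg2 = 1.0 - 2.0 * Q
            k2p = np.where(
                (n_sites > 0) & (arg1 > 0) & (arg2 > 0),
                -0.5 * np.log(np.where(arg1 > 0, arg1, 1.0) * np.sqrt(np.where(arg2 > 0, arg2, 1.0))),
                np.nan,
            )
            p_dist = np.where(n_sites > 0, P + Q, np.nan)
        k2p = k2p + 0.0  # normalise IEEE -0.0 from identical pairs
        d[i, i + 1 :] = k2p
        d[i + 1 :, i] = k2p
        dp[i, i + 1 :] = p_dist
        dp[i + 1 :, i] = p_dist
        ns[i, i + 1 :] = n_sites
        ns[i + 1 :, i] = n_sites
    return d, ns, dp


def build_distance_matrix(ds: BarcodeDataset) -> DistanceMatrix:
    """Compute all unordered pairwise K2P distances for a dataset.

    The dataset should already be filtered to barcode-compliant records;
    shorter sequences are compared as-is under pairwise deletion.
    """
    ids = ds.specimen_ids
    if len(ids) < 2:
        logger.warning("distance matrix requested for %d record(s)", len(ids))
        n = len(ids)
        return DistanceMatrix(ids, np.zeros((n, n)), np.zeros((n, n), dtype=np.int64))
    codes = encode_sequences([r.sequence for r in ds.records])
    d, ns, _ = _pairwise_k2p(codes)
    undefined: set[frozenset] = set()
    invalid: set[frozenset] = set()
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu[np.isnan(d[iu, ju])], ju[np.isnan(d[iu, ju])]):
        pair = frozenset((ids[i], ids[j]))
        if ns[i, j] == 0:
            invalid.add(pair)
        else:
            undefined.add(pair)
    if undefined:
        logger.info("%d saturated pair(s) excluded from distance summaries", len(undefined))
    if invalid:
        logger.info("%d pair(s) share no comparable sites", len(invalid))
    return DistanceMatrix(ids, d, ns, undefined, invalid)


class KimuraDistance(TransformerMixin, BaseEstimator):
    """Transformer mapping aligned sequences to a square K2P distance matrix.

    Stateless (``fit`` only validates); composes with sklearn pipelines that
    accept precomputed distances. ``transform`` accepts a list of equal-length
    sequence strings or a :class:`~barcodebin.records.BarcodeDataset` and
    returns an (n, n) float array with ``nan`` for undefined pairs.
    """

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        seqs = self._validate(X)
        if len(seqs) == 0:
            return np.zeros((0, 0))
        d, _, _ = _pairwise_k2p(encode_sequences(seqs))
        return d

    @staticmethod
    def _validate(X) -> list[str]:
        if isinstance(X, BarcodeDataset):
            return [r.sequence for r in X.records]
        seqs = list(X)
        if any(not isinstance(s, str) for s in seqs):
            raise TypeError("expected a BarcodeDataset or a sequence of strings")
        return seqs


def write_matrix_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square matrix TSV with ids as header and row labels; nan for undefined."""
    with open(path, "w") as fh:
        fh.write("specimen_id\t" + "\t".join(dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{v:.8f}" if not math.isnan(v) else "nan" for v in dm.d[i])
            fh.write(f"{sid}\t{row}\n")


def write_matrix_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP square distance format for NJ tool interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, sid in enumerate(dm.ids):
            row = " ".join(f"{v:.8f}" if not math.isnan(v) else "-1.0" for v in dm.d[i])
            fh.write(f"{sid}  {row}\n")
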