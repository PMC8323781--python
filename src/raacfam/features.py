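"""K-mer composition features over (reduced) alphabets.

A sequence of length L has L-k+1 overlapping k-mers; the feature vector is
the frequency of each of the ``s**k`` possible k-mers over the scheme's
representative alphabet (s = number of groups), so every row sums to 1.
k is limited to 1-3: the feature space grows as ``s**k`` and tripeptides
are the largest composition the approach uses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import ReducedSequence, ReductionScheme, reduce_sequence
from .errors import ConfigError, DatasetError, TooShortError

logger = logging.getLogger(__name__)

MAX_K = 3


@dataclass(frozen=True)
class FeatureSpec:
    """A (scheme, k) pair fixing the encoding; dimension is ``size**k``."""

    scheme: ReductionScheme
    k: int
    feature_names: tuple[str, ...] = field(init=False, compare=False)

    def __post_init__(self):
        if not 1 <= self.k <= MAX_K:
            raise ConfigError(f"k must be in 1..{MAX_K} (got {self.k})")
        names = tuple(
            "".join(kmer)
            for kmer in itertools.product(self.scheme.representatives, repeat=self.k)
        )
        object.__setattr__(self, "feature_names", names)

    @property
    def n_features(self) -> int:
        return self.scheme.size**self.k

    def index_of(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.feature_names)}


def kmer_composition(rseq: ReducedSequence, k: int) -> np.ndarray:
    """Frequency vector of the ``s**k`` k-mers of a reduced sequence.

    Entry i is (count of k-mer i among the L-k+1 overlapping windows)
    divided by L-k+1, so the vector sums to 1.

    Raises
    ------
    TooShortError
        If the sequence has fewer than k residues.
    """
    spec = FeatureSpec(rseq.scheme, k)
    L = len(rseq.symbols)
    if L < k:
        raise TooShortError(rseq.source_id, L, k)
    index = spec.index_of()
    counts = np.zeros(spec.n_features)
    s = rseq.symbols
    for i in range(L - k + 1):
        counts[index[s[i : i + k]]] += 1
    return counts / (L - k + 1)


@dataclass
class FeatureMatrix:
    """n_samples x n_features composition matrix with binary labels.

    ``labels`` are 1 for the positive class, 0 for the negative class.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    spec: FeatureSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DatasetError("values, labels and sample_ids disagree on n_samples")
        if d != self.spec.n_features:
            raise DatasetError(
                f"matrix has {d} columns but spec dimension is {self.spec.n_features}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, feature_indices: Sequence[int]) -> np.ndarray:
        """Column view restricted to the given feature indices."""
        return self.values[:, np.asarray(feature_indices, dtype=int)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=list(self.spec.feature_names), index=self.sample_ids
        )
        df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def encode_sequences(
    records: Iterable[tuple[str, str]],
    spec: FeatureSpec,
    *,
    nonstandard_policy: str = "drop",
) -> tuple[np.ndarray, list[str], int]:
    """Encode (id, sequence) pairs; rows for sequences shorter than k are
    skipped and counted.  Returns (matrix, kept ids, skipped count)."""
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped = 0
    for seq_id, seq in records:
        rseq = reduce_sequence(
            seq, spec.scheme, seq_id=seq_id, nonstandard_policy=nonstandard_policy
        )
        try:
            rows.append(kmer_composition(rseq, spec.k))
        except TooShortError:
            skipped += 1
            continue
        ids.append(seq_id)
    if skipped:
        logger.info("skipped %d sequence(s) shorter than k=%d", skipped, spec.k)
    matrix = np.vstack(rows) if rows else np.empty((0, spec.n_features))
    return matrix, ids, skipped


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def encode_dataset(
    pos_fasta,
    neg_fasta,
    spec: FeatureSpec,
    *,
    nonstandard_policy: str = "drop",
) -> FeatureMatrix:
    """Encode a two-class FASTA pair as a labelled feature matrix.

    Rows are ordered positives then negatives; labels are 1 then 0.
    Sequences shorter than k are skipped with a logged count; a class whose
    sequences are all skipped (or an empty file) is an error.
    """
    parts = []
    for path, label in ((pos_fasta, 1), (neg_fasta, 0)):
        records = read_fasta(path)
        matrix, ids, _ = encode_sequences(
            records, spec, nonstandard_policy=nonstandard_policy
        )
        if matrix.shape[0] == 0:
            raise DatasetError(
                f"no usable sequences in {path} (class label {label})"
            )
        parts.append((matrix, ids, np.full(matrix.shape[0], label, dtype=int)))
    values = np.vstack([p[0] for p in parts])
    ids = [i for p in parts for i in p[1]]
    labels = np.concatenate([p[2] for p in parts])
    return FeatureMatrix(values, labels, ids, spec)


def concat_feature_matrices(matrices: Sequence[FeatureMatrix]) -> pd.DataFrame:
    """Concatenate encodings of the same samples under several (scheme, k)
    specs column-wise — the multi-descriptor form of the feature map.

    All matrices must share sample ids and labels; columns are prefixed
    ``t<type>s<size>k<k>:`` to stay unique.  Returned as a DataFrame since
    the combined object no longer has a single FeatureSpec.
    """
    if not matrices:
        raise DatasetError("no matrices to concatenate")
    first = matrices[0]
    frames = []
    for m in matrices:
        if m.sample_ids != first.sample_ids or not np.array_equal(
            m.labels, first.labels
        ):
            raise DatasetError("matrices to concatenate must share samples and labels")
        prefix = f"t{m.spec.scheme.type_id}s{m.spec.scheme.size}k{m.spec.k}:"
        frames.append(
            pd.DataFrame(
                m.values,
                columns=[prefix + n for n in m.spec.feature_names],
                index=m.sample_ids,
            )
        )
    out = pd.concat(frames, axis=1)
    out.insert(0, "label", first.labels)
    return out
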