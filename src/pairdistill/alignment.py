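"""Alignment I/O, encoding, deduplication, reweighting and train/test splitting.

Sequences are aligned homologous protein domains: equal-length rows over the
20 standard amino acids plus the alignment gap '-', so the alphabet size is
q = 21 by default.  Internally every sequence is a vector of integer codes in
``[0, q)``; the gap always takes the last code.  Positions are 0-based
internally; mutation files use the conventional 1-based notation ("A42G").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO

#: 20 standard amino acids in alphabetical one-letter order, then the gap.
AMINO_ACID_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"


def default_alphabet() -> str:
    return AMINO_ACID_ALPHABET


@dataclass
class EncodedAlignment:
    """Integer-encoded fixed-length sequences with optional per-sequence weights.

    Parameters
    ----------
    codes : (n_sequences, N) int array, entries in [0, q).
    alphabet : ordered string of the q symbols; gap (if present) is last.
    ids : optional sequence labels.
    weights : optional positive per-sequence weights.
    """

    codes: np.ndarray
    alphabet: str = AMINO_ACID_ALPHABET
    ids: list[str] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (n_sequences, N) array")
        q = len(self.alphabet)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= q):
            raise ValueError(f"symbol codes must lie in [0, {q})")
        if self.ids is not None and len(self.ids) != len(self.codes):
            raise ValueError("ids length must match number of sequences")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.codes),):
                raise ValueError("weights must be one per sequence")
            if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
                raise ValueError("weights must be finite and > 0")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return self.n_sequences

    def take(self, indices: np.ndarray) -> "EncodedAlignment":
        indices = np.asarray(indices)
        return EncodedAlignment(
            self.codes[indices],
            alphabet=self.alphabet,
            ids=[self.ids[i] for i in indices] if self.ids is not None else None,
            weights=self.weights[indices] if self.weights is not None else None,
        )

    def decode(self) -> list[str]:
        """Back-translate codes to strings over the alphabet."""
        lut = np.array(list(self.alphabet))
        return ["".join(row) for row in lut[self.codes]]

    def to_fasta(self, path) -> None:
        ids = self.ids or [f"seq{i}" for i in range(len(self))]
        with open(path, "w") as fh:
            for name, seq in zip(ids, self.decode()):
                fh.write(f">{name}\n{seq}\n")


@dataclass
class SplitResult:
    """A train/test partition with distance-stratified test labels."""

    train: EncodedAlignment
    test: EncodedAlignment
    test_labels: list[str]
    split_seed: int


@dataclass
class MutationalDataset:
    """A wild type plus substitution records with experimental fitness values.

    records are ``(substitutions, fitness)`` where substitutions is a list of
    ``(position, from_code, to_code)`` with 0-based positions.
    """

    wildtype: np.ndarray
    records: list[tuple[list[tuple[int, int, int]], float]]
    alphabet: str = AMINO_ACID_ALPHABET

    def __post_init__(self) -> None:
        self.wildtype = np.asarray(self.wildtype, dtype=np.int64)
        N = len(self.wildtype)
        for subs, _ in self.records:
            for pos, frm, _to in subs:
                if not 0 <= pos < N:
                    raise ValueError(f"position {pos} out of range for N={N}")
                if self.wildtype[pos] != frm:
                    raise ValueError(
                        f"from-residue mismatch at position {pos}: wild type has "
                        f"code {self.wildtype[pos]}, record says {frm}"
                    )

    def mutant_codes(self) -> np.ndarray:
        """Materialize every mutant as a full sequence, shape (n_records, N)."""
        out = np.tile(self.wildtype, (len(self.records), 1))
        for r, (subs, _) in enumerate(self.records):
            for pos, _frm, to in subs:
                out[r, pos] = to
        return out

    @property
    def fitness(self) -> np.ndarray:
        return np.array([f for _, f in self.records], dtype=float)


def _encoding_table(alphabet: str) -> np.ndarray:
    """Byte lookup table mapping characters to codes; unknowns map to the gap."""
    gap_code = len(alphabet) - 1
    table = np.full(256, gap_code, dtype=np.int64)
    for code, ch in enumerate(alphabet):
        table[ord(ch)] = code
        table[ord(ch.lower())] = code
    table[ord(".")] = gap_code
    return table


def encode_sequences(strings: Sequence[str], alphabet: str = AMINO_ACID_ALPHABET) -> np.ndarray:
    """Encode equal-length strings to an integer matrix.

    Characters outside the alphabet (non-standard residues such as 'X' or 'B',
    and '.') become the gap code; case is ignored.
    """
    lengths = {len(s) for s in strings}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    table = _encoding_table(alphabet)
    raw = np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)
    return table[raw].reshape(len(strings), -1)


def read_fasta_alignment(path, alphabet: str = AMINO_ACID_ALPHABET) -> EncodedAlignment:
    """Read an aligned FASTA file into an :class:`EncodedAlignment`.

    All records must have the same length.  Non-standard amino acids are
    replaced with a gap.
    """
    if isinstance(path, io.TextIOBase):
        records = list(SeqIO.parse(path, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path!r}")
    strings = [str(r.seq) for r in records]
    codes = encode_sequences(strings, alphabet)
    return EncodedAlignment(codes, alphabet=alphabet, ids=[r.id for r in records])


def deduplicate(aln: EncodedAlignment) -> EncodedAlignment:
    """Drop duplicate symbol vectors, keeping the first occurrence in order."""
    _, first = np.unique(aln.codes, axis=0, return_index=True)
    keep = np.sort(first)
    return aln.take(keep)


def split_train_test(
    aln: EncodedAlignment,
    test_fraction: float = 0.1,
    seed: int = 0,
    distant_fraction: float = 0.1,
) -> SplitResult:
    """Random 9:1 (by default) train/test partition of a deduplicated alignment.

    The test size is ``test_fraction`` of the alignment rounded to the nearest
    integer (minimum 1); test sequences are then stratified into 'close' and
    'distant' by minimum Hamming distance to the training set.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    n_test = max(1, int(round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    train, test = aln.take(train_idx), aln.take(test_idx)
    labels = partition_test_by_distance(test, train, distant_fraction=distant_fraction)
    return SplitResult(train=train, test=test, test_labels=labels, split_seed=seed)


def min_hamming_to_set(seq: np.ndarray, ref: EncodedAlignment) -> float:
    """Minimum normalized Hamming distance from ``seq`` to any reference sequence.

    The normalized Hamming distance is the number of differing positions
    divided by the sequence length.
    """
    if len(ref) == 0:
        raise ValueError("reference alignment is empty")
    seq = np.asarray(seq)
    if seq.shape != (ref.length,):
        raise ValueError("sequence length does not match reference alignment")
    return float(np.min((ref.codes != seq[None, :]).mean(axis=1)))


def _min_hamming_matrix(test: EncodedAlignment, train: EncodedAlignment) -> np.ndarray:
    """Per-test-sequence minimum normalized Hamming distance to the train set."""
    out = np.empty(len(test))
    # chunk over test sequences to bound the (n_test, n_train, N) intermediate
    chunk = max(1, int(2e7 // max(1, len(train) * train.length)))
    for start in range(0, len(test), chunk):
        block = test.codes[start : start + chunk]
        d = (block[:, None, :] != train.codes[None, :, :]).mean(axis=2)
        out[start : start + len(block)] = d.min(axis=1)
    return out


def partition_test_by_distance(
    test: EncodedAlignment, train: EncodedAlignment, distant_fraction: float = 0.1
) -> list[str]:
    """Label the farthest ``distant_fraction`` of test sequences 'distant'.

    Distance is the minimum normalized Hamming distance to the training set;
    the size of the distant stratum is rounded to the nearest integer; ties
    are broken by input order (earlier index wins the distant slot).
    """
    if len(test) == 0 or len(train) == 0:
        raise ValueError("test and train alignments must be non-empty")
    dists = _min_hamming_matrix(test, train)
    n_distant = int(round(distant_fraction * len(test)))
    labels = ["close"] * len(test)
    if n_distant > 0:
        # stable sort on -distance: equal distances keep index order
        order = np.argsort(-dists, kind="stable")
        for i in order[:n_distant]:
            labels[i] = "distant"
    return labels


def compute_weights(aln: EncodedAlignment, similarity_threshold: float = 0.8) -> np.ndarray:
    """Standard phylogenetic reweighting: w_m = 1 / #{neighbors at >= threshold identity}.

    A neighbor of sequence m is any sequence (m itself included) whose fraction
    of identical positions with m is at least ``similarity_threshold``; gaps
    count as an ordinary 21st symbol in the identity computation.
    """
    n = len(aln)
    counts = np.zeros(n)
    chunk = max(1, int(2e7 // max(1, n * aln.length)))
    for start in range(0, n, chunk):
        block = aln.codes[start : start + chunk]
        ident = (block[:, None, :] == aln.codes[None, :, :]).mean(axis=2)
        counts[start : start + len(block)] = (ident >= similarity_threshold).sum(axis=1)
    return 1.0 / counts


def parse_mutation_spec(spec: str, alphabet: str = AMINO_ACID_ALPHABET) -> list[tuple[int, int, int]]:
    """Parse a colon-separated mutation spec like ``"A42G"`` or ``"A1C:G2A"``.

    Positions in the spec are 1-based; the result uses 0-based positions and
    integer codes ``(position, from_code, to_code)``.
    """
    subs = []
    for token in spec.strip().split(":"):
        token = token.strip()
        if len(token) < 3:
            raise ValueError(f"malformed mutation spec {token!r}")
        frm, to = token[0], token[-1]
        try:
            pos = int(token[1:-1]) - 1
        except ValueError as exc:
            raise ValueError(f"malformed position in mutation spec {token!r}") from exc
        try:
            subs.append((pos, alphabet.index(frm.upper()), alphabet.index(to.upper())))
        except ValueError as exc:
            raise ValueError(f"unknown residue in mutation spec {token!r}") from exc
    return subs


def read_mutational_csv(
    path, wildtype: np.ndarray | str, alphabet: str = AMINO_ACID_ALPHABET
) -> MutationalDataset:
    """Read a ``mutant,fitness`` CSV into a validated :class:`MutationalDataset`.

    The mutant column holds colon-separated substitutions ("A1C:G2A") with
    1-based positions; the fitness column is a single numeric value.  A header
    line is skipped if present.
    """
    if isinstance(wildtype, str):
        wildtype = encode_sequences([wildtype], alphabet)[0]
    wildtype = np.asarray(wildtype, dtype=np.int64)
    records: list[tuple[list[tuple[int, int, int]], float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'mutant,fitness', got {line!r}")
            if lineno == 1 and parts[1].lower() in {"fitness", "score", "value"}:
                continue
            subs = parse_mutation_spec(parts[0], alphabet)
            try:
                fitness = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric fitness {parts[1]!r}") from exc
            for pos, frm, _to in subs:
                if not 0 <= pos < len(wildtype):
                    raise ValueError(f"line {lineno}: position {pos + 1} out of range")
                if wildtype[pos] != frm:
                    raise ValueError(
                        f"line {lineno}: wild type has {alphabet[wildtype[pos]]} at "
                        f"position {pos + 1}, spec says {alphabet[frm]}"
                    )
            records.append((subs, fitness))
    return MutationalDataset(wildtype=wildtype, records=records, alphabet=alphabet)
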