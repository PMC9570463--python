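"""Context-based feature encoders for RNA sequence windows.

Three per-position encoders are provided and may be fused channel-wise:

``one_hot``
    4 binary channels in the fixed order A, C, G, U.
``ncp``
    3 binary chemical-property channels: ring structure (1 for purines
    A/G), chemical functionality (1 for amino bases A/C) and hydrogen-bond
    strength (1 for weakly pairing A/U).
``nd``
    1 channel of accumulated nucleotide frequency: at 1-based position
    ``i`` the count of that position's own letter within positions
    ``1..i`` divided by ``i``; values always lie in (0, 1].

The default fusion order is one_hot ‖ ncp ‖ nd, giving 8 channels per
position (a 41-nt window becomes a 41 x 8 matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGU"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: residue sets carrying a 1 in each NCP channel
_NCP_SETS = (frozenset("AG"), frozenset("AC"), frozenset("AU"))

ONE_HOT_LABELS = ("A", "C", "G", "U")
NCP_LABELS = ("ring", "functionality", "hydrogen_bond")
ND_LABELS = ("density",)


class SequenceError(ValueError):
    """Raised for sequences containing symbols outside {A,C,G,U,T}."""


def normalize_sequence(raw: str) -> str:
    """Validate and normalize a nucleotide string to the RNA alphabet.

    Uppercases the input and maps T to U.  Any other symbol (including
    the ambiguity code N) is rejected; the error message reports the
    1-based position of the first offending character.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _INDEX:
            raise SequenceError(
                f"invalid symbol {raw[pos - 1]!r} at position {pos} "
                f"(alphabet is A/C/G/U/T, case-insensitive)"
            )
    return seq


@dataclass(frozen=True)
class EncodingMatrix:
    """Per-position numeric features: L rows x C named channels."""

    values: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_labels):
            raise ValueError("values shape does not match channel labels")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def encode_one_hot(seq: str) -> EncodingMatrix:
    """Binary encoding: L x 4 matrix with channel order A, C, G, U."""
    seq = normalize_sequence(seq)
    idx = np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    values = np.zeros((len(seq), 4), dtype=np.float64)
    values[np.arange(len(seq)), idx] = 1.0
    return EncodingMatrix(values, ONE_HOT_LABELS)


def encode_ncp(seq: str) -> EncodingMatrix:
    """Nucleotide chemical property encoding: L x 3 binary matrix."""
    seq = normalize_sequence(seq)
    values = np.zeros((len(seq), 3), dtype=np.float64)
    for i, ch in enumerate(seq):
        for j, members in enumerate(_NCP_SETS):
            if ch in members:
                values[i, j] = 1.0
    return EncodingMatrix(values, NCP_LABELS)


def encode_nd(seq: str) -> EncodingMatrix:
    """Accumulated nucleotide frequency: L x 1 matrix, entries in (0, 1]."""
    seq = normalize_sequence(seq)
    counts = dict.fromkeys(ALPHABET, 0)
    values = np.empty((len(seq), 1), dtype=np.float64)
    for i, ch in enumerate(seq, start=1):
        counts[ch] += 1
        values[i - 1, 0] = counts[ch] / i
    return EncodingMatrix(values, ND_LABELS)


_ENCODERS = {
    "one_hot": (encode_one_hot, 4),
    "ncp": (encode_ncp, 3),
    "nd": (encode_nd, 1),
}


@dataclass(frozen=True)
class FeatureScheme:
    """Ordered selection of encoders whose outputs are concatenated."""

    encoders: tuple[str, ...] = ("one_hot", "ncp", "nd")

    def __post_init__(self):
        if not self.encoders:
            raise ValueError("feature scheme must name at least one encoder")
        for name in self.encoders:
            if name not in _ENCODERS:
                raise ValueError(
                    f"unknown encoder {name!r}; choose from {sorted(_ENCODERS)}"
                )

    @property
    def total_channels(self) -> int:
        return sum(_ENCODERS[name][1] for name in self.encoders)


DEFAULT_SCHEME = FeatureScheme()


def encode_fusion(seq: str, scheme: FeatureScheme = DEFAULT_SCHEME) -> EncodingMatrix:
    """Channel-wise concatenation of the scheme's encoders, in order."""
    parts = [_ENCODERS[name][0](seq) for name in scheme.encoders]
    values = np.concatenate([p.values for p in parts], axis=1)
    labels = tuple(lbl for p in parts for lbl in p.channel_labels)
    return EncodingMatrix(values, labels)


def encode_batch(seqs, scheme: FeatureScheme = DEFAULT_SCHEME, dtype=np.float32) -> np.ndarray:
    """Encode equal-length sequences into an (N, L, C) array for the model."""
    mats = [encode_fusion(s, scheme).values for s in seqs]
    lengths = {m.shape[0] for m in mats}
    if len(lengths) > 1:
        raise ValueError(f"sequences have differing lengths {sorted(lengths)}")
    return np.stack(mats).astype(dtype)


def export_matrix_tsv(matrix: EncodingMatrix, path) -> None:
    """Write one encoded record as TSV with channel labels in the header."""
    header = "\t".join(("position",) + matrix.channel_labels)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, row in enumerate(matrix.values, start=1):
            fh.write("\t".join([str(i)] + [format(v, "g") for v in row]) + "\n")
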