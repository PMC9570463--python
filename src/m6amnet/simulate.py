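"""Synthetic labeled 41-nt window datasets with a controllable class signal.

Negatives are i.i.d. background sequences with the center trinucleotide
forced to B-C-A (B sampled from {C,G,U}); positives are generated the same
way except that a fraction ``signal_strength`` of them carry a motif drawn
from a position weight matrix planted at a fixed offset from the center.
Because the center context is imposed on both classes, the planted motif
is the only systematic difference between the classes.

Records are assigned pseudo-chromosome labels round-robin so that
chromosome-level hold-out protocols can be exercised; the signal is
chromosome-independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset import BenchmarkDataset, GenomicSite, SampleRecord
from .encoding import ALPHABET

_LETTERS = np.array(list(ALPHABET))


def pwm_from_consensus(consensus: str) -> np.ndarray:
    """Deterministic PWM (4 x m, rows in A,C,G,U order) for a consensus string."""
    pwm = np.zeros((4, len(consensus)))
    for j, ch in enumerate(consensus.upper().replace("T", "U")):
        pwm[ALPHABET.index(ch), j] = 1.0
    return pwm


@dataclass
class SyntheticSpec:
    n_per_class: int
    window_length: int = 41
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: np.ndarray = field(default_factory=lambda: pwm_from_consensus("GGACGU"))
    motif_offset: int = 3  # motif start relative to the center position
    signal_strength: float = 1.0  # fraction of positives carrying the motif
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self):
        self.motif = np.asarray(self.motif, dtype=float)
        if self.motif.shape[0] != 4 or not np.allclose(self.motif.sum(axis=0), 1.0):
            raise ValueError("motif must be a 4 x m PWM with columns summing to 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be 4 probabilities summing to 1")
        center = self.window_length // 2
        cols = self.motif_positions()
        if cols.min() < 0 or cols.max() >= self.window_length:
            raise ValueError("motif extends outside the window")
        forbidden = {center - 2, center - 1, center}
        if forbidden & set(cols.tolist()):
            raise ValueError(
                "motif overlaps the fixed center B-C-A context "
                f"(positions {sorted(forbidden)}); choose another offset"
            )

    def motif_positions(self) -> np.ndarray:
        center = self.window_length // 2
        return center + self.motif_offset + np.arange(self.motif.shape[1])

    def to_yaml(self, path) -> None:
        doc = {
            "n_per_class": self.n_per_class,
            "window_length": self.window_length,
            "background": list(self.background),
            "motif": self.motif.tolist(),
            "motif_offset": self.motif_offset,
            "signal_strength": self.signal_strength,
            "n_chromosomes": self.n_chromosomes,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["background"] = tuple(doc.get("background", (0.25,) * 4))
        doc["motif"] = np.asarray(doc.get("motif", pwm_from_consensus("GGACGU")))
        return cls(**doc)


def _draw_windows(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    """Background windows (as letter indices) with the B-C-A center imposed."""
    idx = rng.choice(4, size=(n, spec.window_length), p=np.asarray(spec.background))
    center = spec.window_length // 2
    idx[:, center] = 0  # A
    idx[:, center - 1] = 1  # C
    b_probs = np.asarray(spec.background)[1:]
    b_probs = b_probs / b_probs.sum()
    idx[:, center - 2] = rng.choice([1, 2, 3], size=n, p=b_probs)  # B in {C,G,U}
    return idx


def generate_synthetic_dataset(spec: SyntheticSpec) -> BenchmarkDataset:
    """Balanced dataset of `2 * n_per_class` windows, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    neg = _draw_windows(rng, spec.n_per_class, spec)
    pos = _draw_windows(rng, spec.n_per_class, spec)
    carriers = rng.random(spec.n_per_class) < spec.signal_strength
    cols = spec.motif_positions()
    for j, col in enumerate(cols):
        draws = rng.choice(4, size=spec.n_per_class, p=spec.motif[:, j])
        pos[carriers, col] = draws[carriers]

    records: list[SampleRecord] = []
    flank = spec.window_length // 2
    all_idx = np.concatenate([pos, neg])
    labels = [1] * spec.n_per_class + [0] * spec.n_per_class
    for i, (row, label) in enumerate(zip(all_idx, labels)):
        window = "".join(_LETTERS[row])
        chrom = f"chr{(i % spec.n_chromosomes) + 1}"
        site = GenomicSite(
            chromosome=chrom,
            position=flank + i * spec.window_length,
            strand="+",
            label="positive" if label else "negative",
        )
        records.append(SampleRecord(site=site, window=window, label=label))
    return BenchmarkDataset(
        records=records,
        flank=flank,
        metadata={"synthetic": True, "seed": spec.seed,
                  "signal_strength": spec.signal_strength},
    )


def estimate_bayes_gap(spec: SyntheticSpec):
    """Probability that a background window shows the motif at its offset.

    For a deterministic (consensus) PWM this is the product of the
    background probabilities of the consensus letters — the motif-collision
    rate that bounds achievable accuracy.  For a degenerate PWM a
    (lower, upper) interval is returned, built from the least/most likely
    admissible letter per column.
    """
    bg = np.asarray(spec.background)
    deterministic = np.all(np.isin(spec.motif, (0.0, 1.0)))
    if deterministic:
        letters = spec.motif.argmax(axis=0)
        return float(np.prod(bg[letters]))
    lo = hi = 1.0
    for j in range(spec.motif.shape[1]):
        admissible = bg[spec.motif[:, j] > 0]
        lo *= float(admissible.min())
        hi *= float(admissible.max())
    return (lo, hi)


def expected_positive_motif_rate(spec: SyntheticSpec) -> float:
    """Expected motif frequency in the positive class: lam + (1-lam)*bg_rate."""
    bg_rate = estimate_bayes_gap(spec)
    if isinstance(bg_rate, tuple):
        raise ValueError("defined only for deterministic consensus motifs")
    lam = spec.signal_strength
    return lam + (1.0 - lam) * bg_rate
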