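"""Benchmark-dataset construction: window extraction, motif filtering,
redundancy removal, negative sampling and split planning.

Coordinates follow BED conventions on input (0-based position of the
candidate adenosine).  Minus-strand sites are reverse-complemented before
T->U normalization, so every emitted window reads 5'->3' on the transcript
strand with the candidate A at the center.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .encoding import SequenceError, normalize_sequence

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20  # xi: 41-nt windows

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    """Reverse complement in the DNA alphabet (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    chromosome: str
    position: int  # 0-based coordinate of the candidate A
    strand: str
    label: str  # positive | negative | candidate

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")


@dataclass(frozen=True)
class SampleRecord:
    site: GenomicSite
    window: str
    label: int  # 1 positive, 0 negative

    @property
    def record_id(self) -> str:
        s = self.site
        return f"{s.chromosome}:{s.position}:{s.strand}:{self.label}"


@dataclass
class BenchmarkDataset:
    records: list[SampleRecord]
    flank: int = DEFAULT_FLANK
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_negative(self) -> int:
        return sum(r.label == 0 for r in self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def windows(self) -> list[str]:
        return [r.window for r in self.records]


@dataclass
class SplitPlan:
    """Disjoint, exhaustive assignment of record ids to partitions."""

    name: str
    assignment: dict[str, str]  # record_id -> "train" | "test"
    seed: int | None = None

    def ids(self, group: str) -> list[str]:
        return [rid for rid, g in self.assignment.items() if g == group]

    @property
    def train_ids(self) -> list[str]:
        return self.ids("train")

    @property
    def test_ids(self) -> list[str]:
        return self.ids("test")


# ---------------------------------------------------------------------------
# window extraction & motif filtering


def extract_window(reference: dict[str, str], site: GenomicSite, flank: int = DEFAULT_FLANK) -> SampleRecord:
    """Cut the (2*flank+1)-nt window centered on `site` from `reference`.

    Raises if the window overruns the sequence ends or if the center is
    not adenosine after strand handling.
    """
    try:
        chrom_seq = reference[site.chromosome]
    except KeyError:
        raise KeyError(f"chromosome {site.chromosome!r} not in reference") from None
    start = site.position - flank
    end = site.position + flank + 1
    if start < 0 or end > len(chrom_seq):
        raise ValueError(
            f"window for site {site.chromosome}:{site.position}:{site.strand} "
            f"out of bounds (need [{start}, {end}) in sequence of length {len(chrom_seq)})"
        )
    raw = chrom_seq[start:end]
    if site.strand == "-":
        raw = reverse_complement(raw)
    window = normalize_sequence(raw)
    center = window[flank]
    if center != "A":
        raise ValueError(
            f"site {site.chromosome}:{site.position}:{site.strand} has center "
            f"{center!r}, expected A"
        )
    label = 1 if site.label == "positive" else 0
    return SampleRecord(site=site, window=window, label=label)


def has_bca_center(record_or_window) -> bool:
    """True iff the center trinucleotide is B-C-A with B in {C,G,U}.

    Positions (-2, -1, 0) relative to the central candidate A.
    """
    window = record_or_window.window if isinstance(record_or_window, SampleRecord) else record_or_window
    center = len(window) // 2
    if len(window) < 3 or center < 2:
        raise ValueError("window too short for center-context check")
    return (
        window[center] == "A"
        and window[center - 1] == "C"
        and window[center - 2] in "CGU"
    )


# ---------------------------------------------------------------------------
# redundancy removal


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("internal identity backend requires equal-length windows")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def redundancy_filter(
    records: list[SampleRecord],
    identity_threshold: float = 0.8,
    backend: str = "internal",
) -> list[SampleRecord]:
    """Greedy clustering at the given global-identity threshold.

    The first-seen member of each cluster is retained (order-dependent but
    deterministic).  The ``cd-hit-est`` backend shells out to the external
    binary when present; the internal backend computes ungapped
    matches/length identity over the equal-length windows.
    """
    if not records:
        raise ValueError("no records to filter")
    if backend == "internal":
        retained: list[SampleRecord] = []
        for rec in records:
            if all(_identity(rec.window, kept.window) < identity_threshold for kept in retained):
                retained.append(rec)
        return retained
    if backend == "cd-hit-est":
        if not 0.8 <= identity_threshold < 1.0:
            raise ValueError("cd-hit-est supports nucleotide thresholds in [0.8, 1.0)")
        return _cdhit_filter(records, identity_threshold)
    raise ValueError(f"unknown backend {backend!r}; use 'internal' or 'cd-hit-est'")


def _cdhit_filter(records: list[SampleRecord], threshold: float) -> list[SampleRecord]:
    exe = shutil.which("cd-hit-est")
    if exe is None:
        raise RuntimeError(
            "cd-hit-est binary not found on PATH; rerun with backend='internal'"
        )
    by_id = {r.record_id: r for r in records}
    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "in.fasta"
        out = Path(tmp) / "out"
        with open(fasta_in, "w") as fh:
            for r in records:
                fh.write(f">{r.record_id}\n{r.window}\n")
        subprocess.run(
            [exe, "-i", str(fasta_in), "-o", str(out), "-c", str(threshold), "-n", "5"],
            check=True, capture_output=True,
        )
        kept_ids = []
        with open(str(out) + ".clstr") as fh:
            for line in fh:
                if line.rstrip().endswith("*"):  # cluster representative
                    rid = line.split(">", 1)[1].split("...", 1)[0]
                    kept_ids.append(rid)
    kept = set(kept_ids)
    return [r for r in records if r.record_id in kept]


# ---------------------------------------------------------------------------
# negative sampling & split planning


def sample_negatives(candidates: list[SampleRecord], n: int, seed: int) -> list[SampleRecord]:
    """Uniform sample of `n` negative windows without replacement."""
    bad = [r.record_id for r in candidates if not has_bca_center(r)]
    if bad:
        raise ValueError(f"{len(bad)} candidate(s) fail the center-context filter, e.g. {bad[0]}")
    if n > len(candidates):
        raise ValueError(f"requested {n} negatives but only {len(candidates)} candidates")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def train_test_split(
    dataset: BenchmarkDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Random train/test plan; stratified by label by default.

    The overall train count is round(train_fraction * N), apportioned to
    the classes by largest remainder so both partitions stay balanced.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = [r.record_id for r in dataset.records]
    labels = dataset.labels()
    rng = np.random.default_rng(seed)
    n_train_total = int(round(train_fraction * len(ids)))
    assignment: dict[str, str] = {}
    if stratified:
        classes = sorted(set(labels.tolist()))
        if len(classes) < 2:
            raise ValueError("stratified split requires both classes present")
        quotas = {}
        remainders = []
        allocated = 0
        for c in classes:
            exact = train_fraction * int((labels == c).sum())
            quotas[c] = int(exact)
            allocated += int(exact)
            remainders.append((-(exact - int(exact)), c))
        for _, c in sorted(remainders):
            if allocated >= n_train_total:
                break
            quotas[c] += 1
            allocated += 1
        for c in classes:
            members = [i for i, lab in zip(ids, labels) if lab == c]
            perm = rng.permutation(len(members))
            for rank, j in enumerate(perm):
                assignment[members[j]] = "train" if rank < quotas[c] else "test"
    else:
        perm = rng.permutation(len(ids))
        for rank, j in enumerate(perm):
            assignment[ids[j]] = "train" if rank < n_train_total else "test"
    # preserve record order in the plan
    ordered = {rid: assignment[rid] for rid in ids}
    return SplitPlan(name=f"random{int(train_fraction * 100)}", assignment=ordered, seed=seed)


def chromosome_holdout_groups(
    dataset: BenchmarkDataset,
    min_count: int = 50,
    per_class: bool = True,
) -> list[SplitPlan]:
    """Leave-one-chromosome-out plans plus one pooled small-chromosome plan.

    A chromosome gets its own hold-out plan when its record count reaches
    `min_count`; with ``per_class=True`` (default) both the positive and
    the negative count must reach it.  All remaining chromosomes are
    pooled into a single final test group.
    """
    chroms: dict[str, list[SampleRecord]] = {}
    for rec in dataset.records:
        if not rec.site.chromosome:
            raise ValueError(f"record {rec.record_id} lacks chromosome metadata")
        chroms.setdefault(rec.site.chromosome, []).append(rec)

    def qualifies(recs: list[SampleRecord]) -> bool:
        if per_class:
            pos = sum(r.label == 1 for r in recs)
            neg = len(recs) - pos
            return pos >= min_count and neg >= min_count
        return len(recs) >= min_count

    large = [c for c in chroms if qualifies(chroms[c])]
    small = [c for c in chroms if c not in large]
    plans = []
    for c in large:
        assignment = {
            r.record_id: ("test" if r.site.chromosome == c else "train")
            for r in dataset.records
        }
        plans.append(SplitPlan(name=f"holdout:{c}", assignment=assignment))
    if small:
        pooled = set(small)
        assignment = {
            r.record_id: ("test" if r.site.chromosome in pooled else "train")
            for r in dataset.records
        }
        plans.append(SplitPlan(name="holdout:" + "+".join(small), assignment=assignment))
    return plans


# ---------------------------------------------------------------------------
# end-to-end construction and I/O


def build_benchmark(
    reference: dict[str, str],
    sites: list[GenomicSite],
    flank: int = DEFAULT_FLANK,
    identity_threshold: float = 0.8,
    backend: str = "internal",
    seed: int = 0,
) -> BenchmarkDataset:
    """Full pipeline: extract -> BCA filter -> redundancy filter per class
    -> sample negatives 1:1 -> balanced benchmark.

    Windows that overlap sequence ends, contain invalid symbols, miss the
    center A or fail the BCA-context filter are dropped with logged counts.
    """
    kept: dict[str, list[SampleRecord]] = {"positive": [], "negative": []}
    drops = {"out_of_bounds": 0, "invalid_symbol": 0, "not_center_A": 0, "not_bca": 0}
    for site in sites:
        try:
            rec = extract_window(reference, site, flank)
        except SequenceError:
            drops["invalid_symbol"] += 1
            continue
        except (ValueError, KeyError) as exc:
            if "out of bounds" in str(exc) or isinstance(exc, KeyError):
                drops["out_of_bounds"] += 1
            else:
                drops["not_center_A"] += 1
            continue
        if not has_bca_center(rec):
            drops["not_bca"] += 1
            continue
        kept["positive" if rec.label == 1 else "negative"].append(rec)
    for key, n in drops.items():
        if n:
            logger.info("dropped %d site(s): %s", n, key)

    positives = redundancy_filter(kept["positive"], identity_threshold, backend) if kept["positive"] else []
    negatives = redundancy_filter(kept["negative"], identity_threshold, backend) if kept["negative"] else []
    n = min(len(positives), len(negatives))
    negatives = sample_negatives(negatives, n, seed) if negatives else []
    positives = positives[:n]
    records = positives + negatives
    return BenchmarkDataset(
        records=records,
        flank=flank,
        metadata={
            "identity_threshold": identity_threshold,
            "backend": backend,
            "seed": seed,
            "drops": drops,
        },
    )


def load_reference_fasta(path) -> dict[str, str]:
    """Read a FASTA file as {record id: uppercase sequence} (DNA or RNA)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_sites_tsv(path) -> list[GenomicSite]:
    """Read sites from BED6 or plain TSV (chrom, pos, strand, label).

    BED6 is detected by column count (>= 6 with numeric cols 2/3); there
    the name column carries the label and `pos` is the interval start.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 6 and parts[1].isdigit() and parts[2].isdigit():
                chrom, start, _end, name, _score, strand = parts[:6]
                sites.append(GenomicSite(chrom, int(start), strand, name or "candidate"))
            elif len(parts) >= 4:
                chrom, pos, strand, label = parts[:4]
                sites.append(GenomicSite(chrom, int(pos), strand, label))
            else:
                raise ValueError(f"unparseable site line: {line!r}")
    return sites


def write_dataset(dataset: BenchmarkDataset, fasta_path, tsv_path=None) -> None:
    """Write windows as FASTA (id = chrom:pos:strand:label) plus companion TSV."""
    with open(fasta_path, "w") as fh:
        for rec in dataset.records:
            fh.write(f">{rec.record_id}\n{rec.window}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("record_id\tchromosome\tposition\tstrand\tlabel\twindow\n")
            for rec in dataset.records:
                s = rec.site
                fh.write(
                    f"{rec.record_id}\t{s.chromosome}\t{s.position}\t{s.strand}\t"
                    f"{rec.label}\t{rec.window}\n"
                )


def read_dataset(fasta_path, flank: int | None = None) -> BenchmarkDataset:
    """Read a dataset written by `write_dataset` (or any window FASTA).

    Record ids of the form chrom:pos:strand:label recover provenance;
    other ids produce records with the id as chromosome and label 0.
    """
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        window = normalize_sequence(str(rec.seq))
        parts = rec.id.split(":")
        if len(parts) == 4 and parts[1].lstrip("-").isdigit() and parts[3] in ("0", "1"):
            site = GenomicSite(parts[0], int(parts[1]), parts[2],
                               "positive" if parts[3] == "1" else "negative")
            label = int(parts[3])
        else:
            site = GenomicSite(rec.id, 0, "+", "candidate")
            label = 0
        records.append(SampleRecord(site=site, window=window, label=label))
    if flank is None:
        flank = len(records[0].window) // 2 if records else DEFAULT_FLANK
    return BenchmarkDataset(records=records, flank=flank)


def write_split_plan(plan: SplitPlan, path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tpartition\n")
        for rid, group in plan.assignment.items():
            fh.write(f"{rid}\t{group}\n")
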