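import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from m6amnet.dataset import (
    BenchmarkDataset,
    GenomicSite,
    SampleRecord,
    chromosome_holdout_groups,
    extract_window,
    has_bca_center,
    read_dataset,
    read_sites_tsv,
    redundancy_filter,
    reverse_complement,
    sample_negatives,
    train_test_split,
    write_dataset,
)


def make_record(window: str, chrom="chr1", pos=100, strand="+", label=1) -> SampleRecord:
    site = GenomicSite(chrom, pos, strand, "positive" if label else "negative")
    return SampleRecord(site=site, window=window, label=label)


def random_window(rng, length=41) -> str:
    seq = list(rng.choice(list("ACGU"), size=length))
    c = length // 2
    seq[c] = "A"
    seq[c - 1] = "C"
    seq[c - 2] = rng.choice(list("CGU"))
    return "".join(seq)


class TestExtractWindow:
    def test_exact_fit(self):
        ref = {"chr1": "G" * 20 + "A" + "C" * 20}
        rec = extract_window(ref, GenomicSite("chr1", 20, "+", "positive"), flank=20)
        assert rec.window == "G" * 20 + "A" + "C" * 20
        assert rec.label == 1

    def test_out_of_bounds(self):
        ref = {"chr1": "G" * 20 + "A" + "C" * 20}
        with pytest.raises(ValueError, match="out of bounds"):
            extract_window(ref, GenomicSite("chr1", 5, "+", "positive"), flank=20)

    def test_minus_strand_matches_biopython_revcomp(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=41))
            # force a T at the center so the minus-strand window centers on A
            seq = seq[:20] + "T" + seq[21:]
            ref = {"chrX": seq}
            rec = extract_window(ref, GenomicSite("chrX", 20, "-", "negative"), flank=20)
            expected = str(Seq(seq).reverse_complement()).replace("T", "U")
            assert rec.window == expected

    def test_center_not_a(self):
        ref = {"chr1": "G" * 41}
        with pytest.raises(ValueError, match="center"):
            extract_window(ref, GenomicSite("chr1", 20, "+", "positive"), flank=20)

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_window({}, GenomicSite("chr9", 20, "+", "positive"), flank=20)

    def test_t_normalized_to_u(self):
        ref = {"chr1": "T" * 20 + "A" + "T" * 20}
        rec = extract_window(ref, GenomicSite("chr1", 20, "+", "positive"), flank=20)
        assert rec.window == "U" * 20 + "A" + "U" * 20


class TestBCACenter:
    def test_gca_true(self):
        assert has_bca_center("UU" + "GCA" + "UUUU")

    def test_aca_false(self):
        assert not has_bca_center("UU" + "ACA" + "UUUU")

    def test_gga_false(self):
        assert not has_bca_center("UU" + "GGA" + "UUUU")

    def test_all_two_letter_contexts_match_motif_oracle(self):
        for b2, b1 in itertools.product("ACGU", repeat=2):
            window = "UU" + b2 + b1 + "A" + "UUUU"  # center of 9-mer at index 4
            expected = b1 == "C" and b2 in "CGU"
            assert has_bca_center(window) == expected

    def test_center_not_a(self):
        assert not has_bca_center("UUCCGUUUU")

    def test_too_short(self):
        with pytest.raises(ValueError):
            has_bca_center("CA")


class TestRedundancyFilter:
    def test_identical_collapse(self):
        w = random_window(np.random.default_rng(0))
        kept = redundancy_filter([make_record(w, pos=1), make_record(w, pos=2)], 0.8)
        assert len(kept) == 1
        assert kept[0].site.position == 1  # first seen wins

    def test_below_threshold_kept(self):
        rng = np.random.default_rng(1)
        a = random_window(rng)
        b = list(a)
        # mutate 9 of 41 positions away from the center context
        mutable = [i for i in range(41) if i not in (18, 19, 20)][:9]
        for i in mutable:
            b[i] = {"A": "C", "C": "G", "G": "U", "U": "A"}[b[i]]
        b = "".join(b)
        ident = sum(x == y for x, y in zip(a, b)) / 41
        assert ident < 0.8
        kept = redundancy_filter([make_record(a, pos=1), make_record(b, pos=2)], 0.8)
        assert len(kept) == 2

    def test_random_windows_all_retained(self):
        rng = np.random.default_rng(2)
        records = [make_record(random_window(rng), pos=i) for i in range(50)]
        kept = redundancy_filter(records, 0.8)
        assert len(kept) == len(records)

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        # mix of random windows and near-duplicates
        base = [random_window(rng) for _ in range(30)]
        dups = []
        for w in base[:10]:
            mutated = list(w)
            mutated[0] = {"A": "C", "C": "G", "G": "U", "U": "A"}[mutated[0]]
            dups.append("".join(mutated))
        records = [make_record(w, pos=i) for i, w in enumerate(base + dups)]
        kept = redundancy_filter(records, 0.8)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                ident = sum(x == y for x, y in zip(a.window, b.window)) / 41
                assert ident < 0.8

    def test_missing_binary_error(self, monkeypatch):
        monkeypatch.setattr("shutil.which", lambda _: None)
        with pytest.raises(RuntimeError, match="internal"):
            redundancy_filter([make_record("CCA" * 13 + "CA")], 0.8, backend="cd-hit-est")

    def test_unknown_backend(self):
        with pytest.raises(ValueError):
            redundancy_filter([make_record("GCA")], 0.8, backend="vsearch")

    def test_empty_error(self):
        with pytest.raises(ValueError):
            redundancy_filter([], 0.8)


class TestSampleNegatives:
    def _candidates(self, n=20):
        rng = np.random.default_rng(5)
        return [make_record(random_window(rng), pos=i, label=0) for i in range(n)]

    def test_balanced_count(self):
        out = sample_negatives(self._candidates(), 10, seed=1)
        assert len(out) == 10

    def test_deterministic(self):
        c = self._candidates()
        a = sample_negatives(c, 10, seed=1)
        b = sample_negatives(c, 10, seed=1)
        assert [r.record_id for r in a] == [r.record_id for r in b]

    def test_zero(self):
        assert sample_negatives(self._candidates(), 0, seed=1) == []

    def test_too_many(self):
        with pytest.raises(ValueError, match="20"):
            sample_negatives(self._candidates(), 21, seed=1)

    def test_rejects_non_bca(self):
        bad = make_record("GG" + "GGA" + "GGGG", pos=0, label=0)
        with pytest.raises(ValueError, match="center-context"):
            sample_negatives([bad], 1, seed=0)


def balanced_dataset(n_per_class=500, n_chrom=1) -> BenchmarkDataset:
    rng = np.random.default_rng(11)
    records = []
    for i in range(2 * n_per_class):
        label = 1 if i < n_per_class else 0
        records.append(make_record(random_window(rng), chrom=f"chr{i % n_chrom + 1}",
                                   pos=i, label=label))
    return BenchmarkDataset(records=records)


class TestTrainTestSplit:
    def test_80_20_counts(self):
        ds = balanced_dataset(500)
        plan = train_test_split(ds, 0.8, seed=0)
        assert len(plan.train_ids) == 800 and len(plan.test_ids) == 200
        labels = {r.record_id: r.label for r in ds.records}
        for group, expect in (("train", 400), ("test", 100)):
            ids = plan.ids(group)
            assert sum(labels[i] for i in ids) == expect

    def test_two_records(self):
        ds = balanced_dataset(1)
        plan = train_test_split(ds, 0.5, seed=0)
        assert len(plan.train_ids) == 1 and len(plan.test_ids) == 1

    def test_deterministic(self):
        ds = balanced_dataset(50)
        assert train_test_split(ds, 0.8, seed=3).assignment == \
            train_test_split(ds, 0.8, seed=3).assignment

    def test_disjoint_exhaustive(self):
        ds = balanced_dataset(50)
        plan = train_test_split(ds, 0.8, seed=3)
        ids = {r.record_id for r in ds.records}
        assert set(plan.train_ids) | set(plan.test_ids) == ids
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_single_class_stratified_error(self):
        rng = np.random.default_rng(0)
        ds = BenchmarkDataset(records=[make_record(random_window(rng), pos=i) for i in range(10)])
        with pytest.raises(ValueError, match="both classes"):
            train_test_split(ds, 0.8, seed=0)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            train_test_split(balanced_dataset(5), 1.5, seed=0)


class TestChromosomeHoldout:
    def _dataset(self, counts: dict[str, int]) -> BenchmarkDataset:
        rng = np.random.default_rng(9)
        records = []
        pos = 0
        for chrom, n in counts.items():
            for i in range(n):
                records.append(make_record(random_window(rng), chrom=chrom,
                                           pos=pos, label=i % 2))
                pos += 1
        return BenchmarkDataset(records=records)

    def test_threshold_rule_total_counts(self):
        ds = self._dataset({"chr1": 100, "chr2": 60, "chr3": 30, "chr4": 10})
        plans = chromosome_holdout_groups(ds, min_count=50, per_class=False)
        names = [p.name for p in plans]
        assert names == ["holdout:chr1", "holdout:chr2", "holdout:chr3+chr4"]
        pooled = plans[-1]
        chroms = {rid.split(":")[0] for rid in pooled.test_ids}
        assert chroms == {"chr3", "chr4"}

    def test_no_pooled_group_when_all_large(self):
        ds = self._dataset({"chr1": 120, "chr2": 120})
        plans = chromosome_holdout_groups(ds, min_count=50, per_class=False)
        assert [p.name for p in plans] == ["holdout:chr1", "holdout:chr2"]

    def test_never_splits_a_chromosome(self):
        ds = self._dataset({"chr1": 120, "chr2": 80, "chr3": 20})
        for plan in chromosome_holdout_groups(ds, min_count=50, per_class=False):
            train_chroms = {rid.split(":")[0] for rid in plan.train_ids}
            test_chroms = {rid.split(":")[0] for rid in plan.test_ids}
            assert not train_chroms & test_chroms

    def test_partition_disjoint_exhaustive(self):
        ds = self._dataset({"chr1": 120, "chr2": 80, "chr3": 20})
        all_ids = {r.record_id for r in ds.records}
        for plan in chromosome_holdout_groups(ds, min_count=50, per_class=False):
            assert set(plan.train_ids) | set(plan.test_ids) == all_ids
            assert not set(plan.train_ids) & set(plan.test_ids)

    def test_per_class_counting(self):
        # 60 records but only 25 positives: pooled under per-class counting
        rng = np.random.default_rng(10)
        records = [make_record(random_window(rng), chrom="chrA", pos=i,
                               label=1 if i < 25 else 0) for i in range(60)]
        records += [make_record(random_window(rng), chrom="chrB", pos=100 + i,
                                label=i % 2) for i in range(120)]
        ds = BenchmarkDataset(records=records)
        plans = chromosome_holdout_groups(ds, min_count=50, per_class=True)
        assert [p.name for p in plans] == ["holdout:chrB", "holdout:chrA"]


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        ds = balanced_dataset(10, n_chrom=2)
        fasta = tmp_path / "ds.fasta"
        tsv = tmp_path / "ds.tsv"
        write_dataset(ds, fasta, tsv)
        back = read_dataset(fasta)
        assert [r.record_id for r in back.records] == [r.record_id for r in ds.records]
        assert [r.window for r in back.records] == [r.window for r in ds.records]
        assert back.flank == ds.flank
        assert tsv.read_text().count("\n") == len(ds) + 1

    def test_read_sites_tsv(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("chr1\t100\t+\tpositive\nchr2\t50\t-\tnegative\n")
        sites = read_sites_tsv(path)
        assert sites[0] == GenomicSite("chr1", 100, "+", "positive")
        assert sites[1].strand == "-"

    def test_read_sites_bed6(self, tmp_path):
        path = tmp_path / "sites.bed"
        path.write_text("chr1\t100\t101\tpositive\t0\t+\n")
        sites = read_sites_tsv(path)
        assert sites[0] == GenomicSite("chr1", 100, "+", "positive")


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA"))
    assert reverse_complement("AACC") == "GGTT"
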