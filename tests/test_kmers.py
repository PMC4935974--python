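"""k-mer counting, enrichment profiles, positional histograms, motif scans."""

import numpy as np
import pytest
from scipy import stats

from rbpscape.annotation import FeatureRecord, RegionLabel, build_annotation
from rbpscape.intervals import GenomicInterval
from rbpscape.kmers import (
    EmptyKmerTableError,
    compare_distributions,
    count_kmers,
    kmer_enrichment,
    motif_positional_histogram,
    sample_background_clusters,
    scan_motif_presence,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


class TestCountKmers:
    def test_single_word(self):
        t = count_kmers(["GGUA"], 4)
        assert t.counts == {"GGUA": 1}
        assert t.freqs == {"GGUA": 1.0}

    def test_overlapping_windows(self):
        assert count_kmers(["GGGG"], 2).counts == {"GG": 3}

    def test_windows_with_n_are_skipped(self):
        assert count_kmers(["GGNA"], 2).counts == {"GG": 1}

    def test_dna_input_transcribed(self):
        assert count_kmers(["GGTA"], 4).counts == {"GGUA": 1}

    def test_k_longer_than_all_sequences_errors(self):
        with pytest.raises(EmptyKmerTableError):
            count_kmers(["ACG", "GU"], 5)

    def test_total_and_order_invariance(self):
        seqs = ["GGUAAGUCCA", "AUGCN", "GG"]
        a = count_kmers(seqs, 3)
        b = count_kmers(seqs[::-1], 3)
        assert a.counts == b.counts
        # total = sum over sequences of countable windows
        # GGUAAGUCCA: 8; AUGCN: windows AUG,UGC,GCN -> 2; GG: 0
        assert a.total == 10


class TestEnrichment:
    def test_percent_enrichment_values(self):
        real = count_kmers(["GGUAGGUA"], 4)  # GGUA f=2/5
        bg = count_kmers(["GGUAACGU"], 4)  # GGUA f=1/5
        prof = kmer_enrichment(real, bg, seed_4mer="GGUA")
        assert prof.loc["GGUA", "percent_enrichment"] == pytest.approx(100.0)
        assert bool(prof.loc["GGUA", "contains_seed"])

    def test_identity_gives_zero(self):
        t = count_kmers(["ACGUACGU"], 4)
        prof = kmer_enrichment(t, t)
        assert (prof["percent_enrichment"].abs() < 1e-12).all()

    def test_seed_flag_is_substring_match(self):
        real = count_kmers(["GGUAAG"], 6)
        prof = kmer_enrichment(real, real, seed_4mer="GGUA")
        assert bool(prof.loc["GGUAAG", "contains_seed"])

    def test_background_zero_is_nan_and_excluded(self):
        real = count_kmers(["AAAA"], 4)
        bg = count_kmers(["CCCC"], 4)
        prof = kmer_enrichment(real, bg, seed_4mer="AAAA")
        assert np.isnan(prof.loc["AAAA", "percent_enrichment"])
        with pytest.raises(ValueError):
            # only the NaN k-mer carries the seed -> group empty after drop
            compare_distributions(prof)


class TestCompareDistributions:
    def test_identical_groups(self):
        import pandas as pd

        prof = pd.DataFrame(
            {
                "percent_enrichment": [1.0, 2.0, 3.0] * 2,
                "contains_seed": [True] * 3 + [False] * 3,
            }
        )
        d, p = compare_distributions(prof)
        assert d == 0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        import pandas as pd

        prof = pd.DataFrame(
            {
                "percent_enrichment": [10.0, 11.0, 12.0, 0.0, 1.0, 2.0],
                "contains_seed": [True] * 3 + [False] * 3,
            }
        )
        d, _ = compare_distributions(prof)
        assert d == 1.0

    def test_detects_planted_mean_shift(self):
        """Seed group shifted +50% vs background scatter: P < 0.01 in >= 95%
        of seeded repetitions at n = 100 vs 4000."""
        import pandas as pd

        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(50, 20, 100), rng.normal(0, 20, 4000)])
            prof = pd.DataFrame(
                {
                    "percent_enrichment": vals,
                    "contains_seed": [True] * 100 + [False] * 4000,
                }
            )
            if compare_distributions(prof)[1] < 0.01:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestBackgroundSampling:
    @pytest.fixture
    def clusters_and_labels(self, two_gene_annotation):
        clusters = [iv(20, 60), iv(200, 240), iv(920, 960)]
        labels = [RegionLabel.FIVE_UTR, RegionLabel.PROXIMAL_INTRON, RegionLabel.THREE_UTR]
        return clusters, labels

    def test_lengths_and_classes_preserved(self, two_gene_annotation, clusters_and_labels):
        clusters, labels = clusters_and_labels
        bg = sample_background_clusters(clusters, labels, two_gene_annotation, seed=1)
        assert sorted(len(b) for b in bg) == sorted(len(c) for c in clusters)
        pool = two_gene_annotation.region_interval_pool()
        for b, label in zip(bg, labels):
            assert any(
                b.start >= p.start and b.end <= p.end and b.strand == p.strand
                for p in pool[label]
            )

    def test_deterministic_given_seed(self, two_gene_annotation, clusters_and_labels):
        clusters, labels = clusters_and_labels
        a = sample_background_clusters(clusters, labels, two_gene_annotation, seed=7)
        b = sample_background_clusters(clusters, labels, two_gene_annotation, seed=7)
        assert a == b

    def test_oversized_cluster_skipped_with_warning(self, toy_annotation):
        huge = iv(0, 5000)
        with pytest.warns(UserWarning, match="skipped"):
            bg = sample_background_clusters(
                [huge], [RegionLabel.EXON], toy_annotation, seed=0
            )
        assert bg == []


class TestPositionalHistogram:
    def test_motif_planted_at_cluster_centers(self):
        rng = np.random.default_rng(0)
        seq = list("".join(rng.choice(list("AC"), 50_000)))  # motif-free bg
        centers = range(2_000, 48_000, 1_000)
        clusters = []
        for c in centers:
            for j, ch in enumerate("GGTAAG"):
                seq[c + j] = ch
            clusters.append(iv(c - 20, c + 20))
        hist = motif_positional_histogram(
            clusters, {"chr1": "".join(seq)}, "GGUAAG", window=1000, bin_width=10
        )
        assert hist.counts.sum() == len(clusters)
        assert hist.bin_centers[hist.counts.argmax()] == pytest.approx(5.0)

    def test_motif_absent(self):
        hist = motif_positional_histogram(
            [iv(500, 540)], {"chr1": "A" * 2000}, "GGUAAG"
        )
        assert hist.counts.sum() == 0

    def test_minus_strand_offsets_mirror(self):
        # motif 30 nt downstream (in transcript direction) of the center
        seq = list("A" * 4000)
        center = 2000
        # on the minus strand, downstream = lower genomic coordinates and
        # the sense-strand motif appears reverse-complemented in the genome
        pos = center - 30  # motif start (transcript direction) at +30
        for j, ch in enumerate("CTTACC"):  # revcomp(GGTAAG)
            seq[pos - 6 + 1 + j] = ch
        hist = motif_positional_histogram(
            [iv(center - 20, center + 20, strand="-")],
            {"chr1": "".join(seq)},
            "GGUAAG",
            window=1000,
            bin_width=10,
        )
        assert hist.counts.sum() == 1
        offset_bin = hist.bin_centers[hist.counts.argmax()]
        assert 25 <= offset_bin <= 35

    def test_uniform_placement_is_flat(self):
        """Motif occurrences in i.i.d. sequence are uniform around random
        cluster centers (chi-square goodness of fit, P > 0.01)."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 600_000))
        centers = rng.integers(1_000, 599_000, 600)
        clusters = [iv(int(c) - 20, int(c) + 20) for c in centers]
        hist = motif_positional_histogram(clusters, {"chr1": seq}, "GGU", window=1000)
        assert hist.counts.sum() > 5_000
        res = stats.chisquare(hist.counts)
        assert res.pvalue > 0.01


class TestMotifScan:
    @pytest.fixture
    def annotation_and_genome(self):
        ann = build_annotation(
            [
                FeatureRecord("chr1", 0, 300, "+", "gene", "g"),
                FeatureRecord("chr1", 0, 100, "+", "exon", "g"),
                FeatureRecord("chr1", 200, 300, "+", "exon", "g"),
                FeatureRecord("chr1", 200, 300, "+", "three_utr", "g"),
            ]
        )
        genome = {"chr1": "A" * 300}
        return ann, genome

    def plant(self, genome, pos, word="GGTAA"):
        s = list(genome["chr1"])
        s[pos : pos + len(word)] = word
        return {"chr1": "".join(s)}

    def test_match_in_requested_region(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        genome = self.plant(genome, 250)  # inside the 3'UTR
        assert scan_motif_presence(ann, genome, "GGUAA", ["three_utr", "intron"]) == {
            "g": True
        }

    def test_absent_everywhere(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        assert scan_motif_presence(ann, genome, "GGUAA", ["three_utr", "intron"]) == {
            "g": False
        }

    def test_region_restriction(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        genome = self.plant(genome, 20)  # inside the coding exon only
        assert scan_motif_presence(ann, genome, "GGUAA", ["three_utr", "intron"]) == {
            "g": False
        }
        assert scan_motif_presence(ann, genome, "GGUAA", ["exon"]) == {"g": True}

    def test_iupac_r_degeneracy(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        genome = self.plant(genome, 120, word="GTAAGT")  # intron, GURAGU w/ R=A? no:
        # GUAAGU matches GURAGU at R=A
        assert scan_motif_presence(ann, genome, "GURAGU", ["intron"]) == {"g": True}
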