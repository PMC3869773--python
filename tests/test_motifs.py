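import numpy as np
import pytest
from hypothesis import given, strategies as st

from polpool.motifs import (
    LocusWindow,
    Motif,
    PromoterWindow,
    denovo_discover,
    extract_promoters,
    hamming,
    redundancy_distance,
    repeat_filter,
    reverse_complement,
    scan_locus,
    scan_sequence,
    zoops_count,
)
from polpool.simulate import SimulationConfig, simulate_genome_with_motifs
from polpool.tables_io import GeneModel

# 50-mer pull-down probes (written 5'->3'; motif cores in the middle)
IL4_PROBE = "GCCAAGCTTGTGAGTCTGAGTTCAAGGATCCACACGGTGCAAAGAGAGAC"
IL4_SCRAMBLE = "GCCAAGCTTGTGAGTCTGAGCGTGCATGCACACACGGTGCAAAGAGAGAC"
IL5_PROBE = "TTACTAAAAGGCCAACCCAGACTGAGTGGAGATAAGAGGATGCTTCTTGG"
IL5_SCRAMBLE = "TTACTAAAAGGCCAACCCAGCAGATTGCTTTATAAGAGGATGCTTCTTGG"
MOTIF1 = Motif("motif1", "CACTGAGTGGAG", 2)
MOTIF3 = Motif("motif3", "TCCAAGGATC", 1)


def oracle_scan(seq, word, max_mm):
    """Brute-force forward-strand Hamming scan."""
    k = len(word)
    return [
        (i, sum(a != b or a == "N" for a, b in zip(seq[i : i + k], word)))
        for i in range(len(seq) - k + 1)
        if sum(a != b or a == "N" for a, b in zip(seq[i : i + k], word)) <= max_mm
    ]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMotifType:
    def test_default_mismatch_budgets(self):
        assert Motif("m", "TCCAAGGATC").max_mismatches == 1  # 10-mer
        assert Motif("m", "CACTGAGTGGAG").max_mismatches == 2  # 12-mer

    def test_invalid_motifs_rejected(self):
        with pytest.raises(ValueError):
            Motif("m", "ACGTN" * 2)
        with pytest.raises(ValueError):
            Motif("m", "ACGT")  # too short
        with pytest.raises(ValueError):
            Motif("m", "ACGTACGT", 8)  # budget >= length


class TestScanSequence:
    def test_pulldown_probe_cores_found(self):
        hits = scan_sequence(IL4_PROBE, MOTIF3, both_strands=False)
        assert [(h.offset, h.mismatches) for h in hits] == [(20, 1)]
        assert IL4_PROBE[20:30] == "TTCAAGGATC"
        hits5 = scan_sequence(IL5_PROBE, MOTIF1, both_strands=False)
        assert (19, 1) in [(h.offset, h.mismatches) for h in hits5]
        assert IL5_PROBE[19:31] == "GACTGAGTGGAG"

    def test_scrambled_cores_lose_the_hits(self):
        for seq, motif, intact in [
            (IL4_SCRAMBLE, MOTIF3, IL4_PROBE),
            (IL5_SCRAMBLE, MOTIF1, IL5_PROBE),
        ]:
            scram = scan_sequence(seq, motif, both_strands=False)
            whole = scan_sequence(intact, motif, both_strands=False)
            assert len(scram) < len(whole)
            assert len(scram) == 0

    def test_matches_exhaustive_oracle_on_probes(self):
        for seq, motif in [
            (IL4_PROBE, MOTIF3),
            (IL4_SCRAMBLE, MOTIF3),
            (IL5_PROBE, MOTIF1),
            (IL5_SCRAMBLE, MOTIF1),
        ]:
            got = [
                (h.offset, h.mismatches)
                for h in scan_sequence(seq, motif, both_strands=False)
            ]
            assert got == oracle_scan(seq, motif.sequence, motif.max_mismatches)

    def test_self_scan_identity(self):
        m = Motif("m", "TCCAAGGATC", 0)
        hits = scan_sequence(m.sequence, m, both_strands=False)
        assert [(h.offset, h.strand, h.mismatches) for h in hits] == [(0, "+", 0)]

    def test_short_sequence_yields_no_hits(self):
        assert scan_sequence("ACGT", MOTIF3) == []

    def test_n_bases_never_match(self):
        m = Motif("m", "ACGTACGTAC", 0)
        assert scan_sequence("ACGTACGTAC".replace("C", "N", 1), m, both_strands=False) == []

    def test_exact_scan_agrees_with_substring_search(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = random_seq(rng, 300)
            word = random_seq(rng, 8)
            m = Motif("m", word, 0)
            got = {h.offset for h in scan_sequence(seq, m, both_strands=False)}
            expected, start = set(), 0
            while (i := seq.find(word, start)) != -1:
                expected.add(i)
                start = i + 1
            assert got == expected

    def test_hit_count_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 2000)
        counts = [
            len(scan_sequence(seq, Motif("m", "TCCAAGGATC", mm))) for mm in range(4)
        ]
        assert counts == sorted(counts)

    def test_reverse_complement_maps_strands(self):
        rng = np.random.default_rng(9)
        seq = random_seq(rng, 500)
        m = Motif("m", "CACTGAGTGGAG", 2)
        fwd = scan_sequence(seq, m, both_strands=True)
        rev = scan_sequence(reverse_complement(seq), m, both_strands=True)
        remap = {
            (len(seq) - h.offset - len(m), {"+": "-", "-": "+"}[h.strand], h.mismatches)
            for h in rev
        }
        assert {(h.offset, h.strand, h.mismatches) for h in fwd} == remap


class TestExtractPromoters:
    GENOME = {"chr1": "".join(np.random.default_rng(0).choice(list("ACGT"), size=5000))}

    def test_plus_strand_window(self):
        model = GeneModel("g1", "chr1", 2000, 3000, "+")
        seq = extract_promoters([model], self.GENOME)["g1"]
        assert seq == self.GENOME["chr1"][1000:2100]
        assert len(seq) == 1100

    def test_minus_strand_window_is_reverse_complemented(self):
        model = GeneModel("g2", "chr1", 2000, 3000, "-")
        seq = extract_promoters([model], self.GENOME)["g2"]
        assert seq == reverse_complement(self.GENOME["chr1"][2900:4000])

    def test_clipping_at_contig_edge(self, caplog):
        model = GeneModel("g3", "chr1", 500, 1500, "+")
        with caplog.at_level("WARNING"):
            seq = extract_promoters([model], self.GENOME)["g3"]
        assert len(seq) == 600
        assert "clipped" in caplog.text

    def test_missing_chromosome_named(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_promoters([GeneModel("g", "chrX", 0, 10, "+")], self.GENOME)

    def test_simulated_promoters_contain_planted_literal(self):
        cfg = SimulationConfig(
            n_genes=30, seed=21, motif_plant_rate_target=1.0,
            motif_plant_rate_background=0.0,
        )
        genome, models, truth = simulate_genome_with_motifs(cfg, gene_length=500)
        promoters = extract_promoters(models, genome)
        assert truth.motif_plants
        for plant in truth.motif_plants:
            prom = promoters[plant["gene_id"]]
            off = plant["promoter_offset"]
            assert prom[off : off + len(cfg.planted_motif)] == cfg.planted_motif.sequence


class TestScanLocus:
    def test_planted_copy_found_at_genomic_coordinate(self):
        cfg = SimulationConfig(
            n_genes=6, seed=5, motif_plant_rate_target=1.0, motif_plant_rate_background=0.0
        )
        genome, models, truth = simulate_genome_with_motifs(cfg, gene_length=500)
        by_gene = {m.gene_id: m for m in models}
        for plant in truth.motif_plants:
            motif = Motif("planted", cfg.planted_motif.sequence, 0)
            hits = scan_locus(by_gene[plant["gene_id"]], genome, motif)
            assert plant["position"] in {h.offset for h in hits}

    def test_zero_flank_excludes_flank_plants(self):
        genome = {"c": "A" * 3000}
        word = "TCCAAGGATC"
        seq = genome["c"][:500] + word + genome["c"][510:]
        genome = {"c": seq}  # plant at 500, upstream of the gene body
        model = GeneModel("g", "c", 1000, 2000, "+")
        m = Motif("m", word, 0)
        assert scan_locus(model, genome, m, LocusWindow(flank=0)) == []
        assert 500 in {h.offset for h in scan_locus(model, genome, m, LocusWindow(flank=10_000))}

    def test_minus_strand_plant_needs_both_strands(self):
        rng = np.random.default_rng(13)
        body = random_seq(rng, 1000)
        word = "TCCAAGGATC"
        seq = body[:300] + reverse_complement(word) + body[310:]
        genome = {"c": seq}
        model = GeneModel("g", "c", 0, len(seq), "+")
        m = Motif("m", word, 0)
        both = {h.offset for h in scan_locus(model, genome, m, LocusWindow(0), both_strands=True)}
        fwd = {h.offset for h in scan_locus(model, genome, m, LocusWindow(0), both_strands=False)}
        assert 300 in both
        assert 300 not in fwd


class TestZoops:
    def test_multiple_hits_count_once(self):
        word = "TCCAAGGATC"
        rng = np.random.default_rng(1)
        seqs = {}
        for i in range(10):
            s = random_seq(rng, 200)
            if i < 4:
                s = word + s[len(word):]
                if i == 0:
                    s = s[:100] + word + s[100 + len(word):]
            seqs[f"s{i}"] = s
        assert zoops_count(seqs, Motif("m", word, 0)) == 4

    def test_empty_input(self):
        assert zoops_count({}, MOTIF3) == 0

    def test_background_hit_rate_matches_analytic_expectation(self):
        # exact forward matches of a 10-mer in random DNA: per-window rate 4^-10
        rng = np.random.default_rng(17)
        n, L, k = 500, 1100, 10
        seqs = {f"s{i}": random_seq(rng, L) for i in range(n)}
        m = Motif("m", "TCCAAGGATC", 1)
        count = zoops_count(seqs, m, both_strands=False)
        p_word = sum(
            __import__("math").comb(k, i) * 3**i for i in range(m.max_mismatches + 1)
        ) / 4**k
        p_seq = 1 - (1 - p_word) ** (L - k + 1)
        mean, sd = n * p_seq, (n * p_seq * (1 - p_seq)) ** 0.5
        assert abs(count - mean) < 4 * sd + 1


class TestRepeatFilter:
    @pytest.mark.parametrize(
        "seq,rejected",
        [
            ("ACACACACAC", True),
            ("AAAAAAAAAA", True),
            ("AGTAGTAGTAGT", True),
            ("CACTGAGTGGAG", False),
            ("TCCAAGGATC", False),
        ],
    )
    def test_examples(self, seq, rejected):
        assert repeat_filter(seq) is rejected


class TestRedundancyDistance:
    def test_shifted_variants_score_low(self):
        assert redundancy_distance("TCCAAGGATC", "TTCCAAGGAT", 2) == 1
        assert redundancy_distance("TCCAAGGATC", "TACAAGGATC", 2) == 1
        assert hamming("TCCAAGGATC", "TTCCAAGGAT") == 6

    def test_unrelated_words_score_high(self):
        assert redundancy_distance("AAACCCGGGT", "TGTGTGACAC", 2) > 4


class TestDenovoDiscover:
    def test_planted_motif_recovered_rank_one(self):
        cfg = SimulationConfig(
            n_genes=90, seed=23, planted_motif=Motif("p", "TCCAAGGATC", 1),
            motif_plant_rate_target=0.8, motif_plant_rate_background=0.05,
        )
        genome, models, truth = simulate_genome_with_motifs(cfg, gene_length=500)
        promoters = extract_promoters(models, genome)
        targets = {g: promoters[g] for g in sorted(truth.target_genes)}
        background = {g: s for g, s in promoters.items() if g not in truth.target_genes}
        found = denovo_discover(targets, background, k=10, max_mm=1, min_fold=3.5)
        assert found
        top_motif, top_result = found[0]
        assert hamming(top_motif.sequence, "TCCAAGGATC") <= 1
        assert top_result.fold >= 3.5

    def test_low_complexity_discoveries_are_suppressed(self):
        rng = np.random.default_rng(31)
        polya = "AAAAAAAAAA"
        targets = {}
        for i in range(30):
            s = random_seq(rng, 300)
            targets[f"t{i}"] = s[:100] + polya + s[110:]
        background = {f"b{i}": random_seq(rng, 300) for i in range(60)}
        found = denovo_discover(targets, background, k=10, max_mm=1, min_fold=3.5)
        for motif, _ in found:
            assert not repeat_filter(motif.sequence)
            assert redundancy_distance(motif.sequence, polya, 2) > 2

    def test_no_self_enrichment_when_target_equals_background(self):
        rng = np.random.default_rng(41)
        seqs = {f"s{i}": random_seq(rng, 400) for i in range(60)}
        found = denovo_discover(seqs, dict(seqs), k=10, max_mm=1, min_fold=3.5)
        assert found == []

    def test_k_larger_than_shortest_sequence_rejected(self):
        with pytest.raises(ValueError, match="shortest"):
            denovo_discover({"t": "ACGTACGT"}, {"b": "ACGTACGTACGTACGT"}, k=10)
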