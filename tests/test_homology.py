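"""Repeat / MIPT / gene homology scanning against brute-force and blastn oracles."""

import shutil
import subprocess

import numpy as np
import pytest

import mitostruct as ms
from mitostruct.homology import extract_locus, find_mipts, find_repeats, locate_genes
from mitostruct.seqs import write_fasta


def brute_force_best_gapless(a: str, b: str, min_len: int, min_identity: float):
    """Exhaustive diagonal scan: does any gapless window of length >= min_len
    at identity >= min_identity exist between a and b (forward strands)?

    Checks every diagonal with a sliding min_len window over the match
    indicator; exact for the gapless alignment class.
    """
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    need = int(np.ceil(min_identity * min_len))
    for d in range(-(len(y) - min_len), len(x) - min_len + 1):
        xs = max(0, d)
        ys = xs - d
        n = min(len(x) - xs, len(y) - ys)
        if n < min_len:
            continue
        eq = (x[xs : xs + n] == y[ys : ys + n]).astype(np.int32)
        window = np.convolve(eq, np.ones(min_len, dtype=np.int32), mode="valid")
        if (window >= need).any():
            return True
    return False


def _reciprocal_overlap(iv1, iv2):
    s1, e1 = iv1
    s2, e2 = iv2
    inter = max(0, min(e1, e2) - max(s1, s2) + 1)
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


class TestFindRepeats:
    def test_planted_exact_483bp_duplicate(self):
        spec = ms.GenomeSpec(
            length=50000, seed=31, planted_repeats=[ms.PlantedRepeat(483, 1.0, 5000, 30000)]
        )
        genome, _ = ms.generate_genome(spec)
        hits = find_repeats(genome)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert abs(h.query_start - 5000) <= 5 and abs(h.query_end - 5482) <= 5
        assert abs(h.subject_start - 30000) <= 5

    @pytest.mark.parametrize("length,expect_hit", [(99, False), (100, True)])
    def test_min_length_boundary(self, length, expect_hit):
        spec = ms.GenomeSpec(
            length=30000,
            seed=32,
            planted_repeats=[ms.PlantedRepeat(length, 1.0, 4000, 20000)],
        )
        genome, _ = ms.generate_genome(spec)
        seq = list(genome.seq)
        # pin flanks of the two copies to differ so a chance flank match
        # cannot stretch a 99 bp plant to 100
        seq[3998], seq[3999 + length] = "A", "A"
        seq[19998], seq[19999 + length] = "C", "C"
        genome = ms.GenomeSequence("g", "".join(seq))
        assert bool(find_repeats(genome)) == expect_hit

    def test_inverted_repeat_reported_with_minus_strand(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=30000, seed=33))
        seq = list(genome.seq)
        seq[20000:20300] = ms.revcomp(genome.seq[4000:4300])
        genome = ms.GenomeSequence("g", "".join(seq))
        hits = find_repeats(genome)
        inv = [h for h in hits if h.subject_strand == "-"]
        assert len(inv) == 1
        # chance matches in the random flank can stretch a hit a few bases
        assert abs(inv[0].query_start - 4001) <= 10
        assert abs(inv[0].subject_start - 20001) <= 10
        assert inv[0].length >= 300

    def test_random_genome_has_no_hits_brute_force_confirms(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=12000, seed=34))
        assert find_repeats(genome) == []
        # exhaustive oracle agrees on a subsample of the same sequence
        assert not brute_force_best_gapless(genome.seq[:4000], genome.seq[4000:8000], 100, 0.90)

    def test_mutated_repeat_above_identity_floor_recovered(self):
        spec = ms.GenomeSpec(
            length=40000, seed=35, planted_repeats=[ms.PlantedRepeat(400, 0.95, 6000, 25000)]
        )
        genome, _ = ms.generate_genome(spec)
        hits = find_repeats(genome)
        assert len(hits) == 1
        assert hits[0].identity > 0.90
        assert abs(hits[0].length - 400) <= 5


@pytest.fixture(scope="module")
def planted():
    plastome = ms.generate_plastome(length=20000, seed=36)
    spec = ms.GenomeSpec(
        length=50000,
        seed=37,
        planted_mipts=[
            ms.PlantedMipt(1001, 2700, 10000, 0.85),  # 1.7 kb analog
            ms.PlantedMipt(5001, 6300, 30000, 0.92),  # 1.3 kb analog
        ],
    )
    genome, truth = ms.generate_genome(spec, plastome)
    return genome, plastome, truth


class TestFindMipts:
    def test_planted_mipts_recovered(self, planted):
        """Both planted MIPTs come back as single hits over the planted
        intervals; mutations falling on the plant's edge bases may shave a
        few bases off the reported boundary."""
        genome, plastome, truth = planted
        hits = find_mipts(genome, plastome)
        assert len(hits) == 2
        hits.sort(key=lambda h: h.query_start)
        assert hits[0].length >= 1600
        assert abs(hits[0].query_start - 10000) <= 15
        assert abs(hits[0].query_end - 11699) <= 15
        assert hits[0].identity == pytest.approx(0.85, abs=0.01)
        assert hits[1].length >= 1250

    def test_below_identity_floor_not_reported(self):
        plastome = ms.generate_plastome(length=20000, seed=38)
        spec = ms.GenomeSpec(
            length=30000, seed=39, planted_mipts=[ms.PlantedMipt(1001, 2000, 9000, 0.75)]
        )
        genome, _ = ms.generate_genome(spec, plastome)
        assert find_mipts(genome, plastome) == []

    def test_unrelated_sequences_no_hits_oracle_confirms(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=20000, seed=40))
        plastome = ms.generate_plastome(length=5000, seed=41)
        assert find_mipts(genome, plastome) == []
        assert not brute_force_best_gapless(genome.seq[:5000], plastome.seq, 100, 0.80)

    def test_blastn_oracle_reciprocal_overlap(self, planted, tmp_path):
        """Hits agree with blastn (the field-standard local aligner) at the
        same thresholds with >= 95% reciprocal interval overlap."""
        assert shutil.which("blastn"), "blastn expected on PATH"
        genome, plastome, _ = planted
        write_fasta(tmp_path / "g.fasta", [genome])
        write_fasta(tmp_path / "p.fasta", [plastome])
        out = subprocess.run(
            [
                "blastn",
                "-query", str(tmp_path / "g.fasta"),
                "-subject", str(tmp_path / "p.fasta"),
                "-outfmt", "6 qstart qend length pident",
                "-dust", "no",
                "-perc_identity", "80",
                "-evalue", "1e-10",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
        blast_hits = [
            (int(q1), int(q2))
            for q1, q2, length, pid in (l.split("\t") for l in out.stdout.splitlines())
            if int(length) >= 100
        ]
        ours = [(h.query_start, h.query_end) for h in find_mipts(genome, plastome)]
        assert len(blast_hits) == len(ours)
        for b in blast_hits:
            assert max(_reciprocal_overlap(b, o) for o in ours) >= 0.95


class TestLocateGenes:
    def test_verbatim_gene_found_with_full_identity(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=30000, seed=45))
        gene = genome.seq[7000:7900]
        host, _ = ms.generate_genome(ms.GenomeSpec(length=30000, seed=46))
        seq = list(host.seq)
        seq[12000:12900] = gene
        host = ms.GenomeSequence("h", "".join(seq))
        loci = locate_genes(host, {"cox1": gene})
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.strand) == (12001, 12900, "+")
        assert l.identity == 1.0 and l.reference_coverage == 1.0
        assert extract_locus(host, l) == gene

    def test_minus_strand_gene_extraction_reverse_complements(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=30000, seed=47))
        gene = genome.seq[2000:2800]
        host, _ = ms.generate_genome(ms.GenomeSpec(length=30000, seed=48))
        seq = list(host.seq)
        seq[15000:15800] = ms.revcomp(gene)
        host = ms.GenomeSequence("h", "".join(seq))
        loci = locate_genes(host, {"rrn18": gene})
        assert len(loci) == 1
        assert loci[0].strand == "-"
        assert extract_locus(host, loci[0]) == gene

    def test_best_of_two_paralogous_copies_chosen(self):
        donor, _ = ms.generate_genome(ms.GenomeSpec(length=10000, seed=49))
        gene = donor.seq[1000:1800]
        host, _ = ms.generate_genome(ms.GenomeSpec(length=40000, seed=50))
        rng = np.random.default_rng(51)

        def degrade(s, identity):
            arr = list(s)
            for i in rng.choice(len(arr), size=int(round((1 - identity) * len(arr))), replace=False):
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            return "".join(arr)

        seq = list(host.seq)
        seq[5000:5800] = degrade(gene, 0.95)
        seq[25000:25800] = degrade(gene, 0.85)
        host = ms.GenomeSequence("h", "".join(seq))
        loci = locate_genes(host, {"atp1": gene})
        assert len(loci) == 1
        assert 5001 - 5 <= loci[0].start <= 5001 + 5  # the 95% copy wins

    def test_absent_gene_omitted(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=20000, seed=52))
        other, _ = ms.generate_genome(ms.GenomeSpec(length=5000, seed=53))
        loci = locate_genes(genome, {"ghost": other.seq[:800]})
        assert loci == []

    def test_empty_reference_set_rejected(self):
        genome, _ = ms.generate_genome(ms.GenomeSpec(length=20000, seed=54))
        with pytest.raises(ValueError):
            locate_genes(genome, {})
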