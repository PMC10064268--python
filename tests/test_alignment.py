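import numpy as np
import pytest

from replitax import alignment as aln
from replitax import synthetic as syn
from replitax.model import GeneRecord, ValidationError


def _random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignLocal:
    def test_self_alignment(self):
        hit = aln.align_local("MKVLITAGHA", "MKVLITAGHA")
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0
        assert hit.subject_coverage == 1.0

    def test_single_substitution_dna(self):
        seq = "ACGT" * 25
        mut = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        hit = aln.align_local(seq, mut, molecule="dna")
        assert hit.identity == pytest.approx(0.99)
        assert hit.n_columns == 100

    def test_alphabet_violation(self):
        with pytest.raises(ValidationError):
            aln.align_local("ACGU", "ACGT", molecule="dna")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aln.align_local("", "ACGT", molecule="dna")

    def test_unrelated_seeded_returns_none(self, rng):
        a = _random_dna(400, rng)
        b = _random_dna(400, rng)
        assert aln.align_local(a, b, molecule="dna", max_exact_len=0) is None


class TestSeededEqualsExhaustive:
    """Oracle suite: the seeded banded route must reproduce the full-DP
    Smith-Waterman hit on homologous pairs up to 2 kb."""

    @pytest.mark.parametrize("rate", [0.0, 0.03, 0.08])
    def test_embedded_mutant_pairs(self, rate, rng):
        for trial in range(8):
            n = int(rng.integers(300, 1200))
            core = _random_dna(n, rng)
            mut = syn.mutate_sequence(
                core, syn.StrainPairSpec(rate, seed=int(rng.integers(1 << 30)))
            )
            subject = _random_dna(300, rng) + mut + _random_dna(300, rng)
            full = aln.align_local(
                core, subject, molecule="dna", max_exact_len=10**6
            )
            seeded = aln.align_local(
                core, subject, molecule="dna", max_exact_len=0
            )
            assert seeded is not None
            assert seeded.score == full.score
            assert seeded.query_span == full.query_span
            assert seeded.subject_span == full.subject_span
            assert seeded.n_identical == full.n_identical

    def test_with_indels(self, rng):
        for _ in range(5):
            core = _random_dna(800, rng)
            mut = syn.mutate_sequence(
                core,
                syn.StrainPairSpec(
                    0.02, indel_rate=0.01, seed=int(rng.integers(1 << 30))
                ),
            )
            subject = _random_dna(200, rng) + mut + _random_dna(200, rng)
            full = aln.align_local(core, subject, molecule="dna",
                                   max_exact_len=10**6)
            seeded = aln.align_local(core, subject, molecule="dna",
                                     max_exact_len=0)
            assert seeded.score == full.score


class TestBBH:
    def test_identical_proteomes_identity_mapping(self, rng):
        prots = {
            f"g{i}": syn.random_protein(250, rng) for i in range(12)
        }
        pairs = aln.bidirectional_best_hits(prots, dict(prots))
        assert len(pairs) == len(prots)
        assert all(p.gene_a == p.gene_b for p in pairs)

    def test_a_only_gene_absent(self, rng):
        shared = {f"g{i}": syn.random_protein(250, rng) for i in range(5)}
        a = dict(shared)
        a["orphan"] = syn.random_protein(250, rng)
        pairs = aln.bidirectional_best_hits(a, shared)
        assert "orphan" not in {p.gene_a for p in pairs}
        assert len(pairs) == 5

    def test_100_gene_orthologs_recovered(self):
        a, b, truth = syn.simulate_strain_pair(
            {"c1": 100}, seed=17, aa_divergence=0.05
        )
        pairs = aln.bidirectional_best_hits(a.proteins_by_id, b.proteins_by_id)
        assert len(pairs) == 100
        assert all(truth.gene_partner[p.gene_a] == p.gene_b for p in pairs)

    def test_symmetry(self, rng):
        a, b, _ = syn.simulate_strain_pair({"c1": 15}, seed=4)
        fwd = aln.bidirectional_best_hits(a.proteins_by_id, b.proteins_by_id)
        rev = aln.bidirectional_best_hits(b.proteins_by_id, a.proteins_by_id)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {
            (p.gene_b, p.gene_a) for p in rev
        }

    def test_gates_monotone(self):
        a, b, _ = syn.simulate_strain_pair({"c1": 20}, seed=5, aa_divergence=0.1)
        pa, pb = a.proteins_by_id, b.proteins_by_id
        loose = aln.bidirectional_best_hits(pa, pb, evalue_max=1e-20,
                                            min_coverage=0.3)
        tight_cov = aln.bidirectional_best_hits(pa, pb, evalue_max=1e-20,
                                                min_coverage=0.9)
        tight_e = aln.bidirectional_best_hits(pa, pb, evalue_max=1e-200,
                                              min_coverage=0.3)
        loose_set = {(p.gene_a, p.gene_b) for p in loose}
        assert {(p.gene_a, p.gene_b) for p in tight_cov} <= loose_set
        assert {(p.gene_a, p.gene_b) for p in tight_e} <= loose_set

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValidationError):
            aln.bidirectional_best_hits({}, {"g": "MKV"})


class TestSyntenyLinks:
    def test_empty_bbh_header_only(self, tmp_path):
        links = aln.synteny_links([], {}, {})
        out = tmp_path / "links.tsv"
        aln.write_links(links, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_toy_links_match_gene_table(self, tmp_path):
        a, b, truth = syn.simulate_strain_pair({"c1": 10}, seed=6)
        pairs = aln.bidirectional_best_hits(a.proteins_by_id, b.proteins_by_id)
        ga = {g.gene_id: g for g in a.genes}
        gb = {g.gene_id: g for g in b.genes}
        links = aln.synteny_links(pairs, ga, gb)
        assert len(links) == 10
        row = links.iloc[0]
        g = ga[pairs[0].gene_a]
        assert (row.replicon_a, row.start_a, row.end_a) == (
            g.replicon_id, g.start, g.end
        )
        aln.write_links(links, tmp_path / "links.tsv")
        assert len((tmp_path / "links.tsv").read_text().splitlines()) == 11

    def test_missing_coordinates_listed(self):
        a, b, _ = syn.simulate_strain_pair({"c1": 3}, seed=7)
        pairs = aln.bidirectional_best_hits(a.proteins_by_id, b.proteins_by_id)
        with pytest.raises(ValidationError, match=pairs[0].gene_a):
            aln.synteny_links(pairs, {}, {g.gene_id: g for g in b.genes})

    def test_translocated_links_cross_replicons(self):
        a, b, truth = syn.simulate_strain_pair({"c1": 25, "c2": 15}, seed=8)
        moved = [
            truth.gene_partner[g.gene_id] for g in a.genes_on("c1")[5:15]
        ]
        b2 = syn.translocate_block(b, moved, "c2_b")
        pairs = aln.bidirectional_best_hits(a.proteins_by_id, b2.proteins_by_id)
        links = aln.synteny_links(
            pairs,
            {g.gene_id: g for g in a.genes},
            {g.gene_id: g for g in b2.genes},
        )
        crossing = links[
            (links.replicon_a == "c1") & (links.replicon_b == "c2_b")
        ]
        assert len(crossing) == 10


class TestCointegrationMap:
    def test_three_source_segments(self):
        a, b, truth = syn.simulate_strain_pair(
            {"r1": 30, "r2": 25, "r3": 20}, seed=9
        )
        b2, co_truth = syn.cointegrate_assembly(
            b, ["r1_b", "r2_b", "r3_b"], seed=10
        )
        pairs = aln.bidirectional_best_hits(b2.proteins_by_id, a.proteins_by_id)
        cmap = aln.cointegration_map(
            "cointegrant",
            b2.genes,
            {g.gene_id: g for g in a.genes},
            pairs,
        )
        assert set(cmap.counts) == {"r1", "r2", "r3"}
        assert len(cmap.segments) == 3
        # gene-level source recovery via the lifted coordinates
        partner = {p.gene_a: p.gene_b for p in pairs}
        ref_rep = {g.gene_id: g.replicon_id for g in a.genes}
        n_ok = sum(
            1
            for src, genes in cmap.segments
            for gid in genes
            if ref_rep[partner[gid]] == src
        )
        assert n_ok / len(b2.genes) >= 0.95

    def test_single_source(self):
        a, b, _ = syn.simulate_strain_pair({"r1": 30}, seed=11)
        pairs = aln.bidirectional_best_hits(b.proteins_by_id, a.proteins_by_id)
        cmap = aln.cointegration_map(
            "r1_b", b.genes, {g.gene_id: g for g in a.genes}, pairs
        )
        assert len(cmap.segments) == 1
        assert cmap.fractions["r1"] == 1.0
        assert len(cmap.segments[0][1]) >= 0.9 * 30

    def test_no_shared_genes_empty(self, rng):
        genes = [GeneRecord("g1", "t", 1, 900, "+")]
        cmap = aln.cointegration_map("t", genes, {}, [])
        assert cmap.counts == {} and cmap.segments == []


class TestTranslocatedBlocks:
    def _setup(self, seed, blocks):
        a, b, truth = syn.simulate_strain_pair(
            {"c1": 60, "c2": 50, "c3": 40}, seed=seed
        )
        b2 = b
        expected_sizes = []
        for src, dest, lo, size in blocks:
            moved = [
                truth.gene_partner[g.gene_id]
                for g in a.genes_on(src)[lo : lo + size]
            ]
            b2 = syn.translocate_block(b2, moved, dest)
            expected_sizes.append(size)
        pairs = aln.bidirectional_best_hits(a.proteins_by_id, b2.proteins_by_id)
        found = aln.detect_translocated_blocks(
            pairs,
            {g.gene_id: g for g in a.genes},
            {g.gene_id: g for g in b2.genes},
            truth.expected_partners,
        )
        return found

    def test_no_translocation_empty(self):
        assert self._setup(21, []) == []

    def test_41_and_25_gene_blocks(self):
        found = self._setup(22, [("c1", "c2_b", 10, 41), ("c3", "c1_b", 5, 25)])
        sizes = sorted(b.size for b in found)
        assert sizes == [25, 41]
        by_size = {b.size: b for b in found}
        assert by_size[41].replicon_a == "c1"
        assert by_size[41].replicon_b == "c2_b"
        assert by_size[25].replicon_a == "c3"
        assert by_size[25].replicon_b == "c1_b"

    def test_min_run_filters_short_blocks(self):
        found = self._setup(23, [("c1", "c2_b", 10, 5)])
        assert found == []


class TestCountSnps:
    def test_identical(self, rng):
        seq = _random_dna(1500, rng)
        assert aln.count_snps(seq, seq) == 0

    def test_three_substitutions(self, rng):
        seq = _random_dna(1500, rng)
        pos = [200, 700, 1200]
        other = "ACGT"
        mut = list(seq)
        for p in pos:
            mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
        assert aln.count_snps(seq, "".join(mut)) == 3

    def test_snps_with_indel(self, rng):
        seq = _random_dna(1000, rng)
        mut = list(seq)
        mut[300] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[300]]
        del mut[600:603]  # gap columns must not count as SNPs
        assert aln.count_snps(seq, "".join(mut)) == 1

    def test_unrelated_rejected(self, rng):
        with pytest.raises(ValidationError, match="identity"):
            aln.count_snps(_random_dna(800, rng), _random_dna(800, rng))
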