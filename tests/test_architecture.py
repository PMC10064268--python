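import numpy as np
import pytest

from replitax import architecture as arch
from replitax.architecture import RepliconMetrics
from replitax.data import reference_replicons
from replitax.model import GenomeAssembly, Replicon, ValidationError


def _random_seq(n, rng, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _signature_oracle(seq):
    """Independent brute-force signature: plain dict counting on the
    sequence and its reverse complement, linearly per strand."""
    mono = {b: 0 for b in "ACGT"}
    di = {x + y: 0 for x in "ACGT" for y in "ACGT"}
    for strand in (seq, _revcomp(seq)):
        for ch in strand:
            if ch in mono:
                mono[ch] += 1
        for i in range(len(strand) - 1):
            pair = strand[i : i + 2]
            if pair in di:
                di[pair] += 1
    tot1 = sum(mono.values())
    tot2 = sum(di.values())
    f1 = {b: c / tot1 for b, c in mono.items()}
    f2 = {d: c / tot2 for d, c in di.items()}
    return np.array(
        [f2[x + y] / (f1[x] * f1[y]) for x in "ACGT" for y in "ACGT"]
    )


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0), ("ACGTN", 50.0)],
    )
    def test_values(self, seq, expected):
        assert arch.gc_content(seq) == pytest.approx(expected)

    def test_all_n_rejected(self):
        with pytest.raises(ValidationError):
            arch.gc_content("NNNN")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            arch.gc_content("")


class TestSignature:
    def test_matches_brute_force_oracle(self, rng):
        seq = _random_seq(2000, rng, p=(0.3, 0.2, 0.2, 0.3))
        sig = arch.dinucleotide_signature(seq)
        assert np.allclose(sig.rho, _signature_oracle(seq), atol=1e-12)

    def test_strand_symmetry_exact(self, rng):
        seq = _random_seq(10_000, rng)
        s1 = arch.dinucleotide_signature(seq)
        s2 = arch.dinucleotide_signature(_revcomp(seq))
        assert np.array_equal(s1.rho, s2.rho)

    def test_homopolymer_rejected(self):
        # symmetrization adds T, but C and G stay absent
        with pytest.raises(ValidationError, match="C"):
            arch.dinucleotide_signature("A" * 100)

    def test_uniform_iid_near_one(self, rng):
        seq = _random_seq(1_000_000, rng)
        sig = arch.dinucleotide_signature(seq)
        assert np.all(np.abs(sig.rho - 1.0) < 0.01)

    def test_n_excluded(self, rng):
        seq = _random_seq(5000, rng)
        with_n = seq[:2500] + "N" * 10 + seq[2500:]
        a = arch.dinucleotide_signature(seq)
        b = arch.dinucleotide_signature(with_n)
        # the N block only severs one dinucleotide: signatures nearly equal
        assert np.abs(a.rho - b.rho).max() < 0.01


class TestDRADistance:
    def test_self_zero(self, rng):
        sig = arch.dinucleotide_signature(_random_seq(5000, rng))
        assert arch.dra_distance(sig, sig) == 0.0

    def test_revcomp_zero(self, rng):
        seq = _random_seq(8000, rng)
        s1 = arch.dinucleotide_signature(seq)
        s2 = arch.dinucleotide_signature(_revcomp(seq))
        assert arch.dra_distance(s1, s2) == 0.0

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(10):
            sigs = [
                arch.dinucleotide_signature(
                    _random_seq(3000, rng, p=tuple(p))
                )
                for p in rng.dirichlet(np.ones(4) * 20, size=3)
            ]
            a, b, c = sigs
            dab = arch.dra_distance(a, b)
            dba = arch.dra_distance(b, a)
            dac = arch.dra_distance(a, c)
            dbc = arch.dra_distance(b, c)
            assert dab >= 0
            assert dab == pytest.approx(dba)
            assert dac <= dab + dbc + 1e-12


def _metrics(rows):
    return [
        RepliconMetrics(replicon_id=r[0], length=r[1], gc=r[2], dra_to_chromosome=r[3])
        for r in rows
    ]


class TestClassification:
    def test_published_1078_gc_screen(self):
        """Printed GC inventory of strain 1078 with DRA set synthetic-pass:
        exactly the three published chromids pass both criteria."""
        inv = reference_replicons()
        grp = inv[inv.strain == "1078"]
        rows = [
            (r.replicon, r.size_bp, r.gc_percent, 0.0)
            for r in grp.itertuples(index=False)
        ]
        out = arch.classify_replicons(_metrics(rows))
        calls = {m.replicon_id: m.classification for m in out}
        assert calls["Chromosome"] == "chromosome"
        chromids = [k for k, v in calls.items() if v == "putative_chromid"]
        assert sorted(chromids) == [
            "Putative chromid 1",
            "Putative chromid 2",
            "Putative chromid 3",
        ]

    def test_cointegrant_is_ambiguous(self):
        """GC 58.41 vs 60.92 fails the 1-point bound while DRA 0.29 passes
        0.4: exactly one criterion -> flagged for further analysis."""
        out = arch.classify_replicons(
            _metrics(
                [
                    ("chrom", 3_709_686, 60.92, 0.0),
                    ("coint", 1_530_638, 58.41, 0.29),
                ]
            )
        )
        assert out[1].classification == "ambiguous"

    def test_single_replicon(self):
        out = arch.classify_replicons(_metrics([("only", 1000, 55.0, None)]))
        assert out[0].classification == "chromosome"

    def test_boundary_inclusive(self):
        out = arch.classify_replicons(
            _metrics([("c", 100, 60.0, 0.0), ("x", 50, 61.0, 0.4)])
        )
        assert out[1].classification == "putative_chromid"

    def test_neither_criterion_is_megaplasmid(self):
        out = arch.classify_replicons(
            _metrics([("c", 100, 60.0, 0.0), ("x", 50, 55.0, 3.0)])
        )
        assert out[1].classification == "megaplasmid"

    def test_order_invariance(self):
        rows = [
            ("c", 100, 60.0, 0.0),
            ("x", 50, 60.5, 0.2),
            ("y", 40, 55.0, 3.0),
        ]
        fwd = arch.classify_replicons(_metrics(rows))
        rev = arch.classify_replicons(_metrics(rows[::-1]))
        assert {m.replicon_id: m.classification for m in fwd} == {
            m.replicon_id: m.classification for m in rev
        }

    def test_largest_tie_broken_by_id(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="replitax"):
            out = arch.classify_replicons(
                _metrics([("b", 100, 60.0, 0.1), ("a", 100, 60.0, 0.1)])
            )
        calls = {m.replicon_id: m.classification for m in out}
        assert calls["a"] == "chromosome"
        assert "tie" in caplog.text

    def test_metrics_and_classify_on_assembly(self, rng):
        chrom = _random_seq(20_000, rng, p=(0.2, 0.3, 0.3, 0.2))
        plasmid = _random_seq(3_000, rng, p=(0.35, 0.15, 0.15, 0.35))
        asm = GenomeAssembly(
            strain="s",
            replicons=[
                Replicon(id="chr", sequence=chrom),
                Replicon(id="p", sequence=plasmid),
            ],
        )
        out = arch.classify_assembly(asm)
        assert out[0].classification == "chromosome"
        assert out[1].classification == "megaplasmid"  # GC ~30 vs ~60


class TestGCSkew:
    def test_single_peak_shape(self):
        seq = "G" * 1000 + "C" * 1000
        mid, prof = arch.cumulative_gc_skew(seq, 100)
        assert len(prof) == 20
        peak = int(np.argmax(prof))
        assert np.all(np.diff(prof[: peak + 1]) > 0)
        assert np.all(np.diff(prof[peak:]) < 0)

    def test_revcomp_is_reversed_negated(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(5000, rng)
        _, p1 = arch.cumulative_gc_skew(seq, 100)
        _, p2 = arch.cumulative_gc_skew(_revcomp(seq), 100)
        # reversed-negated cumulative profile, up to the running offset:
        # per-window skews of the revcomp are the reversed negated skews
        s1 = np.diff(np.r_[0.0, p1])
        s2 = np.diff(np.r_[0.0, p2])
        assert np.allclose(s2, -s1[::-1], atol=1e-12)

    def test_shuffled_flat_relative_to_structured(self):
        rng = np.random.default_rng(6)
        structured = "G" * 5000 + "C" * 5000
        shuffled = "".join(
            rng.permutation(list(structured))
        )
        _, ps = arch.cumulative_gc_skew(structured, 200)
        _, pf = arch.cumulative_gc_skew(shuffled, 200)
        assert np.abs(pf).max() < 0.3 * np.abs(ps).max()

    def test_window_validation(self):
        with pytest.raises(ValidationError):
            arch.cumulative_gc_skew("ACGT" * 10, 30)

    def test_zero_gc_window_contributes_zero(self):
        seq = "AT" * 200 + "G" * 400
        _, prof = arch.cumulative_gc_skew(seq, 80)
        assert prof[0] == 0.0


class TestOriginInference:
    def test_single_v(self):
        seq = "G" * 3000 + "C" * 3000
        _, prof = arch.cumulative_gc_skew(seq, 100)
        assert arch.infer_origin_count(prof) == "single"

    def test_double_v(self):
        seq = ("G" * 1500 + "C" * 1500) * 2
        _, prof = arch.cumulative_gc_skew(seq, 100)
        assert arch.infer_origin_count(prof) == "multiple"

    def test_flat_noise(self):
        rng = np.random.default_rng(11)
        hits = [
            arch.infer_origin_count(
                arch.cumulative_gc_skew(_random_seq(6000, rng), 100)[1]
            )
            for _ in range(10)
        ]
        assert hits.count("indeterminate") >= 8

    def test_short_profile_rejected(self):
        with pytest.raises(ValidationError):
            arch.infer_origin_count(np.zeros(5))


class TestSignatureProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        seq=st.text(alphabet="ACGT", min_size=30, max_size=300).filter(
            lambda s: len(set(s)) == 4
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_self_distance(self, seq):
        sig = arch.dinucleotide_signature(seq)
        rc = _revcomp(seq)
        assert np.array_equal(sig.rho, arch.dinucleotide_signature(rc).rho)
        assert arch.dra_distance(sig, sig) == 0.0

    @given(seq=st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=40, deadline=None)
    def test_gc_bounds(self, seq):
        if set(seq) <= {"N"}:
            with pytest.raises(ValidationError):
                arch.gc_content(seq)
        else:
            assert 0.0 <= arch.gc_content(seq) <= 100.0
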