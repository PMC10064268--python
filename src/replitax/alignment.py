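"""Pairwise alignment engine, BBH orthology, synteny links, and
cointegration / translocation mapping.

Two alignment routes share one scoring scheme per molecule type:

* exhaustive Smith-Waterman (Biopython ``PairwiseAligner``) for sequence
  pairs up to ``max_exact_len``;
* a k-mer seeded, banded Smith-Waterman (numba) above that, used for
  fragment-vs-genome searches. The seeded route is checked against the
  exhaustive route in the test suite.

E-values follow Karlin-Altschul statistics with tabulated gapped constants
(BLOSUM62 open 11 / extend 1: lambda 0.267, K 0.041; DNA +1/-2 open 5 /
extend 2: lambda 1.28, K 0.46) and an effective search space of
``m * n * n_subject_sequences``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .model import GeneRecord, ValidationError

__all__ = [
    "AlignmentHit",
    "BBHPair",
    "align_local",
    "align_global",
    "SeedIndex",
    "bidirectional_best_hits",
    "synteny_links",
    "write_links",
    "cointegration_map",
    "CointegrationMap",
    "detect_translocated_blocks",
    "TranslocatedBlock",
    "count_snps",
]

_DNA_PARAMS = {"lambda": 1.28, "K": 0.46}
_PROT_PARAMS = {"lambda": 0.267, "K": 0.041}

_DNA_SET = frozenset("ACGTN")
_PROT_SET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ*")


def _check_alphabet(seq: str, molecule: str) -> None:
    allowed = _DNA_SET if molecule == "dna" else _PROT_SET
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValidationError(f"invalid {molecule} characters {sorted(bad)}")


@lru_cache(maxsize=8)
def _aligner(molecule: str, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if molecule == "protein":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -12.0  # gap of length k costs 11 + k
        al.extend_gap_score = -1.0
    else:
        al.match_score = 1.0
        al.mismatch_score = -2.0
        al.open_gap_score = -7.0  # gap of length k costs 5 + 2k
        al.extend_gap_score = -2.0
    return al


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float  # identical columns / aligned columns (incl. internal gaps)
    query_coverage: float
    subject_coverage: float
    score: float  # raw score
    bits: float
    evalue: float
    n_identical: int = 0
    n_columns: int = 0
    query_span: tuple[int, int] = (0, 0)  # 0-based half-open
    subject_span: tuple[int, int] = (0, 0)


def _ka_stats(
    score: float, m: int, n: int, n_subjects: int, molecule: str
) -> tuple[float, float]:
    p = _DNA_PARAMS if molecule == "dna" else _PROT_PARAMS
    bits = (p["lambda"] * score - math.log(p["K"])) / math.log(2.0)
    search_space = float(m) * float(n) * max(n_subjects, 1)
    log_e = math.log(search_space) - bits * math.log(2.0)
    evalue = math.exp(log_e) if log_e < 700 else math.inf
    return bits, evalue


def _hit_from_alignment(
    aln,
    a: str,
    b: str,
    molecule: str,
    query_id: str,
    subject_id: str,
    n_subjects: int,
    subject_offset: int = 0,
    full_subject_len: int | None = None,
) -> AlignmentHit | None:
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return None
    n_ident = 0
    aligned_res = 0
    for (qa, qb), (sa, sb) in zip(blocks_a, blocks_b):
        seg_a = a[qa:qb]
        seg_b = b[sa:sb]
        n_ident += sum(x == y for x, y in zip(seg_a, seg_b))
        aligned_res += qb - qa
    q_lo, q_hi = int(blocks_a[0][0]), int(blocks_a[-1][1])
    s_lo, s_hi = int(blocks_b[0][0]), int(blocks_b[-1][1])
    # columns = aligned residue pairs + internal gap columns
    gap_cols = (q_hi - q_lo - aligned_res) + (s_hi - s_lo - aligned_res)
    n_cols = aligned_res + gap_cols
    n_sub = full_subject_len if full_subject_len is not None else len(b)
    bits, evalue = _ka_stats(aln.score, len(a), n_sub, n_subjects, molecule)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=n_ident / n_cols if n_cols else 0.0,
        query_coverage=(q_hi - q_lo) / len(a),
        subject_coverage=(s_hi - s_lo) / n_sub,
        score=float(aln.score),
        bits=bits,
        evalue=evalue,
        n_identical=n_ident,
        n_columns=n_cols,
        query_span=(q_lo, q_hi),
        subject_span=(s_lo + subject_offset, s_hi + subject_offset),
    )


# ---------------------------------------------------------------------------
# Seeded banded route (DNA)

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i


def _nt_codes(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=1)
def _banded_kernel():
    from numba import njit

    @njit(cache=False)
    def kernel(q, s, band_lo, band_hi, match, mismatch, gap_open, gap_ext):
        n = q.shape[0]
        m = s.shape[0]
        W = band_hi - band_lo + 1
        NEG = -(10**9)
        H = np.full((n + 1, W), NEG, dtype=np.int64)
        E = np.full((n + 1, W), NEG, dtype=np.int64)
        F = np.full((n + 1, W), NEG, dtype=np.int64)
        tH = np.zeros((n + 1, W), dtype=np.uint8)  # 0 stop 1 diag 2 E 3 F
        tE = np.zeros((n + 1, W), dtype=np.uint8)  # 1 open 0 extend
        tF = np.zeros((n + 1, W), dtype=np.uint8)
        for k in range(W):
            j = 0 + band_lo + k
            if 0 <= j <= m:
                H[0, k] = 0
        best = 0
        bi = -1
        bk = -1
        for i in range(1, n + 1):
            for k in range(W):
                j = i + band_lo + k
                if j < 1 or j > m:
                    if 0 <= j <= m:
                        H[i, k] = 0
                    continue
                qc = q[i - 1]
                sc = s[j - 1]
                if qc < 4 and qc == sc:
                    sub = match
                else:
                    sub = mismatch
                diag = H[i - 1, k]
                dscore = diag + sub if diag > NEG else NEG
                e = NEG
                te = 0
                if k - 1 >= 0:
                    ho = H[i, k - 1]
                    ee = E[i, k - 1]
                    if ho > NEG and ho + gap_open >= ee + gap_ext:
                        e = ho + gap_open
                        te = 1
                    elif ee > NEG:
                        e = ee + gap_ext
                        te = 0
                f = NEG
                tf = 0
                if k + 1 < W:
                    ho = H[i - 1, k + 1]
                    ff = F[i - 1, k + 1]
                    if ho > NEG and ho + gap_open >= ff + gap_ext:
                        f = ho + gap_open
                        tf = 1
                    elif ff > NEG:
                        f = ff + gap_ext
                        tf = 0
                E[i, k] = e
                tE[i, k] = te
                F[i, k] = f
                tF[i, k] = tf
                h = 0
                th = 0
                if dscore > h:
                    h = dscore
                    th = 1
                if e > h:
                    h = e
                    th = 2
                if f > h:
                    h = f
                    th = 3
                H[i, k] = h
                tH[i, k] = th
                if h > best:
                    best = h
                    bi = i
                    bk = k
        # traceback
        n_ident = 0
        n_cols = 0
        aligned_res = 0
        if bi < 0:
            return best, 0, 0, 0, 0, 0, 0
        i = bi
        k = bk
        q_hi = bi
        s_hi = bi + band_lo + bk
        state = 0  # 0 = H, 1 = E, 2 = F
        while True:
            if state == 0:
                th = tH[i, k]
                if th == 0:
                    break
                if th == 1:
                    j = i + band_lo + k
                    if q[i - 1] < 4 and q[i - 1] == s[j - 1]:
                        n_ident += 1
                    n_cols += 1
                    aligned_res += 1
                    i -= 1
                elif th == 2:
                    state = 1
                else:
                    state = 2
            elif state == 1:  # gap in query, consume subject
                n_cols += 1
                te = tE[i, k]
                k -= 1
                if te == 1:
                    state = 0
            else:  # gap in subject, consume query
                n_cols += 1
                tf = tF[i, k]
                i -= 1
                k += 1
                if tf == 1:
                    state = 0
        q_lo = i
        s_lo = i + band_lo + k
        return best, q_lo, q_hi, s_lo, s_hi, n_ident, n_cols

    return kernel


class SeedIndex:
    """Exact k-mer position index of a subject sequence (DNA)."""

    def __init__(self, sequence: str, k: int = 15, max_occ: int = 64):
        self.sequence = sequence.upper()
        self.k = k
        self.max_occ = max_occ
        index: dict[str, list[int]] = {}
        seq = self.sequence
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            hits = index.setdefault(kmer, [])
            if len(hits) < max_occ:
                hits.append(pos)
        self.index = index

    def seeds(self, query: str, stride: int = 1) -> list[tuple[int, int]]:
        k = self.k
        out = []
        q = query.upper()
        for qpos in range(0, len(q) - k + 1, stride):
            for spos in self.index.get(q[qpos : qpos + k], ()):
                out.append((qpos, spos))
        return out


def _cluster_diagonals(
    seeds: list[tuple[int, int]], max_gap: int = 200
) -> list[tuple[int, int, int]]:
    """Group seeds by diagonal (spos - qpos); returns (lo, hi, n_seeds)."""
    diags = sorted(s - q for q, s in seeds)
    clusters: list[tuple[int, int, int]] = []
    lo = hi = diags[0]
    count = 1
    for d in diags[1:]:
        if d - hi <= max_gap:
            hi = d
            count += 1
        else:
            clusters.append((lo, hi, count))
            lo = hi = d
            count = 1
    clusters.append((lo, hi, count))
    clusters.sort(key=lambda c: -c[2])
    return clusters


def _align_seeded(
    a: str,
    b: str,
    query_id: str,
    subject_id: str,
    n_subjects: int,
    index: SeedIndex | None = None,
    k: int = 15,
    band_pad: int = 48,
    max_clusters: int = 4,
) -> AlignmentHit | None:
    if index is None:
        index = SeedIndex(b, k=k)
    seeds = index.seeds(a)
    if not seeds:
        return None
    kernel = _banded_kernel()
    qc = _nt_codes(a)
    sc = _nt_codes(index.sequence)
    best = None
    for lo, hi, _count in _cluster_diagonals(seeds)[:max_clusters]:
        res = kernel(qc, sc, lo - band_pad, hi + band_pad, 1, -2, -7, -2)
        score, q_lo, q_hi, s_lo, s_hi, n_ident, n_cols = res
        if score <= 0 or n_cols == 0:
            continue
        bits, evalue = _ka_stats(score, len(a), len(b), n_subjects, "dna")
        hit = AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            identity=n_ident / n_cols,
            query_coverage=(q_hi - q_lo) / len(a),
            subject_coverage=(s_hi - s_lo) / len(b),
            score=float(score),
            bits=bits,
            evalue=evalue,
            n_identical=int(n_ident),
            n_columns=int(n_cols),
            query_span=(int(q_lo), int(q_hi)),
            subject_span=(int(s_lo), int(s_hi)),
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def align_local(
    a: str,
    b: str,
    molecule: str = "protein",
    query_id: str = "query",
    subject_id: str = "subject",
    n_subjects: int = 1,
    max_exact_len: int = 50_000,
    seed_index: SeedIndex | None = None,
) -> AlignmentHit | None:
    """Best local alignment of ``a`` (query) against ``b`` (subject).

    Exhaustive Smith-Waterman up to ``max_exact_len``; k-mer seeded banded
    route above that (DNA only). Returns None when no positive-scoring
    alignment (or, on the seeded route, no seed) is found.
    """
    if not a or not b:
        raise ValidationError("empty sequence")
    _check_alphabet(a, molecule)
    _check_alphabet(b, molecule)
    a = a.upper()
    b = b.upper()
    if max(len(a), len(b)) <= max_exact_len and seed_index is None:
        aligner = _aligner(molecule, "local")
        alignments = aligner.align(a, b)
        if alignments.score <= 0:
            return None
        return _hit_from_alignment(
            alignments[0], a, b, molecule, query_id, subject_id, n_subjects
        )
    if molecule != "dna":
        raise ValidationError(
            "seeded alignment route supports DNA only; protein sequences "
            "above the exact-DP limit are not supported"
        )
    return _align_seeded(
        a, b, query_id, subject_id, n_subjects, index=seed_index
    )


def align_global(a: str, b: str, molecule: str = "dna"):
    """Needleman-Wunsch global alignment (Biopython Alignment object)."""
    if not a or not b:
        raise ValidationError("empty sequence")
    _check_alphabet(a, molecule)
    return _aligner(molecule, "global").align(a.upper(), b.upper())[0]


# ---------------------------------------------------------------------------
# BBH orthology

@dataclass
class BBHPair:
    gene_a: str
    gene_b: str
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_hits(
    query: dict[str, str],
    subject: dict[str, str],
    k: int = 5,
) -> dict[str, AlignmentHit]:
    """Best local hit in ``subject`` for every query protein.

    Candidate pairs are limited to proteins sharing at least one k-mer
    (guaranteed for homologs at the divergences of interest); ties on score
    break by higher identity, then lexicographic subject id.
    """
    inverted: dict[str, set[str]] = {}
    for sid, sseq in subject.items():
        for kmer in _kmer_set(sseq, k):
            inverted.setdefault(kmer, set()).add(sid)
    n_subj = len(subject)
    best: dict[str, AlignmentHit] = {}
    for qid in sorted(query):
        qseq = query[qid]
        cands: set[str] = set()
        for kmer in _kmer_set(qseq, k):
            cands |= inverted.get(kmer, set())
        top: AlignmentHit | None = None
        for sid in sorted(cands):
            hit = align_local(
                qseq,
                subject[sid],
                molecule="protein",
                query_id=qid,
                subject_id=sid,
                n_subjects=n_subj,
            )
            if hit is None:
                continue
            # best by score, then identity; exact ties keep the
            # lexicographically smallest subject id (sorted iteration)
            if top is None or (hit.score, hit.identity) > (
                top.score,
                top.identity,
            ):
                top = hit
        if top is not None:
            best[qid] = top
    return best


def bidirectional_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    evalue_max: float = 1e-100,
    min_coverage: float = 0.5,
    min_identity: float = 0.0,
) -> list[BBHPair]:
    """Reciprocal best hits with both gates applied to both directions.

    A pair is kept when gene_b is gene_a's best scoring hit in B and vice
    versa, and both hits satisfy ``evalue <= evalue_max`` and coverage of
    *each* protein >= ``min_coverage`` (plus the optional identity gate).
    """
    if not proteome_a or not proteome_b:
        raise ValidationError("both proteomes must be non-empty")
    ab = _best_hits(proteome_a, proteome_b)
    ba = _best_hits(proteome_b, proteome_a)

    def passes(hit: AlignmentHit) -> bool:
        return (
            hit.evalue <= evalue_max
            and hit.query_coverage >= min_coverage
            and hit.subject_coverage >= min_coverage
            and hit.identity >= min_identity
        )

    pairs = []
    for ga, hit_ab in sorted(ab.items()):
        gb = hit_ab.subject_id
        hit_ba = ba.get(gb)
        if hit_ba is None or hit_ba.subject_id != ga:
            continue
        if passes(hit_ab) and passes(hit_ba):
            pairs.append(BBHPair(gene_a=ga, gene_b=gb, hit_ab=hit_ab, hit_ba=hit_ba))
    return pairs


# ---------------------------------------------------------------------------
# Synteny links

_PALETTE = [
    "red", "blue", "green", "orange", "purple",
    "dgrey", "vdyellow", "teal",
]


def synteny_links(
    bbh: list[BBHPair],
    genes_a: dict[str, GeneRecord],
    genes_b: dict[str, GeneRecord],
) -> pd.DataFrame:
    """One circos-style link per BBH pair, colored by source replicon."""
    missing = sorted(
        {p.gene_a for p in bbh if p.gene_a not in genes_a}
        | {p.gene_b for p in bbh if p.gene_b not in genes_b}
    )
    if missing:
        raise ValidationError(f"genes without coordinates: {missing}")
    replicons_a = sorted({genes_a[p.gene_a].replicon_id for p in bbh})
    color_of = {
        rid: _PALETTE[i % len(_PALETTE)] for i, rid in enumerate(replicons_a)
    }
    rows = []
    for p in bbh:
        ga, gb = genes_a[p.gene_a], genes_b[p.gene_b]
        rows.append(
            {
                "replicon_a": ga.replicon_id,
                "start_a": ga.start,
                "end_a": ga.end,
                "replicon_b": gb.replicon_id,
                "start_b": gb.start,
                "end_b": gb.end,
                "identity": round(p.hit_ab.identity, 4),
                "color": color_of[ga.replicon_id],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicon_a", "start_a", "end_a",
            "replicon_b", "start_b", "end_b", "identity", "color",
        ],
    )


def write_links(links: pd.DataFrame, path) -> None:
    """circos links file: coordinates then ``color=...`` option column."""
    with open(path, "w") as fh:
        fh.write(
            "#replicon_a\tstart_a\tend_a\treplicon_b\tstart_b\tend_b\toptions\n"
        )
        for r in links.itertuples(index=False):
            fh.write(
                f"{r.replicon_a}\t{r.start_a}\t{r.end_a}\t"
                f"{r.replicon_b}\t{r.start_b}\t{r.end_b}\t"
                f"color={r.color},identity={r.identity}\n"
            )


# ---------------------------------------------------------------------------
# Cointegration and translocations

@dataclass
class CointegrationMap:
    target_replicon: str
    counts: dict[str, int]  # reference replicon -> n target genes
    fractions: dict[str, float]
    segments: list[tuple[str, list[str]]] = field(default_factory=list)
    # segments: (source reference replicon, target gene ids in order)


def _runs(
    items: list[tuple[str, str | None]], min_run: int, max_gap: int
) -> list[tuple[str, list[str]]]:
    """Maximal runs of consecutive (gene, source) entries sharing a source.

    ``source=None`` entries (no partner) are tolerated inside a run up to
    ``max_gap`` consecutively and are not counted as members.
    """
    runs: list[tuple[str, list[str]]] = []
    cur_src: str | None = None
    cur: list[str] = []
    gap = 0

    def flush():
        nonlocal cur, cur_src
        if cur_src is not None and len(cur) >= min_run:
            runs.append((cur_src, cur))
        cur, cur_src = [], None

    for gene, src in items:
        if src is None:
            gap += 1
            if gap > max_gap:
                flush()
                gap = 0
            continue
        if src != cur_src:
            flush()
            cur_src = src
        cur.append(gene)
        gap = 0
    flush()
    return runs


def cointegration_map(
    target_replicon: str,
    target_genes: list[GeneRecord],
    reference_genes: dict[str, GeneRecord],
    bbh: list[BBHPair],
    min_run: int = 10,
    max_gap: int = 2,
) -> CointegrationMap:
    """Map a (candidate cointegrant) replicon onto reference replicons.

    ``target_genes`` are the genes of the target strain; BBH pairs are
    (target, reference). Reports, per reference replicon, the count and
    fraction of target genes whose partner lies on it, plus dominant-source
    segments (runs of >= ``min_run`` consecutive target genes sharing one
    source, tolerating up to ``max_gap`` partnerless genes).
    """
    partner = {p.gene_a: p.gene_b for p in bbh}
    ordered = sorted(
        (g for g in target_genes if g.replicon_id == target_replicon),
        key=lambda g: (g.start, g.gene_id),
    )
    items: list[tuple[str, str | None]] = []
    counts: dict[str, int] = {}
    for g in ordered:
        gb = partner.get(g.gene_id)
        src = None
        if gb is not None and gb in reference_genes:
            src = reference_genes[gb].replicon_id
            counts[src] = counts.get(src, 0) + 1
        items.append((g.gene_id, src))
    total = sum(counts.values())
    if total == 0:
        import logging

        logging.getLogger("replitax").warning(
            "cointegration_map: no BBH partners on %r", target_replicon
        )
        return CointegrationMap(target_replicon, {}, {}, [])
    fractions = {k: v / total for k, v in counts.items()}
    segments = _runs(items, min_run=min_run, max_gap=max_gap)
    return CointegrationMap(target_replicon, counts, fractions, segments)


@dataclass
class TranslocatedBlock:
    replicon_a: str
    replicon_b: str
    gene_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def detect_translocated_blocks(
    bbh: list[BBHPair],
    genes_a: dict[str, GeneRecord],
    genes_b: dict[str, GeneRecord],
    expected_partners: dict[str, str],
    min_run: int = 10,
    max_gap: int = 2,
) -> list[TranslocatedBlock]:
    """Runs of consecutive strain-A genes whose partners sit on an
    unexpected strain-B replicon.

    ``expected_partners`` maps each A replicon to its orthologous B
    replicon. Genes without a BBH partner are tolerated inside a run (up to
    ``max_gap`` consecutive); genes matching the expected replicon break it.
    """
    partner = {p.gene_a: p.gene_b for p in bbh}
    blocks: list[TranslocatedBlock] = []
    for rep_a in sorted({g.replicon_id for g in genes_a.values()}):
        expected = expected_partners.get(rep_a)
        ordered = sorted(
            (g for g in genes_a.values() if g.replicon_id == rep_a),
            key=lambda g: (g.start, g.gene_id),
        )
        items: list[tuple[str, str | None]] = []
        for g in ordered:
            gb = partner.get(g.gene_id)
            if gb is None or gb not in genes_b:
                items.append((g.gene_id, None))
                continue
            rep_b = genes_b[gb].replicon_id
            # expected-partner genes break runs: encode as a unique sentinel
            items.append((g.gene_id, rep_b if rep_b != expected else "\0expected"))
        for src, gene_ids in _runs(items, min_run=min_run, max_gap=max_gap):
            if src != "\0expected":
                blocks.append(
                    TranslocatedBlock(
                        replicon_a=rep_a, replicon_b=src, gene_ids=gene_ids
                    )
                )
    return blocks


# ---------------------------------------------------------------------------
# SNP counting

def count_snps(a: str, b: str, min_identity: float = 0.7) -> int:
    """Substitution count over non-gap columns of a global DNA alignment.

    Raises when alignment identity falls below ``min_identity`` (sequences
    likely non-homologous).
    """
    aln = align_global(a, b, molecule="dna")
    cnt = aln.counts()
    aligned = cnt.identities + cnt.mismatches
    if aligned == 0 or cnt.identities / aligned < min_identity:
        raise ValidationError(
            "sequences align below the identity sanity gate "
            f"({cnt.identities}/{aligned} identical)"
        )
    return int(cnt.mismatches)
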