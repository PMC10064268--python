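"""Genome- and proteome-relatedness indices.

* ``anib`` — fragment-based average nucleotide identity: the query genome is
  cut into non-overlapping 1020-bp fragments, each searched against the
  subject with the seeded aligner; fragments passing the 30% identity / 70%
  coverage gates contribute their identity. Reported per direction and as
  the direction mean.
* ``d4_identity`` — pooled identities / HSP length over the retained
  fragment hits of both directions (the raw identity fraction; no
  regression to a DDH percentage is applied).
* ``cpaai`` — core-proteome AAI pooled over per-marker pairwise global
  alignments of a shared marker set.
* ``wpaai`` — whole-proteome AAI: mean identity over BBH ortholog pairs
  passing 30% identity / 70% coverage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentHit,
    SeedIndex,
    align_global,
    align_local,
    bidirectional_best_hits,
)
from .model import GenomeAssembly, ValidationError

__all__ = [
    "ANIResult",
    "anib",
    "d4_identity",
    "cpaai",
    "wpaai",
    "pairwise_matrix",
]

logger = logging.getLogger("replitax")

_SPACER = "N" * 24  # joins replicons; longer than the seed k so no k-mer spans


@dataclass
class ANIResult:
    ani: float  # mean of the two directions, percent
    ani_ab: float
    ani_ba: float
    n_fragments_ab: int
    n_fragments_ba: int
    hits_ab: list[AlignmentHit] = field(default_factory=list)
    hits_ba: list[AlignmentHit] = field(default_factory=list)


def _genome_seq(genome: GenomeAssembly | str) -> str:
    if isinstance(genome, str):
        return genome.upper()
    return _SPACER.join(r.sequence for r in genome.replicons)


def _fragments(seq: str, size: int) -> list[str]:
    out = []
    for part in seq.split("N" * len(_SPACER)):
        out.extend(part[i : i + size] for i in range(0, len(part), size))
    return [f for f in out if len(f) >= 100]


def _one_direction(
    query: str,
    subject: str,
    fragment: int,
    min_identity: float,
    min_coverage: float,
) -> tuple[float, int, list[AlignmentHit]]:
    index = SeedIndex(subject, k=15)
    identities = []
    hits = []
    for i, frag in enumerate(_fragments(query, fragment)):
        hit = align_local(
            frag,
            subject,
            molecule="dna",
            query_id=f"frag{i:05d}",
            subject_id="subject",
            max_exact_len=0,
            seed_index=index,
        )
        if hit is None:
            continue
        hits.append(hit)
        if hit.identity >= min_identity and hit.query_coverage >= min_coverage:
            identities.append(hit.identity)
    if not identities:
        raise ValidationError(
            "no fragments passed the ANI gates; genomes may be unrelated"
        )
    return 100.0 * float(np.mean(identities)), len(identities), hits


def anib(
    genome_a: GenomeAssembly | str,
    genome_b: GenomeAssembly | str,
    fragment: int = 1020,
    min_frag_identity: float = 0.3,
    min_frag_coverage: float = 0.7,
) -> ANIResult:
    """Fragment-based ANI (both directions plus their mean, in percent)."""
    seq_a = _genome_seq(genome_a)
    seq_b = _genome_seq(genome_b)
    if len(seq_a) < 10 * fragment or len(seq_b) < 10 * fragment:
        raise ValidationError("each genome must span at least 10 fragments")
    ab, n_ab, hits_ab = _one_direction(
        seq_a, seq_b, fragment, min_frag_identity, min_frag_coverage
    )
    ba, n_ba, hits_ba = _one_direction(
        seq_b, seq_a, fragment, min_frag_identity, min_frag_coverage
    )
    return ANIResult(
        ani=(ab + ba) / 2.0,
        ani_ab=ab,
        ani_ba=ba,
        n_fragments_ab=n_ab,
        n_fragments_ba=n_ba,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
    )


def d4_identity(
    genome_a: GenomeAssembly | str,
    genome_b: GenomeAssembly | str,
    evalue_max: float = 1e-15,
    ani_result: ANIResult | None = None,
) -> float:
    """Sum(identities) / sum(HSP length) x 100 over retained fragment HSPs.

    HSPs are the per-fragment best hits of the fragment engine (both
    directions) with e-value <= ``evalue_max``. This is the raw identity
    fraction, deliberately not converted to a DDH-like percentage.
    """
    if ani_result is None:
        ani_result = anib(genome_a, genome_b)
    ident = 0
    cols = 0
    for hit in itertools.chain(ani_result.hits_ab, ani_result.hits_ba):
        if hit.evalue <= evalue_max:
            ident += hit.n_identical
            cols += hit.n_columns
    if cols == 0:
        raise ValidationError("no HSPs above the score gate")
    return 100.0 * ident / cols


# ---------------------------------------------------------------------------
# AAI

def _marker_identity(seq1: str, seq2: str) -> tuple[int, int]:
    """(identical, both-aligned columns) of a global protein alignment."""
    aln = align_global(seq1, seq2, molecule="protein")
    cnt = aln.counts()
    return int(cnt.identities), int(cnt.identities + cnt.mismatches)


def cpaai(
    markers: dict[str, dict[str, str]],
    min_markers: int = 10,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Core-proteome AAI matrix from a marker table.

    ``markers`` maps marker id -> {strain: protein}. Markers missing any
    strain are dropped (logged). A strain absent from more than
    ``max_missing_frac`` of all markers is an error. Identity is pooled over
    markers: sum(identical columns) / sum(columns aligned in both), x 100.
    """
    if not markers:
        raise ValidationError("empty marker set")
    strains = sorted({s for per in markers.values() for s in per})
    n_total = len(markers)
    for s in strains:
        missing = sum(1 for per in markers.values() if s not in per)
        if missing > max_missing_frac * n_total:
            raise ValidationError(
                f"strain {s!r} missing from {missing}/{n_total} markers"
            )
    complete = {
        mid: per for mid, per in markers.items() if set(per) >= set(strains)
    }
    dropped = sorted(set(markers) - set(complete))
    if dropped:
        logger.info("cpaai: dropped %d incomplete markers: %s",
                    len(dropped), ", ".join(dropped[:5]))
    if len(complete) < min_markers:
        raise ValidationError(
            f"only {len(complete)} complete markers (< {min_markers})"
        )
    mat = pd.DataFrame(100.0, index=strains, columns=strains)
    for s1, s2 in itertools.combinations(strains, 2):
        ident = cols = 0
        for per in complete.values():
            i, c = _marker_identity(per[s1], per[s2])
            ident += i
            cols += c
        val = 100.0 * ident / cols if cols else 0.0
        mat.loc[s1, s2] = mat.loc[s2, s1] = val
    return mat


def wpaai(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    evalue_max: float = 1e-3,
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
) -> float:
    """Whole-proteome AAI: unweighted mean identity over BBH pairs."""
    pairs = bidirectional_best_hits(
        proteome_a,
        proteome_b,
        evalue_max=evalue_max,
        min_coverage=min_coverage,
        min_identity=min_identity,
    )
    if not pairs:
        raise ValidationError("no orthologs pass the wpAAI gates")
    return 100.0 * float(np.mean([p.hit_ab.identity for p in pairs]))


# ---------------------------------------------------------------------------
# Matrices

def pairwise_matrix(
    items: dict[str, object],
    func,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Square matrix (diagonal 100) from a pairwise percent-valued index."""
    labels = sorted(items)
    mat = pd.DataFrame(100.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        val = float(func(items[a], items[b]))
        mat.loc[a, b] = val
        mat.loc[b, a] = val if symmetric else float(func(items[b], items[a]))
    return mat
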