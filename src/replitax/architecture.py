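"""Per-replicon composition metrics and chromosome/chromid/megaplasmid calls.

The dinucleotide signature is computed strand-symmetrically: the sequence is
considered together with its reverse complement, dinucleotides are counted
linearly on each strand (no wrap across the circular junction), and

    rho*_XY = f*_XY / (f*_X * f*_Y)

with f* the mono-/dinucleotide frequencies on the symmetrized sequence. The
signature difference between two replicons is reported as

    delta* = (100 / 16) * sum_XY |rho1_XY - rho2_XY|

i.e. the mean absolute rho difference scaled by 100, which puts the chromid
screening threshold at 0.4 on this scale. Non-ACGT bases are excluded from
all counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .model import GenomeAssembly, Replicon, ValidationError

__all__ = [
    "DinucSignature",
    "RepliconMetrics",
    "gc_content",
    "dinucleotide_signature",
    "dra_distance",
    "replicon_metrics",
    "classify_replicons",
    "classify_assembly",
    "cumulative_gc_skew",
    "infer_origin_count",
]

BASES = "ACGT"
DINUCLEOTIDES = [x + y for x in BASES for y in BASES]

# ASCII code -> base index (A=0 C=1 G=2 T=3, everything else = 4 -> masked)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
    return out[::-1]


def gc_content(seq: str) -> float:
    """GC percentage over A/C/G/T positions only (N excluded)."""
    if not seq:
        raise ValidationError("empty sequence")
    codes = _encode(seq)
    counts = np.bincount(codes, minlength=5)
    acgt = int(counts[:4].sum())
    if acgt == 0:
        raise ValidationError("sequence contains no A/C/G/T bases")
    return 100.0 * (int(counts[1]) + int(counts[2])) / acgt


@dataclass(frozen=True)
class DinucSignature:
    """Strand-symmetric dinucleotide relative abundances (16-vector)."""

    rho: np.ndarray  # shape (16,), order AA, AC, ... TT

    def __post_init__(self) -> None:
        if self.rho.shape != (16,):
            raise ValidationError("signature must have 16 entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DINUCLEOTIDES, self.rho.tolist()))


def _count_mono_di(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mono = np.bincount(codes, minlength=5)[:4].astype(float)
    a, b = codes[:-1], codes[1:]
    valid = (a < 4) & (b < 4)
    idx = (a[valid].astype(np.intp) * 4) + b[valid]
    di = np.bincount(idx, minlength=16).astype(float)
    return mono, di


def dinucleotide_signature(seq: str) -> DinucSignature:
    if len(seq) < 2:
        raise ValidationError("sequence too short for dinucleotide counts")
    fwd = _encode(seq)
    rev = _revcomp_codes(fwd)
    mono = np.zeros(4)
    di = np.zeros(16)
    for codes in (fwd, rev):
        m, d = _count_mono_di(codes)
        mono += m
        di += d
    missing = [BASES[i] for i in range(4) if mono[i] == 0]
    if missing:
        raise ValidationError(
            f"degenerate composition: base(s) {missing} absent"
        )
    f1 = mono / mono.sum()
    f2 = di / di.sum()
    rho = f2.reshape(4, 4) / np.outer(f1, f1)
    return DinucSignature(rho=rho.reshape(16))


def dra_distance(sig1: DinucSignature, sig2: DinucSignature) -> float:
    """Scaled signature distance delta* (threshold 0.4 for chromids)."""
    return float((100.0 / 16.0) * np.abs(sig1.rho - sig2.rho).sum())


# ---------------------------------------------------------------------------
# Classification

@dataclass
class RepliconMetrics:
    replicon_id: str
    length: int
    gc: float
    dra_to_chromosome: float | None = None
    classification: str | None = None


def replicon_metrics(assembly: GenomeAssembly) -> list[RepliconMetrics]:
    """Length, GC, and DRA distance to the (largest) chromosome."""
    if not assembly.replicons:
        raise ValidationError(f"assembly {assembly.strain!r} has no replicons")
    largest = max(assembly.replicons, key=lambda r: (r.length, r.id))
    chrom_sig = dinucleotide_signature(largest.sequence)
    metrics = []
    for rep in assembly.replicons:
        dra = (
            0.0
            if rep.id == largest.id
            else dra_distance(chrom_sig, dinucleotide_signature(rep.sequence))
        )
        metrics.append(
            RepliconMetrics(
                replicon_id=rep.id,
                length=rep.length,
                gc=gc_content(rep.sequence),
                dra_to_chromosome=dra,
            )
        )
    return metrics


def classify_replicons(
    metrics: list[RepliconMetrics],
    gc_tol: float = 1.0,
    dra_tol: float = 0.4,
) -> list[RepliconMetrics]:
    """Chromosome / putative_chromid / ambiguous / megaplasmid calls.

    The largest replicon is the chromosome (ties broken by id order, with a
    warning). Every other replicon is compared to it: both the GC and the
    DRA criteria pass (boundary inclusive) -> putative_chromid; exactly one
    passes -> ambiguous (flagged for further analysis); neither ->
    megaplasmid.
    """
    if not metrics:
        raise ValidationError("no replicon metrics supplied")
    ranked = sorted(metrics, key=lambda m: (-m.length, m.replicon_id))
    chromosome = ranked[0]
    if len(ranked) > 1 and ranked[1].length == chromosome.length:
        import logging

        logging.getLogger("replitax").warning(
            "largest-replicon tie between %r and %r broken by id order",
            chromosome.replicon_id,
            ranked[1].replicon_id,
        )
    out = []
    for m in metrics:
        cls = "chromosome"
        if m.replicon_id != chromosome.replicon_id:
            if m.dra_to_chromosome is None:
                raise ValidationError(
                    f"replicon {m.replicon_id!r}: DRA distance not computed"
                )
            gc_ok = abs(m.gc - chromosome.gc) <= gc_tol
            dra_ok = m.dra_to_chromosome <= dra_tol
            if gc_ok and dra_ok:
                cls = "putative_chromid"
            elif gc_ok or dra_ok:
                cls = "ambiguous"
            else:
                cls = "megaplasmid"
        out.append(
            RepliconMetrics(
                replicon_id=m.replicon_id,
                length=m.length,
                gc=m.gc,
                dra_to_chromosome=m.dra_to_chromosome,
                classification=cls,
            )
        )
    return out


def classify_assembly(
    assembly: GenomeAssembly, gc_tol: float = 1.0, dra_tol: float = 0.4
) -> list[RepliconMetrics]:
    return classify_replicons(
        replicon_metrics(assembly), gc_tol=gc_tol, dra_tol=dra_tol
    )


# ---------------------------------------------------------------------------
# GC skew

def cumulative_gc_skew(
    seq: str, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative per-window (G-C)/(G+C) profile.

    Returns (window midpoints in bp, cumulative skew), one point per window
    (``ceil(len(seq)/window)`` points). Windows with no G or C contribute 0.
    """
    n = len(seq)
    if window < 1 or window > n // 10:
        raise ValidationError("window must be in [1, len(seq)/10]")
    codes = _encode(seq)
    is_g = (codes == 2).astype(np.int64)
    is_c = (codes == 1).astype(np.int64)
    n_win = -(-n // window)
    pad = n_win * window - n
    if pad:
        is_g = np.r_[is_g, np.zeros(pad, dtype=np.int64)]
        is_c = np.r_[is_c, np.zeros(pad, dtype=np.int64)]
    g = is_g.reshape(n_win, window).sum(axis=1)
    c = is_c.reshape(n_win, window).sum(axis=1)
    denom = g + c
    skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    midpoints = np.minimum(
        np.arange(n_win) * window + window / 2.0, n
    )
    return midpoints, np.cumsum(skew)


def _circular_extrema(z: np.ndarray, prominence: float) -> tuple[int, ...]:
    """Prominent peak positions of a circular profile (indices mod n)."""
    n = len(z)
    tiled = np.r_[z, z, z]
    peaks, _ = find_peaks(tiled, prominence=prominence)
    hits = sorted({int(p - n) for p in peaks if n <= p < 2 * n})
    return tuple(hits)


def _direction_consistency(steps: np.ndarray) -> float:
    """Fraction of steps moving in the majority direction."""
    nz = steps[steps != 0]
    if len(nz) == 0:
        return 0.0
    up = float(np.mean(nz > 0))
    return max(up, 1.0 - up)


def infer_origin_count(
    profile: np.ndarray,
    smooth_windows: int = 5,
    prominence_frac: float = 0.25,
    min_separation_frac: float = 0.25,
    min_consistency: float = 0.7,
) -> str:
    """'single', 'multiple', or 'indeterminate' from a cumulative skew profile.

    The profile is treated as circular, smoothed with a moving average, and
    prominent maxima/minima (prominence >= ``prominence_frac`` of the range)
    are counted. A single origin shows exactly one maximum and one minimum
    region, separated by at least ``min_separation_frac`` of the replicon,
    with directionally consistent skew along the two replichore arms; two or
    more prominent extrema pairs indicate multiple origins; everything else
    (including flat random-walk noise) is indeterminate.
    """
    z = np.asarray(profile, dtype=float)
    if len(z) < 10:
        raise ValidationError("profile needs at least 10 windows")
    kernel = np.ones(smooth_windows) / smooth_windows
    sm = np.convolve(np.r_[z[-smooth_windows:], z, z[:smooth_windows]], kernel, mode="same")
    sm = sm[smooth_windows:-smooth_windows]
    rng = sm.max() - sm.min()
    if rng == 0:
        return "indeterminate"
    prom = prominence_frac * rng
    maxima = _circular_extrema(sm, prom)
    minima = _circular_extrema(-sm, prom)
    n = len(sm)
    steps = np.diff(np.r_[z, z[0]])  # circular step series

    def arc_consistency(lo: int, hi: int) -> float:
        if lo < hi:
            return _direction_consistency(steps[lo:hi])
        return _direction_consistency(np.r_[steps[lo:], steps[:hi]])

    # replichore arms must be directionally consistent, unlike a random
    # walk whose excursions also produce prominent extrema
    extrema = sorted(
        [(i, "max") for i in maxima] + [(i, "min") for i in minima]
    )
    alternating = all(
        extrema[i][1] != extrema[(i + 1) % len(extrema)][1]
        for i in range(len(extrema))
    )
    arcs_ok = alternating and all(
        arc_consistency(extrema[i][0], extrema[(i + 1) % len(extrema)][0])
        >= min_consistency
        for i in range(len(extrema))
    )
    if len(maxima) >= 2 and len(minima) >= 2 and arcs_ok:
        return "multiple"
    if len(maxima) == 1 and len(minima) == 1 and arcs_ok:
        i, j = maxima[0], minima[0]
        arc = min(abs(i - j), n - abs(i - j))
        if arc >= min_separation_frac * n:
            return "single"
    return "indeterminate"
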