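"""Synthetic multipartite genomes with known ground truth.

Replicon sequences are sampled from a first-order Markov chain whose
stationary dinucleotide content matches a requested GC and (optionally) a
requested 16-entry relative-abundance signature; strain pairs are derived
by per-site substitution (and optional single-base indels); cointegrants,
translocated gene blocks, and group-structured gene presence/absence are
produced with machine-readable truth tables so every analysis stage can be
tested without external data.

All operations are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneRecord, GenomeAssembly, ProteinRecord, Replicon, ValidationError

__all__ = [
    "RepliconSpec",
    "StrainPairSpec",
    "PangenomeSpec",
    "build_transition_matrix",
    "generate_replicon",
    "generate_assembly",
    "mutate_sequence",
    "simulate_cointegrant",
    "cointegrate_assembly",
    "simulate_pangenome",
    "PangenomeTruth",
    "random_protein",
    "mutate_protein",
    "assembly_from_gene_table",
    "simulate_strain_pair",
    "translocate_block",
    "tumorigenes_like_preset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_DINUC = [x + y for x in "ACGT" for y in "ACGT"]


# ---------------------------------------------------------------------------
# Specs

@dataclass
class RepliconSpec:
    id: str
    length: int
    target_gc: float  # percent
    signature_source: str | np.ndarray = "independent"
    # "shared_with_chromosome" | "independent" | explicit 16-vector of rho
    role_truth: str = "chromosome"  # chromosome | chromid | megaplasmid

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValidationError(f"replicon spec {self.id!r}: length < 1000")
        if not 20.0 <= self.target_gc <= 80.0:
            raise ValidationError(
                f"replicon spec {self.id!r}: target_gc outside [20, 80]"
            )
        if isinstance(self.signature_source, str):
            if self.signature_source not in (
                "shared_with_chromosome",
                "independent",
            ):
                raise ValidationError(
                    f"unknown signature_source {self.signature_source!r}"
                )
        else:
            self.signature_source = np.asarray(self.signature_source, float)
            if self.signature_source.shape != (16,):
                raise ValidationError("explicit signature must have 16 entries")


@dataclass
class StrainPairSpec:
    substitution_rate: float
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("substitution_rate", self.substitution_rate),
            ("indel_rate", self.indel_rate),
        ):
            if not 0.0 <= rate < 0.5:
                raise ValidationError(f"{name} must be in [0, 0.5)")

    @property
    def ground_truth_identity(self) -> float:
        return 1.0 - self.substitution_rate


@dataclass
class PangenomeSpec:
    n_strains_a: int
    n_strains_b: int
    n_core: int = 0
    n_a_specific: int = 0
    n_b_specific: int = 0
    n_cloud: int = 0
    aa_divergence_within: float = 0.02
    aa_divergence_between: float = 0.1
    n_compensated: int = 0  # A-specific clusters with a divergent B homolog
    compensation_divergence: float = 0.5
    protein_length: int = 300
    cloud_presence: float = 0.4

    def __post_init__(self) -> None:
        if self.n_strains_a < 1 or self.n_strains_b < 1:
            raise ValidationError("need at least one strain per group")
        for n in (self.n_core, self.n_a_specific, self.n_b_specific, self.n_cloud):
            if n < 0:
                raise ValidationError("gene counts must be >= 0")
        for d in (self.aa_divergence_within, self.aa_divergence_between):
            if not 0.0 <= d < 1.0:
                raise ValidationError("divergences must be in [0, 1)")
        if self.n_compensated > self.n_a_specific:
            raise ValidationError("n_compensated exceeds n_a_specific")


# ---------------------------------------------------------------------------
# Markov-chain sequence generation

def _base_probs(target_gc: float) -> np.ndarray:
    gc = target_gc / 100.0
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def build_transition_matrix(
    target_gc: float, rho: np.ndarray | None = None
) -> np.ndarray:
    """4x4 transition matrix whose chain realizes the GC and signature.

    With ``rho`` given, joint dinucleotide frequencies are formed as
    ``rho_XY * p_X * p_Y`` and Sinkhorn-balanced so that both marginals equal
    the target base composition; the chain then has the requested stationary
    GC exactly. A signature inconsistent with its own marginals (i.e. with
    ``sum_Y rho_XY p_Y != 1`` for some X) is projected onto the closest
    balanced joint, so strong requested biases are realized in direction but
    may be damped in magnitude.
    """
    p = _base_probs(target_gc)
    if rho is None:
        return np.tile(p, (4, 1))
    rho = np.asarray(rho, float).reshape(4, 4)
    if np.any(rho < 0):
        x, y = np.argwhere(rho < 0)[0]
        raise ValidationError(
            f"infeasible signature: rho[{'ACGT'[x]}{'ACGT'[y]}] < 0"
        )
    f2 = rho * np.outer(p, p)
    if np.any(f2.sum(axis=1) == 0):
        x = int(np.argwhere(f2.sum(axis=1) == 0)[0][0])
        raise ValidationError(
            f"infeasible signature: all dinucleotides starting with "
            f"{'ACGT'[x]} have zero probability"
        )
    for _ in range(50):  # Sinkhorn balancing to marginals p
        f2 *= (p / f2.sum(axis=1))[:, None]
        f2 *= (p / f2.sum(axis=0))[None, :]
    trans = f2 / f2.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(trans)):
        raise ValidationError("infeasible signature: non-normalizable matrix")
    return trans


def _markov_chain_codes(
    transition: np.ndarray, length: int, rng: np.random.Generator
) -> np.ndarray:
    from numba import njit

    cum = np.cumsum(transition, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    p0 = transition.mean(axis=0)
    first = int(np.searchsorted(np.cumsum(p0), u[0]))

    @njit(cache=False)
    def walk(cum, u, first):
        n = u.shape[0]
        out = np.empty(n, dtype=np.uint8)
        state = first
        out[0] = state
        for i in range(1, n):
            x = u[i]
            row = cum[state]
            nxt = 0
            while row[nxt] < x:
                nxt += 1
            state = nxt
            out[i] = state
        return out

    return walk(cum, u, min(first, 3))


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_replicon(
    spec: RepliconSpec,
    seed: int,
    shared_matrix: np.ndarray | None = None,
) -> tuple[Replicon, np.ndarray]:
    """Sample one replicon; returns (replicon, transition matrix used).

    ``shared_matrix`` must be supplied when the spec's signature source is
    ``shared_with_chromosome``.
    """
    if isinstance(spec.signature_source, np.ndarray):
        trans = build_transition_matrix(spec.target_gc, spec.signature_source)
    elif spec.signature_source == "shared_with_chromosome":
        if shared_matrix is None:
            raise ValidationError(
                f"replicon {spec.id!r}: shared signature requested but no "
                "chromosome matrix supplied"
            )
        trans = shared_matrix
    else:
        trans = build_transition_matrix(spec.target_gc)
    rng = np.random.default_rng(seed)
    codes = _markov_chain_codes(trans, spec.length, rng)
    return Replicon(id=spec.id, sequence=_codes_to_seq(codes)), trans


def generate_assembly(
    strain: str, specs: list[RepliconSpec], seed: int
) -> tuple[GenomeAssembly, dict[str, str]]:
    """Generate a multipartite genome; returns (assembly, role truth map).

    The first spec with role ``chromosome`` provides the shared transition
    matrix for ``shared_with_chromosome`` replicons.
    """
    chrom_specs = [s for s in specs if s.role_truth == "chromosome"]
    if len(chrom_specs) != 1:
        raise ValidationError("exactly one spec must have role chromosome")
    rng = np.random.default_rng(seed)
    chrom_matrix: np.ndarray | None = None
    replicons: list[Replicon] = []
    # chromosome first so its matrix is available, but keep input order
    order = sorted(specs, key=lambda s: s.role_truth != "chromosome")
    built: dict[str, Replicon] = {}
    for s in order:
        sub_seed = int(rng.integers(0, 2**63 - 1))
        rep, trans = generate_replicon(s, sub_seed, shared_matrix=chrom_matrix)
        if s.role_truth == "chromosome":
            chrom_matrix = trans
        built[s.id] = rep
    replicons = [built[s.id] for s in specs]
    truth = {s.id: s.role_truth for s in specs}
    return GenomeAssembly(strain=strain, replicons=replicons), truth


# ---------------------------------------------------------------------------
# Mutation

def mutate_sequence(seq: str, spec: StrainPairSpec) -> str:
    """Independent per-site substitutions (uniform over the 3 other bases),
    plus optional single-base insertions/deletions at ``indel_rate``."""
    rng = np.random.default_rng(spec.seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    idx = lut[codes]
    acgt = idx < 4
    sub = (rng.random(len(seq)) < spec.substitution_rate) & acgt
    if sub.any():
        offset = rng.integers(1, 4, size=int(sub.sum()))
        idx[sub] = (idx[sub] + offset) % 4
        codes[sub] = _BASES[idx[sub]]
    if spec.indel_rate > 0:
        u = rng.random(len(codes))
        keep = u >= spec.indel_rate / 2.0  # deletions
        ins = u > 1.0 - spec.indel_rate / 2.0  # insertion after the site
        parts: list[bytes] = []
        arr = codes
        out = []
        ins_bases = _BASES[rng.integers(0, 4, size=int(ins.sum()))]
        it = iter(ins_bases)
        for i in range(len(arr)):
            if keep[i]:
                out.append(arr[i])
            if ins[i]:
                out.append(next(it))
        codes = np.array(out, dtype=np.uint8)
    return codes.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Cointegration

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class CointegrantTruth:
    order: list[str]  # source replicon ids in cointegrant order
    orientation: dict[str, str]  # source id -> "+" | "-"
    junctions: list[int]  # 1-based positions of segment starts
    source_of_gene: dict[str, str] = field(default_factory=dict)


def simulate_cointegrant(
    replicons: list[Replicon],
    seed: int,
    genes: list[GeneRecord] | None = None,
    new_id: str = "cointegrant",
) -> tuple[Replicon, CointegrantTruth, list[GeneRecord]]:
    """Fuse replicons into one circular replicon in random order/orientation.

    Gene coordinates (when given) are lifted onto the cointegrant; truth
    records segment order, orientations, junction positions (segment starts,
    1-based; a single replicon yields one junction, the circular closure),
    and each gene's source replicon.
    """
    if not replicons:
        raise ValidationError("cointegrant needs at least one replicon")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(replicons)))
    orientation = {
        replicons[i].id: ("+" if rng.random() < 0.5 else "-") for i in order
    }
    parts: list[str] = []
    offsets: dict[str, int] = {}
    junctions: list[int] = []
    pos = 0
    ordered_ids = []
    for i in order:
        rep = replicons[i]
        ordered_ids.append(rep.id)
        junctions.append(pos + 1)
        offsets[rep.id] = pos
        seq = rep.sequence
        if orientation[rep.id] == "-":
            seq = _revcomp(seq)
        parts.append(seq)
        pos += rep.length
    fused = Replicon(id=new_id, sequence="".join(parts))
    truth = CointegrantTruth(
        order=ordered_ids, orientation=orientation, junctions=junctions
    )
    lifted: list[GeneRecord] = []
    if genes:
        lengths = {r.id: r.length for r in replicons}
        for g in genes:
            if g.replicon_id not in offsets:
                continue
            off = offsets[g.replicon_id]
            L = lengths[g.replicon_id]
            if orientation[g.replicon_id] == "+":
                start, end, strand = off + g.start, off + g.end, g.strand
            else:
                start = off + (L - g.end + 1)
                end = off + (L - g.start + 1)
                strand = "-" if g.strand == "+" else "+"
            lifted.append(
                GeneRecord(
                    gene_id=g.gene_id,
                    replicon_id=new_id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=g.product,
                )
            )
            truth.source_of_gene[g.gene_id] = g.replicon_id
    return fused, truth, lifted


def cointegrate_assembly(
    assembly: GenomeAssembly,
    replicon_ids: list[str],
    seed: int,
    new_id: str = "cointegrant",
) -> tuple[GenomeAssembly, CointegrantTruth]:
    """Replace the named replicons of an assembly by their cointegrant."""
    chosen = [assembly.replicon(rid) for rid in replicon_ids]
    genes_in = [g for g in assembly.genes if g.replicon_id in set(replicon_ids)]
    fused, truth, lifted = simulate_cointegrant(
        chosen, seed, genes=genes_in, new_id=new_id
    )
    keep_reps = [r for r in assembly.replicons if r.id not in set(replicon_ids)]
    keep_genes = [g for g in assembly.genes if g.replicon_id not in set(replicon_ids)]
    merged = GenomeAssembly(
        strain=assembly.strain,
        replicons=keep_reps + [fused],
        genes=keep_genes + lifted,
        proteome=list(assembly.proteome),
    )
    return merged, truth


# ---------------------------------------------------------------------------
# Proteins and gene tables

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < divergence
    if mask.any():
        pool = np.array(list(_AA20))
        repl = pool[rng.integers(0, 20, size=int(mask.sum()))]
        same = repl == chars[mask]
        while same.any():
            repl[same] = pool[rng.integers(0, 20, size=int(same.sum()))]
            same = repl == chars[mask]
        chars[mask] = repl
    return "".join(chars)


_GENE_PITCH = 1200  # bp allotted per gene slot on synthetic replicons
_GENE_LEN = 900


def assembly_from_gene_table(
    strain: str,
    replicon_genes: dict[str, list[tuple[str, str]]],
    seed: int = 0,
) -> GenomeAssembly:
    """Build an assembly from {replicon_id: [(gene_id, aa_seq), ...]}.

    Genes are laid out on a fixed pitch; replicon DNA is random filler (the
    proteome is authoritative for alignment work on synthetic strains).
    """
    rng = np.random.default_rng(seed)
    replicons, genes, proteome = [], [], []
    for rid in replicon_genes:
        gene_list = replicon_genes[rid]
        length = max(len(gene_list) * _GENE_PITCH + 600, 1000)
        seq = _codes_to_seq(
            rng.integers(0, 4, size=length).astype(np.uint8)
        )
        replicons.append(Replicon(id=rid, sequence=seq))
        for i, (gid, aa) in enumerate(gene_list):
            start = i * _GENE_PITCH + 1
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    replicon_id=rid,
                    start=start,
                    end=start + _GENE_LEN - 1,
                    strand="+" if (i % 2 == 0) else "-",
                )
            )
            proteome.append(ProteinRecord(gene_id=gid, aa_sequence=aa))
    return GenomeAssembly(
        strain=strain, replicons=replicons, genes=genes, proteome=proteome
    )


# ---------------------------------------------------------------------------
# Orthologous strain pairs, translocations

@dataclass
class StrainPairTruth:
    expected_partners: dict[str, str]  # replicon of A -> replicon of B
    gene_partner: dict[str, str]  # gene of A -> gene of B
    translocated: list[tuple[str, str, list[str]]] = field(default_factory=list)
    # (replicon_a, actual replicon_b, gene ids of A)


def simulate_strain_pair(
    replicon_sizes: dict[str, int],
    seed: int,
    aa_divergence: float = 0.05,
    protein_length: int = 300,
    strain_a: str = "strainA",
    strain_b: str = "strainB",
) -> tuple[GenomeAssembly, GenomeAssembly, StrainPairTruth]:
    """Two strains with one-to-one orthologous gene complements.

    ``replicon_sizes`` maps replicon names to gene counts. Strain B carries
    the same replicons (ids suffixed ``_b``) with orthologs diverged by
    ``aa_divergence``.
    """
    rng = np.random.default_rng(seed)
    table_a: dict[str, list[tuple[str, str]]] = {}
    table_b: dict[str, list[tuple[str, str]]] = {}
    truth = StrainPairTruth(expected_partners={}, gene_partner={})
    for rid, n_genes in replicon_sizes.items():
        rid_b = f"{rid}_b"
        truth.expected_partners[rid] = rid_b
        a_list, b_list = [], []
        for i in range(n_genes):
            gid_a = f"{rid}.g{i:04d}"
            gid_b = f"{rid_b}.g{i:04d}"
            ancestor = random_protein(protein_length, rng)
            a_list.append((gid_a, mutate_protein(ancestor, aa_divergence / 2, rng)))
            b_list.append((gid_b, mutate_protein(ancestor, aa_divergence / 2, rng)))
            truth.gene_partner[gid_a] = gid_b
        table_a[rid] = a_list
        table_b[rid_b] = b_list
    sub = rng.integers(0, 2**31)
    asm_a = assembly_from_gene_table(strain_a, table_a, seed=int(sub))
    asm_b = assembly_from_gene_table(strain_b, table_b, seed=int(sub) + 1)
    return asm_a, asm_b, truth


def translocate_block(
    assembly: GenomeAssembly,
    gene_ids: list[str],
    dest_replicon: str,
) -> GenomeAssembly:
    """Move the named genes to the end of ``dest_replicon`` (contiguously),
    re-laying gene coordinates on both affected replicons."""
    moved = set(gene_ids)
    table: dict[str, list[tuple[str, str]]] = {}
    prot = assembly.proteins_by_id
    for rep in assembly.replicons:
        table[rep.id] = [
            (g.gene_id, prot[g.gene_id])
            for g in assembly.genes_on(rep.id)
            if g.gene_id not in moved
        ]
    if dest_replicon not in table:
        raise ValidationError(f"unknown destination replicon {dest_replicon!r}")
    by_id = {g.gene_id: g for g in assembly.genes}
    ordered = sorted(gene_ids, key=lambda gid: (by_id[gid].start, gid))
    table[dest_replicon].extend((gid, prot[gid]) for gid in ordered)
    return assembly_from_gene_table(assembly.strain, table, seed=0)


# ---------------------------------------------------------------------------
# Pan-genome simulation

@dataclass
class PangenomeTruth:
    table: pd.DataFrame  # cluster_id, category, then one presence col/strain
    strains_a: list[str]
    strains_b: list[str]

    def clusters(self, category: str) -> list[str]:
        t = self.table
        return list(t.loc[t["category"] == category, "cluster_id"])


def simulate_pangenome(
    spec: PangenomeSpec, seed: int
) -> tuple[dict[str, dict[str, str]], PangenomeTruth]:
    """Per-strain proteomes plus a presence/absence truth table.

    Gene ids are ``<cluster>|<strain>``. Compensated clusters additionally
    plant a homolog diverged by ``compensation_divergence`` in every B
    strain (ids ``<cluster>c|<strain>``), recorded with category
    ``compensation``.
    """
    rng = np.random.default_rng(seed)
    strains_a = [f"A{i+1}" for i in range(spec.n_strains_a)]
    strains_b = [f"B{i+1}" for i in range(spec.n_strains_b)]
    all_strains = strains_a + strains_b
    proteomes: dict[str, dict[str, str]] = {s: {} for s in all_strains}
    rows = []

    def add_cluster(cid, category, present, ancestors):
        """ancestors: strain -> group ancestor sequence."""
        row = {"cluster_id": cid, "category": category}
        for s in all_strains:
            if s in present:
                aa = mutate_protein(
                    ancestors[s], spec.aa_divergence_within / 2, rng
                )
                proteomes[s][f"{cid}|{s}"] = aa
                row[s] = 1
            else:
                row[s] = 0
        rows.append(row)

    def group_ancestors(root):
        anc_a = mutate_protein(root, spec.aa_divergence_between / 2, rng)
        anc_b = mutate_protein(root, spec.aa_divergence_between / 2, rng)
        return {s: (anc_a if s in strains_a else anc_b) for s in all_strains}

    for i in range(spec.n_core):
        root = random_protein(spec.protein_length, rng)
        add_cluster(f"core{i:04d}", "core", set(all_strains), group_ancestors(root))
    for i in range(spec.n_a_specific):
        root = random_protein(spec.protein_length, rng)
        cid = f"aspec{i:04d}"
        add_cluster(cid, "A_specific", set(strains_a), {s: root for s in all_strains})
        if i < spec.n_compensated:
            homolog = mutate_protein(root, spec.compensation_divergence, rng)
            add_cluster(
                f"{cid}c",
                "compensation",
                set(strains_b),
                {s: homolog for s in all_strains},
            )
    for i in range(spec.n_b_specific):
        root = random_protein(spec.protein_length, rng)
        add_cluster(f"bspec{i:04d}", "B_specific", set(strains_b), {s: root for s in all_strains})
    for i in range(spec.n_cloud):
        root = random_protein(spec.protein_length, rng)
        present = {
            s for s in all_strains if rng.random() < spec.cloud_presence
        }
        # cloud genes must not be core or specific by accident
        if len(present) in (0, len(all_strains)):
            present = {all_strains[int(rng.integers(0, len(all_strains)))]}
        if present == set(strains_a) or present == set(strains_b):
            present.pop()
            if not present:
                present = {strains_a[0]}
        add_cluster(f"cloud{i:04d}", "cloud", present, {s: root for s in all_strains})

    table = pd.DataFrame(rows, columns=["cluster_id", "category"] + all_strains)
    return proteomes, PangenomeTruth(
        table=table, strains_a=strains_a, strains_b=strains_b
    )


# ---------------------------------------------------------------------------
# Preset

def tumorigenes_like_preset(
    seed: int, scale: float = 0.1
) -> dict[str, tuple[GenomeAssembly, dict[str, str]]]:
    """Three multipartite genomes mirroring the bundled replicon inventory
    (default 10x smaller). Chromids share the chromosome signature and GC;
    megaplasmids get an independent signature at their inventory GC."""
    from .data import reference_replicons

    inv = reference_replicons()
    # mildly structured chromosome signature (CG/TA depletion)
    rho = np.ones((4, 4))
    rho[1, 2] = rho[2, 1] = 0.72  # CG / GC pairing
    rho[3, 0] = rho[0, 3] = 0.80  # TA / AT
    rho[0, 0] = rho[3, 3] = 1.18
    out: dict[str, tuple[GenomeAssembly, dict[str, str]]] = {}
    rng = np.random.default_rng(seed)
    for strain, group in inv.groupby("strain", sort=False):
        specs = []
        chrom = group.loc[group["role"] == "chromosome"].iloc[0]
        for _, row in group.iterrows():
            role = row["role"]
            if role == "chromosome":
                source: str | np.ndarray = rho.reshape(16)
                gc = float(row["gc_percent"])
            elif role == "chromid":
                source = "shared_with_chromosome"
                gc = float(chrom["gc_percent"])
            else:
                source = "independent"
                gc = float(row["gc_percent"])
            specs.append(
                RepliconSpec(
                    id=str(row["replicon"]),
                    length=max(int(row["size_bp"] * scale), 1000),
                    target_gc=gc,
                    signature_source=source,
                    role_truth="chromid" if role == "chromid" else role,
                )
            )
        out[str(strain)] = generate_assembly(
            str(strain), specs, seed=int(rng.integers(0, 2**31))
        )
    return out
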