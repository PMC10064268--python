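"""Ortholog clustering, species-specific gene detection, and
species/genus demarcation from relatedness matrices.

Ortholog clusters are connected components of the all-pairs BBH graph; a
component that ends up with two or more genes from one strain is split so
that each gene keeps only its highest-scoring edges (weakest edges removed
until every strain is represented at most once per cluster).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .alignment import align_local, bidirectional_best_hits
from .model import GeneRecord, ValidationError

__all__ = [
    "OrthologCluster",
    "cluster_orthologs",
    "presence_matrix",
    "SpecificGeneReport",
    "core_and_specific",
    "compensation_check",
    "greedy_identity_clustering",
    "DemarcationReport",
    "demarcate",
]


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (strain, gene_id)

    @property
    def strains(self) -> set[str]:
        return {s for s, _ in self.members}

    def copy_number(self, strain: str) -> int:
        return sum(1 for s, _ in self.members if s == strain)


def cluster_orthologs(
    proteomes: dict[str, dict[str, str]],
    evalue_max: float = 1e-10,
    min_coverage: float = 0.75,
) -> list[OrthologCluster]:
    """BBH-graph connected components across all strain pairs.

    Components with a duplicated strain are split by removing the weakest
    edges (lowest bit score, ties by ids) until every strain occurs at most
    once per component; each removal only severs an edge, so genes always
    keep their strongest links.
    """
    if len(proteomes) < 2:
        raise ValidationError("need at least 2 strains")
    g = nx.Graph()
    for strain, prots in proteomes.items():
        for gid in prots:
            g.add_node((strain, gid))
    for sa, sb in itertools.combinations(sorted(proteomes), 2):
        if not proteomes[sa] or not proteomes[sb]:
            continue
        for pair in bidirectional_best_hits(
            proteomes[sa],
            proteomes[sb],
            evalue_max=evalue_max,
            min_coverage=min_coverage,
        ):
            g.add_edge(
                (sa, pair.gene_a),
                (sb, pair.gene_b),
                score=min(pair.hit_ab.score, pair.hit_ba.score),
            )

    clusters: list[OrthologCluster] = []
    worklist = sorted(
        (set(c) for c in nx.connected_components(g)),
        key=lambda c: sorted(c)[0],
    )
    while worklist:
        comp = worklist.pop(0)
        strains = [s for s, _ in comp]
        sub = g.subgraph(comp)
        if len(strains) == len(set(strains)) or sub.number_of_edges() == 0:
            clusters.append(
                OrthologCluster(cluster_id="", members=sorted(comp))
            )
            continue
        sub = sub.copy()
        weakest = min(
            sub.edges(data=True),
            key=lambda e: (e[2]["score"], sorted((e[0], e[1]))),
        )
        sub.remove_edge(weakest[0], weakest[1])
        worklist.extend(
            sorted(
                (set(c) for c in nx.connected_components(sub)),
                key=lambda c: sorted(c)[0],
            )
        )
    # label deterministically by first member
    clusters.sort(key=lambda c: c.members[0])
    for i, c in enumerate(clusters):
        c.cluster_id = f"OC{i:05d}"
    return clusters


def presence_matrix(
    clusters: list[OrthologCluster], strains: list[str], copy_number: bool = False
) -> pd.DataFrame:
    """Strains x clusters 0/1 (or copy-number) matrix."""
    data = {}
    for c in clusters:
        if copy_number:
            data[c.cluster_id] = [c.copy_number(s) for s in strains]
        else:
            data[c.cluster_id] = [int(s in c.strains) for s in strains]
    return pd.DataFrame(data, index=strains)


@dataclass
class SpecificGeneReport:
    group_a: str
    group_b: str
    core: list[str]
    a_specific: list[str]
    b_specific: list[str]
    locations: dict[str, dict[str, str]] = field(default_factory=dict)
    # cluster -> strain -> replicon id
    copy_numbers: dict[str, dict[str, int]] = field(default_factory=dict)
    compensation: dict[str, str] = field(default_factory=dict)


def core_and_specific(
    clusters: list[OrthologCluster],
    group_assignment: dict[str, str],
    genes: dict[str, dict[str, GeneRecord]] | None = None,
) -> SpecificGeneReport:
    """Core and strictly species-specific clusters.

    A cluster is A-specific iff it is present in *all* strains of group A
    and absent from *all* strains of group B (strict quantifiers), and vice
    versa. ``genes`` ({strain: {gene_id: record}}) adds per-cluster replicon
    locations and per-strain copy numbers.
    """
    groups = sorted(set(group_assignment.values()))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    strains_a = {s for s, g in group_assignment.items() if g == ga}
    strains_b = {s for s, g in group_assignment.items() if g == gb}
    if not strains_a or not strains_b:
        raise ValidationError("both groups must be non-empty")
    report = SpecificGeneReport(
        group_a=ga, group_b=gb, core=[], a_specific=[], b_specific=[]
    )
    for c in clusters:
        present = c.strains
        if present >= (strains_a | strains_b):
            report.core.append(c.cluster_id)
        elif present >= strains_a and not (present & strains_b):
            report.a_specific.append(c.cluster_id)
        elif present >= strains_b and not (present & strains_a):
            report.b_specific.append(c.cluster_id)
        else:
            continue
        report.copy_numbers[c.cluster_id] = {
            s: c.copy_number(s) for s in sorted(present)
        }
        if genes:
            report.locations[c.cluster_id] = {
                s: genes[s][gid].replicon_id
                for s, gid in c.members
                if s in genes and gid in genes[s]
            }
    return report


def compensation_check(
    cluster_sequences: list[str],
    other_group_proteomes: dict[str, dict[str, str]],
    min_identity: float = 0.3,
    min_coverage: float = 0.5,
) -> str:
    """'compensated' if the cluster representative finds any relaxed-gate
    homolog in the other group's proteomes, else 'not_found'."""
    if not cluster_sequences:
        raise ValidationError("cluster has no sequences")
    rep = max(cluster_sequences, key=len)
    for strain in sorted(other_group_proteomes):
        prots = other_group_proteomes[strain]
        for gid in sorted(prots):
            hit = align_local(
                rep, prots[gid], molecule="protein", n_subjects=len(prots)
            )
            if (
                hit is not None
                and hit.identity >= min_identity
                and hit.query_coverage >= min_coverage
            ):
                return "compensated"
    return "not_found"


def greedy_identity_clustering(
    proteins: dict[str, str], threshold: float = 0.9
) -> list[list[str]]:
    """CD-HIT-style greedy clustering by decreasing length.

    Each sequence joins the first cluster whose representative it matches at
    >= ``threshold`` identity computed over the shorter sequence, otherwise
    it founds a new cluster (and becomes its representative).
    """
    if not proteins:
        raise ValidationError("empty protein set")
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for pid in order:
        seq = proteins[pid]
        placed = False
        for i, rep_id in enumerate(reps):
            rep_seq = proteins[rep_id]
            hit = align_local(seq, rep_seq, molecule="protein")
            if hit is None:
                continue
            ident = hit.n_identical / min(len(seq), len(rep_seq))
            if ident >= threshold:
                clusters[i].append(pid)
                placed = True
                break
        if not placed:
            reps.append(pid)
            clusters.append([pid])
    return clusters


# ---------------------------------------------------------------------------
# Demarcation

@dataclass
class DemarcationReport:
    species: list[set[str]]
    genera: list[set[str]]
    ambiguous_species_pairs: list[tuple[str, str, float]]
    ambiguous_genus_taxa: list[str]


def _single_linkage(matrix: pd.DataFrame, threshold: float) -> list[set[str]]:
    g = nx.Graph()
    labels = list(matrix.index)
    g.add_nodes_from(labels)
    for a, b in itertools.combinations(labels, 2):
        if float(matrix.loc[a, b]) >= threshold:
            g.add_edge(a, b)
    return sorted(
        (set(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)[0]
    )


def demarcate(
    ani: pd.DataFrame,
    cpaai_matrix: pd.DataFrame | None = None,
    ani_species: tuple[float, float] = (95.0, 96.0),
    cpaai_genus: float = 86.0,
) -> DemarcationReport:
    """Threshold-based species and genus partitions.

    Species are single-linkage components at ANI >= the upper species bound;
    pairs falling inside the [lower, upper) window are flagged ambiguous.
    Genera are single-linkage components at cpAAI >= the genus threshold; a
    taxon with cpAAI above threshold to more than one (other) component is
    flagged. A species spanning two genera is an error.
    """
    labels = list(ani.index)
    if list(ani.columns) != labels:
        raise ValidationError("ANI matrix labels are not square")
    lo, hi = ani_species
    species = _single_linkage(ani, hi)
    ambiguous_pairs = [
        (a, b, float(ani.loc[a, b]))
        for a, b in itertools.combinations(labels, 2)
        if lo <= float(ani.loc[a, b]) < hi
    ]
    if cpaai_matrix is None:
        return DemarcationReport(species, [set(labels)], ambiguous_pairs, [])
    if sorted(cpaai_matrix.index) != sorted(labels):
        raise ValidationError("ANI and cpAAI matrices have different labels")
    genera = _single_linkage(cpaai_matrix, cpaai_genus)
    # flag taxa linked above threshold to >1 would-be component once removed
    ambiguous_taxa = []
    for t in labels:
        others = [x for x in labels if x != t]
        sub = cpaai_matrix.loc[others, others]
        comps = _single_linkage(sub, cpaai_genus)
        linked = {
            i
            for i, comp in enumerate(comps)
            if any(float(cpaai_matrix.loc[t, x]) >= cpaai_genus for x in comp)
        }
        if len(linked) > 1:
            ambiguous_taxa.append(t)
    for sp in species:
        spanning = [g for g in genera if g & sp]
        if len(spanning) > 1:
            raise ValidationError(
                f"species {sorted(sp)} spans multiple genera"
            )
    return DemarcationReport(species, genera, ambiguous_pairs, ambiguous_taxa)
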