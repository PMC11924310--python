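"""Convergent amino-acid substitution (CAAS) screen.

Habitat-labelled protein homolog clusters (aligned, arctic vs temperate
members from culture transcriptomes and environmental metatranscriptomes)
are scanned column by column for positions where the two habitats carry
disjoint residue sets with at least one side fixed on a single residue —
the signature of a substitution repeatedly selected in one habitat.

Candidates then pass through the screen's quality filters:

* additional-species: the substitution is not private to the focal species
  pair — both habitats must be represented beyond it at the site;
* expression: the cluster contains metatranscriptome members from both
  habitats, i.e. the variant is expressed in both native environments;
* conserved-context: the site sits in an otherwise gapless, conserved
  alignment region;
* phylogenetic independence: Fitch parsimony on the species tree shows the
  convergent residue arose on at least two independent branches.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    ConfigurationError,
    EmptyAlignmentError,
    InvalidParameterError,
    LabelingError,
)

GAP = "-"
HABITATS = ("arctic", "temperate")
#: COG-style functional-category letters for "central dogma" processes
CENTRAL_DOGMA_LETTERS = frozenset("JKL")
#: letters for metabolic functions (carbohydrate, lipid, secondary metabolism)
METABOLIC_LETTERS = frozenset("GIQ")


@dataclasses.dataclass(frozen=True)
class HabitatLabel:
    taxon: str
    habitat: str  # arctic | temperate
    source: str = "culture"  # culture | metatranscriptome
    is_focal: bool = False

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise LabelingError(f"unknown habitat {self.habitat!r} for {self.taxon}")
        if self.source not in ("culture", "metatranscriptome"):
            raise LabelingError(f"unknown source {self.source!r} for {self.taxon}")


@dataclasses.dataclass
class HomologCluster:
    """An aligned protein family with one habitat label per member."""

    cluster_id: str
    members: dict[str, str]  # taxon -> aligned sequence (gap '-')
    labels: dict[str, HabitatLabel]  # taxon -> label
    tree: dendropy.Tree | None = None
    column_map: list[int] | None = None  # trimmed column -> original column

    def __post_init__(self):
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) > 1:
            raise InvalidParameterError(
                f"cluster {self.cluster_id}: unequal sequence lengths {sorted(lengths)}"
            )
        for taxon in self.members:
            if taxon not in self.labels:
                raise LabelingError(f"cluster {self.cluster_id}: member {taxon} unlabeled")

    @property
    def length(self) -> int:
        return len(next(iter(self.members.values()))) if self.members else 0

    def taxa_by_habitat(self, habitat: str) -> list[str]:
        return [t for t in self.members if self.labels[t].habitat == habitat]


@dataclasses.dataclass(frozen=True)
class ContextCheck:
    passed: bool
    edge: bool = False  # window ran past the alignment edge
    gap_free: bool = True
    mean_other_variability: float = float("nan")


@dataclasses.dataclass
class CAASRecord:
    cluster_id: str
    column: int  # 0-based, in the coordinates of the scanned alignment
    arctic_residues: frozenset[str]
    temperate_residues: frozenset[str]
    specificity: str  # arctic | temperate | both
    carriers: dict[str, list[str]]  # residue -> taxa carrying it
    filter_flags: dict[str, bool] = dataclasses.field(default_factory=dict)
    original_column: int | None = None  # pre-trimming coordinate, if mapped

    def passes(self, which: Iterable[str]) -> bool:
        return all(self.filter_flags.get(name, False) for name in which)


@dataclasses.dataclass(frozen=True)
class CandidateSummary:
    n_candidates: int
    n_annotated: int
    by_specificity: dict[str, int]
    by_functional_group: dict[str, int]
    n_central_dogma: int
    n_metabolic: int


# ---------------------------------------------------------------------------
# clustering


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Fraction identical over the global pairwise alignment length."""
    from Bio import Align

    if aligner is None:
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-0.5,
        )
    a = seq_a.replace(GAP, "")
    b = seq_b.replace(GAP, "")
    if not a or not b:
        return 0.0
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != GAP for x, y in zip(s1, s2))
    return matches / len(s1)


def cluster_homologs(
    sequences: Mapping[str, str], identity_threshold: float = 0.75
) -> list[list[str]]:
    """Single-linkage clustering of sequences at a pairwise-identity threshold.

    Transitive: A~B and B~C at >= threshold puts A, B, C in one cluster even
    if A~C falls below it.  Returns member-ID groups, deterministic order.
    """
    if not 0 < identity_threshold <= 1:
        raise InvalidParameterError("identity_threshold must be in (0, 1]")
    ids = list(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-0.5,
    )
    for a, b in itertools.combinations(ids, 2):
        if find(a) == find(b):
            continue
        if pairwise_identity(sequences[a], sequences[b], aligner) >= identity_threshold:
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


# ---------------------------------------------------------------------------
# trimming


def column_gap_fractions(cluster: HomologCluster) -> np.ndarray:
    seqs = list(cluster.members.values())
    arr = np.array([list(s) for s in seqs])
    return (arr == GAP).mean(axis=0)


def trim_alignment(
    cluster: HomologCluster, gap_fraction_max: float = 0.5
) -> HomologCluster:
    """Remove gappy columns by a breakpoint on the gap-fraction distribution.

    The cutoff is chosen where the sorted per-column gap fractions jump most
    steeply (the largest gap in the empirical distribution), so a block of
    clean columns plus a minority of gap-riddled ones splits naturally; when
    the distribution has no usable jump, the fixed ``gap_fraction_max``
    cutoff applies.  Columns with gap fraction above the cutoff are removed
    and a trimmed->original column map is kept so positions stay reportable
    in original coordinates.
    """
    fractions = column_gap_fractions(cluster)
    uniq = np.unique(fractions)
    if uniq.size == 1:
        cutoff = gap_fraction_max if uniq[0] > gap_fraction_max else uniq[0]
    else:
        jumps = np.diff(uniq)
        j = int(np.argmax(jumps))
        cutoff = float(uniq[j]) if jumps[j] > 0 else gap_fraction_max
    keep = np.flatnonzero(fractions <= cutoff)
    if keep.size == 0:
        raise EmptyAlignmentError(f"cluster {cluster.cluster_id}: every column removed")
    base_map = cluster.column_map or list(range(cluster.length))
    return HomologCluster(
        cluster_id=cluster.cluster_id,
        members={t: "".join(s[i] for i in keep) for t, s in cluster.members.items()},
        labels=cluster.labels,
        tree=cluster.tree,
        column_map=[base_map[i] for i in keep],
    )


# ---------------------------------------------------------------------------
# scanning


def _column_residues(cluster: HomologCluster, col: int, habitat: str) -> dict[str, list[str]]:
    """residue -> carrier taxa of one habitat at one column (gaps excluded)."""
    out: dict[str, list[str]] = {}
    for taxon in cluster.taxa_by_habitat(habitat):
        res = cluster.members[taxon][col]
        if res != GAP:
            out.setdefault(res, []).append(taxon)
    return out


def classify_origin_specificity(
    arctic_set: frozenset[str] | set[str], temperate_set: frozenset[str] | set[str]
) -> str:
    """arctic / temperate / both, by which side is fixed on a single residue."""
    a, t = frozenset(arctic_set), frozenset(temperate_set)
    if not a or not t:
        raise ClassificationError("both residue sets must be nonempty")
    if a & t:
        raise ClassificationError(f"residue sets overlap: {sorted(a & t)}")
    if len(a) == 1 and len(t) == 1:
        return "both"
    if len(a) == 1:
        return "arctic"
    if len(t) == 1:
        return "temperate"
    raise ClassificationError("neither side is fixed on a single residue")


def scan_caas(cluster: HomologCluster, *, allow_gaps: bool = False) -> list[CAASRecord]:
    """Column scan for habitat-disjoint residue sets with a fixed side.

    By default only columns ungapped in every member are considered
    (conservative); with ``allow_gaps`` gapped members simply contribute no
    residue at that column.  Taxa absent from the cluster never veto a
    record — coverage varies across clusters.
    """
    if len(cluster.taxa_by_habitat("arctic")) < 2 or len(cluster.taxa_by_habitat("temperate")) < 2:
        raise LabelingError(
            f"cluster {cluster.cluster_id}: need >=2 members per habitat to scan"
        )
    records = []
    seqs = cluster.members
    for col in range(cluster.length):
        if not allow_gaps and any(s[col] == GAP for s in seqs.values()):
            continue
        arctic = _column_residues(cluster, col, "arctic")
        temperate = _column_residues(cluster, col, "temperate")
        if not arctic or not temperate:
            continue
        a_set, t_set = frozenset(arctic), frozenset(temperate)
        if a_set & t_set:
            continue
        if len(a_set) > 1 and len(t_set) > 1:
            continue
        records.append(
            CAASRecord(
                cluster_id=cluster.cluster_id,
                column=col,
                arctic_residues=a_set,
                temperate_residues=t_set,
                specificity=classify_origin_specificity(a_set, t_set),
                carriers={**arctic, **temperate},
                original_column=(cluster.column_map[col] if cluster.column_map else col),
            )
        )
    return records


def check_conserved_context(
    cluster: HomologCluster,
    column: int,
    window: int = 5,
    max_other_variability: float = 0.3,
) -> ContextCheck:
    """Is the site embedded in a gapless, conserved region?

    Every column within +/-window of the site must be gap-free in all
    members, and the mean per-column residue diversity (distinct residues /
    members) over those columns, the focal site excluded, must not exceed
    ``max_other_variability``.  A window running past the alignment edge
    fails with the edge flag set rather than raising.
    """
    if not 0 <= column < cluster.length:
        raise InvalidParameterError(f"column {column} outside alignment")
    lo, hi = column - window, column + window
    if lo < 0 or hi >= cluster.length:
        return ContextCheck(passed=False, edge=True)
    seqs = list(cluster.members.values())
    n = len(seqs)
    diversities = []
    for col in range(lo, hi + 1):
        residues = {s[col] for s in seqs}
        if GAP in residues:
            return ContextCheck(passed=False, gap_free=False)
        if col != column:
            diversities.append(len(residues) / n)
    mean_var = float(np.mean(diversities)) if diversities else 0.0
    return ContextCheck(
        passed=mean_var <= max_other_variability,
        mean_other_variability=mean_var,
    )


# ---------------------------------------------------------------------------
# filters


def filter_additional_species(record: CAASRecord, labels: Mapping[str, HabitatLabel]) -> bool:
    """Criterion: the substitution extends beyond the focal species pair.

    For each habitat side fixed on a single residue, some non-focal taxon
    must carry that residue; and the opposite habitat must also be
    represented by a non-focal taxon at this site.
    """
    if not any(lab.is_focal for lab in labels.values()):
        raise ConfigurationError("no focal species flagged in the labels")

    def non_focal_at_site(habitat: str) -> bool:
        side = (
            record.arctic_residues if habitat == "arctic" else record.temperate_residues
        )
        taxa = [t for res in side for t in record.carriers.get(res, [])]
        return any(not labels[t].is_focal for t in taxa)

    def non_focal_carrier(residues: frozenset[str]) -> bool:
        if len(residues) != 1:
            return True  # only fixed sides need a convergent non-focal carrier
        (res,) = residues
        return any(not labels[t].is_focal for t in record.carriers.get(res, []))

    return (
        non_focal_at_site("arctic")
        and non_focal_at_site("temperate")
        and non_focal_carrier(record.arctic_residues)
        and non_focal_carrier(record.temperate_residues)
    )


def filter_expression_evidence(cluster: HomologCluster) -> bool:
    """Cluster expressed in both habitats' metatranscriptome collections."""
    seen = {
        lab.habitat
        for t, lab in cluster.labels.items()
        if t in cluster.members and lab.source == "metatranscriptome"
    }
    return set(HABITATS) <= seen


def count_origins_fitch(
    tree: dendropy.Tree, tip_states: Mapping[str, str], target_residue: str
) -> int:
    """Minimum number of independent origins of ``target_residue`` on the tree.

    Tips are recoded target (1) vs other (0) and the derived residue is
    treated as irreversible: an origin is charged on every 0->1 branch, and
    once for ancestral presence at the root, while 1->0 reversals are
    disallowed.  Under that constraint the small-parsimony minimum equals
    the number of maximal clades whose tips all carry the target —
    phylogenetically separate carrier groups.  Branch lengths are ignored.
    Returns 0 when no tip carries the residue.
    """

    def tip_state(name: str) -> int:
        if name not in tip_states:
            raise InvalidParameterError(f"tip {name!r} has no character state")
        return 1 if tip_states[name] == target_residue else 0

    def visit(node) -> tuple[bool, int]:
        """(subtree is carrier-pure, origins counted among non-pure parts)."""
        if node.is_leaf():
            return bool(tip_state(node.taxon.label)), 0
        child = [visit(ch) for ch in node.child_nodes()]
        if all(pure for pure, _ in child):
            return True, 0
        # node is mixed: each carrier-pure child clade is one origin
        origins = sum(1 if pure else sub for pure, sub in child)
        return False, origins

    pure, origins = visit(tree.seed_node)
    return 1 if pure else origins


def filter_independence(
    record: CAASRecord, cluster: HomologCluster, min_origins: int = 2
) -> bool:
    """Did each fixed convergent residue arise independently >= min_origins times?"""
    if cluster.tree is None:
        raise ConfigurationError(f"cluster {cluster.cluster_id} has no species tree")
    tip_states = {t: cluster.members[t][record.column] for t in cluster.members}
    tree = _subtree_for(cluster.tree, set(tip_states))
    for residues in (record.arctic_residues, record.temperate_residues):
        if len(residues) == 1:
            (res,) = residues
            if count_origins_fitch(tree, tip_states, res) < min_origins:
                return False
    return True


def _subtree_for(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Tree:
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(sorted(taxa))
    return sub


# ---------------------------------------------------------------------------
# full screen + summary

DEFAULT_FILTERS = ("additional_species", "expression", "conserved_context", "independence")


def apply_filters(
    records: list[CAASRecord],
    cluster: HomologCluster,
    *,
    window: int = 5,
    max_other_variability: float = 0.3,
    min_origins: int = 2,
    use_independence: bool = True,
) -> list[CAASRecord]:
    """Annotate each record's filter flags in place; returns the same list."""
    expressed = filter_expression_evidence(cluster)
    for rec in records:
        rec.filter_flags["additional_species"] = filter_additional_species(
            rec, cluster.labels
        )
        rec.filter_flags["expression"] = expressed
        rec.filter_flags["conserved_context"] = check_conserved_context(
            cluster, rec.column, window=window, max_other_variability=max_other_variability
        ).passed
        if use_independence and cluster.tree is not None:
            rec.filter_flags["independence"] = filter_independence(
                rec, cluster, min_origins=min_origins
            )
        else:
            rec.filter_flags["independence"] = True
    return records


def screen_cluster(
    cluster: HomologCluster,
    *,
    trim: bool = True,
    gap_fraction_max: float = 0.5,
    filters: Sequence[str] = DEFAULT_FILTERS,
    **filter_kw,
) -> list[CAASRecord]:
    """Trim, scan, and filter one cluster; returns records passing all filters."""
    work = trim_alignment(cluster, gap_fraction_max) if trim else cluster
    records = scan_caas(work)
    apply_filters(records, work, **filter_kw)
    return [r for r in records if r.passes(filters)]


def id_level_specificity(specificities: Iterable[str]) -> str:
    """Collapse per-position calls to one call per alignment ID."""
    s = set(specificities)
    if not s:
        raise ClassificationError("no records for this ID")
    if s == {"arctic"}:
        return "arctic"
    if s == {"temperate"}:
        return "temperate"
    return "both"


def parse_functional_letters(group_field: str) -> list[str]:
    """Category letters from a functional-group string like '[J] Translation...'."""
    import re

    return re.findall(r"\[([A-Z])\]", group_field or "")


def summarize_candidates(
    records: list[CAASRecord],
    annotations: pd.DataFrame | None = None,
    *,
    id_col: str = "cluster_id",
    annotation_col: str = "functional_annotation",
    group_col: str = "functional_group",
) -> CandidateSummary:
    """ID-level tallies of the candidate set.

    An ID with several positions counts once; its specificity is the shared
    call when all positions agree and "both" otherwise.  IDs without a
    functional annotation fall under the unknown-function bucket; the
    central-dogma count covers letters J/K/L, the metabolic count G/I/Q
    (an ID with letters in both groups counts in both).
    """
    by_id: dict[str, list[str]] = {}
    for rec in records:
        by_id.setdefault(rec.cluster_id, []).append(rec.specificity)
    spec_counts = {"arctic": 0, "temperate": 0, "both": 0}
    for cid, specs in by_id.items():
        spec_counts[id_level_specificity(specs)] += 1

    ann_map: dict[str, str] = {}
    group_map: dict[str, str] = {}
    if annotations is not None:
        for _, row in annotations.iterrows():
            cid = str(row[id_col])
            ann = row.get(annotation_col)
            if isinstance(ann, str) and ann.strip() not in ("", "-", "—"):
                ann_map[cid] = ann.strip()
            grp = row.get(group_col)
            if isinstance(grp, str) and grp.strip():
                group_map[cid] = grp.strip()

    n_annotated = sum(1 for cid in by_id if cid in ann_map)
    by_group: dict[str, int] = {}
    n_central = n_metabolic = 0
    for cid in by_id:
        letters = parse_functional_letters(group_map.get(cid, ""))
        informative = [L for L in letters if L != "S"]
        if not informative or cid not in ann_map:
            by_group["S"] = by_group.get("S", 0) + 1
            continue
        for L in informative:
            by_group[L] = by_group.get(L, 0) + 1
        if set(informative) & CENTRAL_DOGMA_LETTERS:
            n_central += 1
        if set(informative) & METABOLIC_LETTERS:
            n_metabolic += 1

    return CandidateSummary(
        n_candidates=len(by_id),
        n_annotated=n_annotated,
        by_specificity=spec_counts,
        by_functional_group=by_group,
        n_central_dogma=n_central,
        n_metabolic=n_metabolic,
    )


def records_table(records: list[CAASRecord], annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Human-facing candidate table (positions 1-based in scan coordinates)."""
    ann_map = {}
    grp_map = {}
    if annotations is not None:
        for _, row in annotations.iterrows():
            cid = str(row["cluster_id"])
            ann_map[cid] = row.get("functional_annotation", "")
            grp_map[cid] = row.get("functional_group", "")
    rows = []
    for rec in records:
        rows.append(
            {
                "alignment_id": rec.cluster_id,
                "position": rec.column + 1,
                "original_position": (rec.original_column + 1
                                      if rec.original_column is not None else ""),
                "arctic_aa": ", ".join(sorted(rec.arctic_residues)),
                "temperate_aa": ", ".join(sorted(rec.temperate_residues)),
                "specificity": rec.specificity,
                "functional_annotation": ann_map.get(rec.cluster_id, ""),
                "functional_group": grp_map.get(rec.cluster_id, ""),
                **{f"filter_{k}": v for k, v in sorted(rec.filter_flags.items())},
            }
        )
    return pd.DataFrame(rows)
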