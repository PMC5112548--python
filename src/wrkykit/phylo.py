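"""Distance-based phylogeny utilities for protein families.

Covers: Poisson-corrected pairwise distances with a site-coverage
filter, neighbor joining, lineage-specific group propagation on the
resulting (unrooted) tree with overlap detection, alignment-consensus
extraction at high/low thresholds, and equal-probability discrete-gamma
rate categories for among-site rate variation.

Multiple sequence alignment itself is consumed, not computed: alignments
enter as aligned FASTA or Clustal files.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

GAP_CHARS = frozenset("-.")
UNASSIGNED = "UNASSIGNED"


class DistanceModel(Enum):
    P_DISTANCE = "p"
    POISSON = "poisson"


@dataclass
class AlignedBlock:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows have unequal lengths")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def read_alignment(path, fmt: Optional[str] = None) -> AlignedBlock:
    """Read an aligned FASTA or Clustal file into an :class:`AlignedBlock`."""
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return AlignedBlock(
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
    )


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: DistanceModel

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m


class UndefinedDistanceError(ValueError):
    """Poisson correction undefined for a saturated pair (p >= 1)."""


def site_coverage_mask(block: AlignedBlock, coverage: float = 0.95) -> np.ndarray:
    """Boolean mask of columns whose non-gap fraction is at least ``coverage``."""
    arr = np.array([list(r) for r in block.rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    return nongap.mean(axis=0) >= coverage


def pairwise_distances(
    block: AlignedBlock,
    model: DistanceModel = DistanceModel.POISSON,
    coverage: float = 0.95,
) -> DistanceMatrix:
    """Pairwise distances with partial deletion at the given site coverage.

    Columns failing the coverage filter are removed first; the p-distance
    of a pair is then mismatches over mutually ungapped retained sites.
    The Poisson correction is -ln(1 - p).
    """
    if len(block.ids) < 2:
        raise ValueError("need at least two sequences")
    arr = np.array([list(r) for r in block.rows])
    arr = arr[:, site_coverage_mask(block, coverage)]
    nongap = ~np.isin(arr, list(GAP_CHARS))
    n = len(block.ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                p = 0.0
            else:
                p = float((arr[i, both] != arr[j, both]).sum()) / compared
            if model is DistanceModel.POISSON:
                if p >= 1.0:
                    raise UndefinedDistanceError(
                        f"pair ({block.ids[i]}, {block.ids[j]}): p-distance {p} >= 1"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(ids=list(block.ids), matrix=dm, model=model)


# ---------------------------------------------------------------------------
# trees

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves are labelled nodes; internal nodes are unlabelled integers.
    """

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]  # node -> label

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def _label_to_node(self) -> dict[str, int]:
        return {lab: n for n, lab in self.leaf_labels.items()}

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (sum of branch lengths)."""
        labels = self.leaves
        node_of = self._label_to_node()
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = {node_of[lab]: 0.0}
            stack = [node_of[lab]]
            while stack:
                u = stack.pop()
                for v, w in self.adjacency[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, lab2 in enumerate(labels):
                out[i, j] = dist[node_of[lab2]]
        return labels, out

    def splits(self) -> list[tuple[frozenset[str], float]]:
        """For every edge, the leaf set on one side plus the branch length."""
        out = []
        seen = set()
        for u in self.adjacency:
            for v, w in self.adjacency[u].items():
                if (v, u) in seen or (u, v) in seen:
                    continue
                seen.add((u, v))
                side = self._leaves_beyond(v, u)
                out.append((frozenset(side), w))
        return out

    def _leaves_beyond(self, start: int, blocked: int) -> set[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        found = set()
        stack = [(start, blocked)]
        visited = {blocked, start}
        if start in self.leaf_labels:
            found.add(self.leaf_labels[start])
        while stack:
            u, came = stack.pop()
            for v in self.adjacency[u]:
                if v in visited:
                    continue
                visited.add(v)
                if v in self.leaf_labels:
                    found.add(self.leaf_labels[v])
                stack.append((v, u))
        return found

    def to_newick(self) -> str:
        # serialize rooted at an arbitrary internal node (topology-neutral)
        internal = [n for n in self.adjacency if n not in self.leaf_labels]
        root = internal[0] if internal else next(iter(self.adjacency))

        def emit(u: int, parent: Optional[int]) -> str:
            children = [v for v in self.adjacency[u] if v != parent]
            if not children:
                return self.leaf_labels[u]
            inner = ",".join(
                f"{emit(v, u)}:{self.adjacency[u][v]:.10g}" for v in children
            )
            label = self.leaf_labels.get(u, "")
            return f"({inner}){label}"

        return emit(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        adjacency: dict[int, dict[int, float]] = {}
        labels: dict[int, str] = {}
        index: dict = {}

        def nid(node) -> int:
            if node not in index:
                index[node] = len(index)
                adjacency[index[node]] = {}
            return index[node]

        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            w = edge.length if edge.length is not None else 0.0
            adjacency[u][v] = w
            adjacency[v][u] = w
        for node in dt.leaf_node_iter():
            labels[nid(node)] = node.taxon.label.replace(" ", "_")
        # drop a degree-2 artificial root if present, merging its edges
        for u in list(adjacency):
            if u not in labels and len(adjacency[u]) == 2:
                (a, wa), (b, wb) = adjacency[u].items()
                del adjacency[a][u]
                del adjacency[b][u]
                adjacency[a][b] = adjacency[b][a] = wa + wb
                del adjacency[u]
        return cls(adjacency=adjacency, leaf_labels=labels)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining.

    Ties in the Q criterion are broken by the lowest-index pair, making
    the agglomeration deterministic. Negative branch lengths are clamped
    to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = dm.matrix.astype(float).copy()
    # active nodes; node ids: 0..n-1 leaves, then new internal ids
    active = list(range(n))
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: dm.ids[i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def put(i, j, val):
        dist[(min(i, j), max(i, j))] = val

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        u = next_id
        next_id += 1
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        adjacency.setdefault(u, {})
        adjacency[u][i] = li
        adjacency[i][u] = li
        adjacency[u][j] = lj
        adjacency[j][u] = lj
        for k in active:
            if k in (i, j):
                continue
            put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    # final star resolution for the last three nodes
    a, b, c = active
    u = next_id
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    adjacency[u] = {}
    for node, length in ((a, la), (b, lb), (c, lc)):
        length = max(length, 0.0)
        adjacency.setdefault(node, {})[u] = length
        adjacency[u][node] = length
    return PhyloTree(adjacency=adjacency, leaf_labels=leaf_labels)


# ---------------------------------------------------------------------------
# group assignment

@dataclass
class GroupAssignment:
    labels: dict[str, str]  # leaf -> group label (or UNASSIGNED)
    conflicts: set[str] = field(default_factory=set)


def assign_groups(
    tree: PhyloTree, reference_labels: Mapping[str, str]
) -> GroupAssignment:
    """Propagate reference group labels to query leaves.

    Each query leaf receives the label of the smallest split side (over
    all edges of the unrooted tree) that contains the query and whose
    labelled reference members are non-empty and unanimous. Queries for
    which every such side mixes labels are UNASSIGNED and flagged as
    conflicts. The result is invariant to re-rooting because it is
    defined on splits.
    """
    if not reference_labels:
        raise ValueError("no labelled reference leaves supplied")
    leaves = set(tree.leaves)
    missing = set(reference_labels) - leaves
    if missing:
        raise ValueError(f"reference leaves not on tree: {sorted(missing)}")
    sides = [side for side, _ in tree.splits()]
    # include both orientations of every split
    all_leaves = frozenset(leaves)
    sides = sides + [all_leaves - s for s in sides]
    labels: dict[str, str] = {}
    conflicts: set[str] = set()
    for leaf in leaves:
        if leaf in reference_labels:
            labels[leaf] = reference_labels[leaf]
            continue
        best: tuple[int, str] | None = None
        for side in sides:
            if leaf not in side:
                continue
            groups = {reference_labels[x] for x in side if x in reference_labels}
            if len(groups) != 1:
                continue
            key = (len(side), next(iter(groups)))
            if best is None or key < best:
                best = key
        if best is None:
            labels[leaf] = UNASSIGNED
            conflicts.add(leaf)
        else:
            labels[leaf] = best[1]
    return GroupAssignment(labels=labels, conflicts=conflicts)


def group_overlap_report(
    assignment: GroupAssignment,
    family_numbers: Mapping[str, int],
) -> dict[int, set[str]]:
    """Per WRKY family number, the set of groups containing its members.

    Only returns families present in at least two groups (the flagged
    overlaps); an empty dict means every family is confined to one group.
    Unassigned leaves are ignored.
    """
    by_number: dict[int, set[str]] = {}
    for leaf, number in family_numbers.items():
        group = assignment.labels.get(leaf)
        if group is None or group == UNASSIGNED:
            continue
        by_number.setdefault(number, set()).add(group)
    return {num: groups for num, groups in by_number.items() if len(groups) >= 2}


# ---------------------------------------------------------------------------
# consensus

class ConsensusTier(Enum):
    HIGH = "high"
    LOW = "low"
    NONE = "none"


@dataclass
class ConsensusResult:
    symbols: list[str]  # per-column plurality symbol ("" where no residues)
    tiers: list[ConsensusTier]
    high: float
    low: float

    def motifs(self, tier: ConsensusTier = ConsensusTier.HIGH) -> list[str]:
        """Contiguous runs of columns at or above the given tier."""
        keep = {ConsensusTier.HIGH}
        if tier is ConsensusTier.LOW:
            keep.add(ConsensusTier.LOW)
        runs, current = [], []
        for sym, t in zip(self.symbols, self.tiers):
            if t in keep and sym:
                current.append(sym)
            elif current:
                runs.append("".join(current))
                current = []
        if current:
            runs.append("".join(current))
        return runs


def consensus_motif(
    block: AlignedBlock, high: float = 0.90, low: float = 0.50
) -> ConsensusResult:
    """Per-column plurality consensus with HIGH/LOW/NONE confidence tiers.

    Frequencies are computed over all rows, so a gap-rich column cannot
    reach a high tier; the gap itself is never reported as consensus
    symbol. Plurality ties go to the alphabetically first residue.
    """
    if not block.rows:
        raise ValueError("empty alignment")
    nrows = len(block.rows)
    symbols, tiers = [], []
    for col in range(block.n_sites):
        counts: dict[str, int] = {}
        for row in block.rows:
            ch = row[col]
            if ch in GAP_CHARS:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            symbols.append("")
            tiers.append(ConsensusTier.NONE)
            continue
        sym = min(counts, key=lambda c: (-counts[c], c))
        freq = counts[sym] / nrows
        if freq >= high:
            tier = ConsensusTier.HIGH
        elif freq >= low:
            tier = ConsensusTier.LOW
        else:
            tier = ConsensusTier.NONE
        symbols.append(sym)
        tiers.append(tier)
    return ConsensusResult(symbols=symbols, tiers=tiers, high=high, low=low)


# ---------------------------------------------------------------------------
# discrete gamma rates

@dataclass
class GammaRateModel:
    alpha: float
    ncat: int
    category_rates: np.ndarray


def discrete_gamma_rates(alpha: float, ncat: int = 5) -> GammaRateModel:
    """Equal-probability discrete-gamma rate categories (mean rate 1).

    Rates are drawn from a gamma distribution with shape ``alpha`` and
    mean 1 (rate parameter also ``alpha``), cut into ``ncat`` equal
    probability intervals; each category rate is the mean of the density
    over its interval, so the rates average exactly to one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if ncat < 2:
        raise ValueError("need at least two categories")
    bounds = _gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds)
    upper[0] = 0.0
    upper[-1] = 1.0
    rates = ncat * np.diff(upper)
    return GammaRateModel(alpha=float(alpha), ncat=ncat, category_rates=rates)


def fit_gamma_alpha(
    target_rates: Sequence[float], ncat: Optional[int] = None
) -> tuple[float, float]:
    """1-D search for the shape whose category rates best match a target set.

    Returns (alpha, max absolute deviation per category).
    """
    from scipy.optimize import minimize_scalar

    target = np.asarray(target_rates, dtype=float)
    k = ncat or len(target)

    def objective(log_alpha: float) -> float:
        rates = discrete_gamma_rates(math.exp(log_alpha), k).category_rates
        return float(np.max(np.abs(rates - target)))

    res = minimize_scalar(
        objective,
        bounds=(math.log(1e-2), math.log(100.0)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return math.exp(res.x), objective(res.x)
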