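"""TerL phylogeny and MRCA-based family assignment.

The classification rule is the one used for crAss-like phage taxonomy
transfer: find the most recent common ancestor (MRCA) of all reference
leaves sharing a family label on the midpoint-rooted tree, then assign that
family to every leaf descending from the MRCA. Leaves outside every labeled
MRCA stay unclassified; leaves under nested labeled MRCAs take the label of
the smallest enclosing clade.

Tree search itself is kept deliberately simple: a progressive MSA, p-distance
matrix and canonical neighbor joining stand in for a full ML pipeline - the
classification algorithm is what this module exists to exercise. Pre-built
trees can be supplied as Newick instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .records import ProteinRecord

FAMILY_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")

# ---------------------------------------------------------------------------
# progressive MSA


_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA21 = "ACDEFGHIKLMNPQRSTVWY-"
_GAP_SCORE = -4.0


def _column_score_matrix() -> np.ndarray:
    m = np.zeros((21, 21))
    for i, a in enumerate(_ALPHA21):
        for j, b in enumerate(_ALPHA21):
            if a == "-" and b == "-":
                m[i, j] = 0.0
            elif a == "-" or b == "-":
                m[i, j] = _GAP_SCORE
            else:
                m[i, j] = _B62[a][b]
    return m


_COLSCORE = _column_score_matrix()
_SYM21 = {c: i for i, c in enumerate(_ALPHA21)}


def _profile(rows: List[str]) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for r in rows:
        idx = [_SYM21.get(c, _SYM21["A"]) for c in r]
        prof[np.arange(L), idx] += 1.0
    return prof / len(rows)


def _nw_profiles(rows_a: List[str], rows_b: List[str]) \
        -> Tuple[List[str], List[str]]:
    """Global profile-profile alignment with linear gaps; returns the two
    input row sets padded to the merged alignment."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ _COLSCORE @ pb.T
    La, Lb = S.shape
    g = -_GAP_SCORE
    M = np.empty((La + 1, Lb + 1))
    M[0, :] = -g * np.arange(Lb + 1)
    M[:, 0] = -g * np.arange(La + 1)
    for i in range(1, La + 1):
        tmp = np.maximum(M[i - 1, :-1] + S[i - 1], M[i - 1, 1:] - g)
        run = np.maximum.accumulate(np.concatenate(
            ([M[i, 0] + g * 0], tmp + g * np.arange(1, Lb + 1))))
        M[i, 1:] = run[1:] - g * np.arange(1, Lb + 1)
    # traceback (diagonal preferred, then up, then left - deterministic)
    i, j = La, Lb
    ops = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(M[i, j], M[i - 1, j - 1] + S[i - 1, j - 1]):
            ops.append("D"); i -= 1; j -= 1
        elif i > 0 and np.isclose(M[i, j], M[i - 1, j] - g):
            ops.append("U"); i -= 1
        else:
            ops.append("L"); j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for r, o in zip(rows_a, out_a):
                o.append(r[ia])
            ia += 1
        else:
            for o in out_a:
                o.append("-")
        if op in ("D", "L"):
            for r, o in zip(rows_b, out_b):
                o.append(r[ib])
            ib += 1
        else:
            for o in out_b:
                o.append("-")
    return ["".join(o) for o in out_a], ["".join(o) for o in out_b]


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    sets = [set(s[i:i + k] for i in range(max(1, len(s) - k + 1)))
            for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            d[i, j] = d[j, i] = 1.0 - inter / union if union else 0.0
    return d


def progressive_msa(proteins: Sequence[ProteinRecord]) \
        -> Tuple[List[str], List[str]]:
    """Progressive multiple alignment (UPGMA k-mer guide tree, BLOSUM62
    profile-profile merges, linear gaps). Returns (ids, equal-length rows)
    in input order."""
    if len(proteins) < 2:
        raise ValueError("need at least two sequences to align")
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    seqs = [p.seq for p in proteins]
    ids = [p.id for p in proteins]
    n = len(seqs)
    d = _kmer_distance(seqs)
    Z = linkage(squareform(d, checks=False), method="average")
    # clusters[i] = (member_indices, aligned_rows)
    clusters: Dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        rows_a, rows_b = _nw_profiles(ca[1], cb[1])
        clusters[n + step] = (ca[0] + cb[0], rows_a + rows_b)
    (_, (members, rows)), = clusters.items()
    ordered = [None] * n
    for m, r in zip(members, rows):
        ordered[m] = r
    return ids, ordered


# ---------------------------------------------------------------------------
# distances and neighbor joining


def distance_matrix(rows: Sequence[str]) -> np.ndarray:
    """Pairwise p-distances over columns where neither row has a gap."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"rows {i} and {j} share no comparable positions")
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / m
    return d


def neighbor_joining(d: np.ndarray,
                     labels: Sequence[str]) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining; returns an unrooted tree.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch. Ties in the Q criterion break to the first (i, j)
    in row-major order, which is deterministic for a fixed label order.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    # node bookkeeping: newick fragments with branch lengths
    nodes = [f"{lab}" for lab in labels]
    lens: List[Optional[float]] = [None] * n
    active = list(range(n))
    D = d.copy()
    frags = {i: nodes[i] for i in range(n)}

    def clamp(li: float, lj: float) -> Tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = sub[ai, aj] / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = sub[ai, aj] - li
        li, lj = clamp(li, lj)
        new = D.shape[0]
        newrow = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, :new] = newrow
        D[:new, new] = newrow
        frags[new] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        active = [x for x in active if x not in (i, j)] + [new]
    # final three-way join
    i, j, k = active
    li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    newick = (f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g},"
              f"{frags[k]}:{lk:.10g});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return tree


# ---------------------------------------------------------------------------
# midpoint rooting


def _leaf_paths(tree: dendropy.Tree):
    leaves = tree.leaf_nodes()
    dists = {}
    for lf in leaves:
        node = lf
        dist = 0.0
        chain = []
        while node is not None:
            chain.append((node, dist))
            dist += node.edge.length or 0.0
            node = node.parent_node
        dists[lf] = dict((id(nd), (nd, dv)) for nd, dv in chain)
    return leaves, dists


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path."""
    tree = tree.clone(depth=1)
    leaves, chains = _leaf_paths(tree)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    best = None   # (dist, label_a, label_b, leaf_a, leaf_b)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            # distance via the highest shared node
            shared = set(chains[a]) & set(chains[b])
            dab = min(chains[a][s][1] + chains[b][s][1] for s in shared)
            key = tuple(sorted((a.taxon.label, b.taxon.label)))
            cand = (-dab, key, a, b)
            if best is None or cand < best:
                best = cand
    diameter = -best[0]
    a, b = best[2], best[3]
    if diameter <= 0:
        warnings.warn("all branch lengths zero; rooting at first internal "
                      "node")
        internal = next(nd for nd in tree.preorder_node_iter()
                        if not nd.is_leaf())
        tree.reroot_at_node(internal, update_bipartitions=False)
        return tree
    # walk from a toward b until the midpoint
    shared = set(chains[a]) & set(chains[b])
    mrca = min((chains[a][s][1] + chains[b][s][1], s) for s in shared)[1]
    half = diameter / 2.0
    node = a
    walked = 0.0
    while id(node) != mrca:
        elen = node.edge.length or 0.0
        if walked + elen >= half:
            # midpoint on this edge, at (half - walked) above `node`
            tree.reroot_at_edge(node.edge,
                                length1=elen - (half - walked),
                                length2=half - walked,
                                update_bipartitions=False)
            return tree
        walked += elen
        node = node.parent_node
    # midpoint lies on b's side of the mrca
    node = b
    walked_b = diameter - half
    walked = 0.0
    while id(node) != mrca:
        elen = node.edge.length or 0.0
        if walked + elen >= walked_b:
            tree.reroot_at_edge(node.edge,
                                length1=elen - (walked_b - walked),
                                length2=walked_b - walked,
                                update_bipartitions=False)
            return tree
        walked += elen
        node = node.parent_node
    tree.reroot_at_node(chains[a][mrca][0], update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# MRCA taxonomy propagation


@dataclass
class TaxonomyAssignment:
    leaf_id: str
    family: str
    assigning_mrca: Optional[str] = None


def parse_reference_labels(tree: dendropy.Tree) -> Dict[str, str]:
    """Reference families from leaf labels of the form ``id|family``."""
    refs = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if "|" in label:
            _, fam = label.rsplit("|", 1)
            refs[label] = fam
    return refs


def propagate_taxonomy(tree: dendropy.Tree,
                       reference: Optional[Dict[str, str]] = None,
                       families: Optional[Sequence[str]] = None) \
        -> List[TaxonomyAssignment]:
    """Assign every leaf the family of the smallest labeled MRCA clade it
    descends from; leaves under no labeled MRCA are unclassified."""
    tree.is_rooted = True
    if reference is None:
        reference = parse_reference_labels(tree)
    if families is None:
        families = sorted(set(reference.values()))
    by_family: Dict[str, List[str]] = {f: [] for f in families}
    for leaf_id, fam in reference.items():
        if fam in by_family:
            by_family[fam].append(leaf_id)
    label_to_leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    clades = []   # (n_leaves, family, set of leaf labels, mrca id)
    for fam in families:
        members = by_family[fam]
        if not members:
            raise ValueError(f"reference family {fam!r} has no leaves")
        taxa = [label_to_leaf[m].taxon for m in members if m in label_to_leaf]
        if len(taxa) == 1:
            mrca = label_to_leaf[members[0]]
        else:
            mrca = tree.mrca(taxa=taxa)
        under = {lf.taxon.label for lf in mrca.leaf_iter()}
        clades.append((len(under), fam, under, str(id(mrca))))
    clades.sort(key=lambda t: (t[0], t[1]))
    out = []
    for label in sorted(label_to_leaf):
        assigned = TaxonomyAssignment(leaf_id=label, family="unclassified")
        for size, fam, under, mrca_id in clades:
            if label in under:
                assigned = TaxonomyAssignment(leaf_id=label, family=fam,
                                              assigning_mrca=mrca_id)
                break
        out.append(assigned)
    return out


def classify_terl(proteins: Sequence[ProteinRecord],
                  reference: Dict[str, str]) \
        -> Tuple[dendropy.Tree, List[TaxonomyAssignment]]:
    """Full classification stage: MSA, p-distances, NJ, midpoint rooting,
    MRCA propagation. ``reference`` maps protein ids to family labels."""
    ids, rows = progressive_msa(proteins)
    d = distance_matrix(rows)
    tree = neighbor_joining(d, ids)
    rooted = midpoint_root(tree)
    assignments = propagate_taxonomy(rooted, reference)
    return rooted, assignments
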