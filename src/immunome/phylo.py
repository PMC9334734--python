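"""Distance-based phylogenetics of extracted protein domains.

Pairwise distances are maximum-likelihood estimates under the JTT empirical
amino-acid model with invariable sites and discrete-gamma rate variation
(JTT+I+Gamma); trees are built by neighbor joining (Saitou-Nei agglomeration
with the Studier-Keppler Q criterion) and internal-branch support comes from
nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .jtt import AA_INDEX, AMINO_ACIDS, JTT_FREQS, rate_matrix

logger = logging.getLogger(__name__)

_T_MIN, _T_MAX = 1e-8, 50.0


class ZeroComparableSitesError(ValueError):
    """A sequence pair shares no gap-free, unambiguous columns."""


@dataclass(frozen=True)
class RateModel:
    """JTT+I+Gamma rate model.

    ``gamma_categories`` discrete equal-probability gamma categories (each
    represented by its category mean, Yang's approximation) are combined with
    a proportion ``p_inv`` of invariable sites. Variable-category rates are
    rescaled by 1/(1 - p_inv) so the mixture's expected rate is exactly 1;
    distances therefore stay in expected substitutions per site.
    """

    gamma_categories: int = 4
    gamma_shape: float = 1.0
    p_inv: float = 0.2

    def __post_init__(self):
        if self.gamma_categories < 1:
            raise ValueError("need at least one gamma category")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")

    @cached_property
    def frequencies(self) -> np.ndarray:
        return JTT_FREQS.copy()

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible generator: symmetrize with pi^(1/2) and use eigh
        q = rate_matrix()
        d = np.sqrt(JTT_FREQS)
        sym = (q * d[:, np.newaxis]) / d[np.newaxis, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u / d[:, np.newaxis]      # D^-1 U
        right = u.T * d[np.newaxis, :]   # U^T D
        return w, left, right

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if t < 0:
            raise ValueError("negative time")
        w, left, right = self._eigen
        p = (left * np.exp(w * t)[np.newaxis, :]) @ right
        return np.clip(p, 0.0, None)

    @cached_property
    def category_rates(self) -> np.ndarray:
        """Rates of the variable-site gamma categories (scaled by 1/(1-p_inv))."""
        a = self.gamma_shape
        k = self.gamma_categories
        if k == 1:
            means = np.array([1.0])
        else:
            bounds = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
            upper = gammainc(a + 1.0, np.concatenate([bounds * a, [np.inf]]))
            lower = gammainc(a + 1.0, np.concatenate([[0.0], bounds * a]))
            means = k * (upper - lower)
        return means / (1.0 - self.p_inv)


@dataclass(frozen=True)
class Alignment:
    """Fixed-width amino-acid alignment with unique, ordered taxa."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from .io import _open_text
        from Bio import SeqIO
        taxa, seqs = [], []
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                taxa.append(rec.id)
                seqs.append(str(rec.seq).upper())
        return cls(tuple(taxa), tuple(seqs))

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        rows = tuple("".join(s[c] for c in cols) for s in self.sequences)
        return Alignment(self.taxa, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.taxa, self.sequences):
                fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    """20x20 site-pattern counts over pairwise-complete columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ia = np.array([AA_INDEX.get(c, -1) for c in seq_a])
    ib = np.array([AA_INDEX.get(c, -1) for c in seq_b])
    ok = (ia >= 0) & (ib >= 0)
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia[ok], ib[ok]), 1.0)
    return counts


def ml_distance(seq_a: str, seq_b: str, model: RateModel) -> float:
    """ML distance (expected substitutions/site) under JTT+I+Gamma.

    Sites where either sequence carries a gap or ambiguity are excluded
    (pairwise deletion). The likelihood in t is maximized by bounded scalar
    optimization on [1e-8, 50] to absolute tolerance 1e-8; hitting the upper
    bound reports the bound with a saturation warning.
    """
    counts = _pair_counts(seq_a, seq_b)
    n_sites = counts.sum()
    if n_sites == 0:
        raise ZeroComparableSitesError("no comparable sites between sequences")
    if np.trace(counts) == n_sites:
        return 0.0

    pi = model.frequencies
    rates = model.category_rates
    k = model.gamma_categories
    p_inv = model.p_inv
    inv_term = p_inv * np.diag(pi) if p_inv > 0 else 0.0

    def neg_ll(t: float) -> float:
        f = np.zeros((20, 20))
        for r in rates:
            f += model.transition_matrix(t * r)
        f = pi[:, np.newaxis] * f * ((1.0 - p_inv) / k)
        f = f + inv_term
        with np.errstate(divide="ignore"):
            logf = np.log(f)
        logf[counts == 0] = 0.0
        return -float((counts * logf).sum())

    res = minimize_scalar(neg_ll, bounds=(_T_MIN, _T_MAX), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    if t_hat > _T_MAX - 1e-4:
        logger.warning("distance optimizer hit upper bound %.1f (saturated pair)",
                       _T_MAX)
        return _T_MAX
    return t_hat


def distance_matrix(alignment: Alignment, model: RateModel) -> np.ndarray:
    """Symmetric pairwise ML distance matrix over the alignment's taxa."""
    n = len(alignment.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_distance(
                alignment.sequences[i], alignment.sequences[j], model
            )
    return d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj(taxa: Iterable[str], dm: np.ndarray) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei; Studier-Keppler Q criterion).

    Exact on additive matrices. Negative branch lengths are clamped to zero
    with the deficit transferred to the sibling branch so the pair distance
    is preserved. Ties in Q are broken by the smallest (i, j) index pair.
    """
    taxa = list(taxa)
    n = len(taxa)
    dm = np.asarray(dm, dtype=float)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")

    tns = dendropy.TaxonNamespace(taxa)
    nodes: list[dendropy.Node] = []
    for t in taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append(nd)

    size = 2 * n
    big = np.zeros((size, size))
    big[:n, :n] = dm
    active = list(range(n))
    next_idx = n

    while len(active) > 3:
        m = len(active)
        sub = big[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, np.newaxis] - r[np.newaxis, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = li
        nj_.edge.length = lj
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        for pos, a_idx in enumerate(active):
            big[next_idx, a_idx] = big[a_idx, next_idx] = new_d[pos]
        nodes.append(parent)
        del active[j], active[i]
        active.append(next_idx)
        next_idx += 1

    a, b, c = active
    dab, dac, dbc = big[a, b], big[a, c], big[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = dendropy.Node()
    for nd, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(nd)
        nd.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, Robinson-Foulds, support
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the leaf set, one canonical side each.

    Each internal branch induces a split; the side not containing the
    lexicographically smallest leaf label is stored, making the identity
    complement-invariant.
    """
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(
                *(below[id(ch)] for ch in nd.child_nodes())
            )
        if nd.parent_node is None:
            continue
        side = below[id(nd)]
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if ref in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Number of bipartitions present in exactly one of the two trees."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


@dataclass
class SupportedTree:
    """Point-estimate NJ tree with percent bootstrap supports.

    ``supports`` maps each internal bipartition of the tree to the percentage
    of completed bootstrap replicates containing it. The dendropy tree also
    carries the rounded percentages as internal node labels for Newick export.
    """

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    replicates_completed: int

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def bootstrap(alignment: Alignment, model: RateModel, B: int,
              seed: int) -> SupportedTree:
    """Column-resampling bootstrap supports for the NJ point tree.

    Replicates in which some sequence pair shares no comparable sites are
    skipped (logged); supports are normalized by completed replicates.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    point = nj(alignment.taxa, distance_matrix(alignment, model))
    point_splits = bipartitions(point)
    tally = {bp: 0 for bp in point_splits}
    rng = np.random.default_rng(seed)
    completed = 0
    for b in range(B):
        rep = alignment.resample_columns(rng)
        try:
            rep_tree = nj(rep.taxa, distance_matrix(rep, model))
        except ZeroComparableSitesError:
            logger.warning("bootstrap replicate %d skipped: zero comparable sites", b)
            continue
        completed += 1
        rep_splits = bipartitions(rep_tree)
        for bp in point_splits:
            if bp in rep_splits:
                tally[bp] += 1
    if completed == 0:
        raise ValueError("all bootstrap replicates failed")
    supports = {bp: 100.0 * c / completed for bp, c in tally.items()}

    all_leaves = leaf_labels(point)
    ref = min(all_leaves)
    below: dict[int, frozenset[str]] = {}
    for nd in point.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
            continue
        below[id(nd)] = frozenset().union(*(below[id(ch)] for ch in nd.child_nodes()))
        side = below[id(nd)]
        if ref in side:
            side = all_leaves - side
        if side in supports:
            nd.label = str(int(round(supports[side])))
    return SupportedTree(point, supports, completed)


# ---------------------------------------------------------------------------
# tree-vs-group concordance
# ---------------------------------------------------------------------------

def group_concordance(
    tree: dendropy.Tree,
    assignment: Mapping[str, str],
) -> dict[str, dict]:
    """Per-group monophyly report against an unrooted tree.

    A group is concordant when some bipartition separates exactly that group.
    Otherwise the best-covering clade (maximum F1 between a bipartition side
    and the group) is found and group members outside it reported as
    outliers. Singleton groups are trivially concordant.
    """
    leaves = leaf_labels(tree)
    missing = leaves - set(assignment)
    if missing:
        raise ValueError(f"leaves without group assignment: {sorted(missing)}")
    groups: dict[str, set[str]] = {}
    for leaf, grp in assignment.items():
        if leaf in leaves:
            groups.setdefault(grp, set()).add(leaf)

    sides: list[frozenset[str]] = []
    for bp in bipartitions(tree):
        sides.append(bp)
        sides.append(frozenset(leaves - bp))
    sides.extend(frozenset([lf]) for lf in leaves)

    report: dict[str, dict] = {}
    for grp in sorted(groups):
        members = frozenset(groups[grp])
        if len(members) < 2:
            report[grp] = {"concordant": True, "outliers": [],
                           "trivial": True, "size": len(members)}
            continue
        if any(members == s for s in sides) or members == leaves:
            report[grp] = {"concordant": True, "outliers": [],
                           "trivial": False, "size": len(members)}
            continue
        best_f1, best_side = -1.0, frozenset()
        for s in sides:
            tp = len(members & s)
            if tp == 0:
                continue
            f1 = 2.0 * tp / (len(members) + len(s))
            if f1 > best_f1 or (f1 == best_f1 and sorted(s) < sorted(best_side)):
                best_f1, best_side = f1, s
        outliers = sorted(members - best_side)
        report[grp] = {"concordant": False, "outliers": outliers,
                       "trivial": False, "size": len(members)}
    return report
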