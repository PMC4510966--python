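"""Rooted, time-calibrated phylogenies and adaptive-regime paintings.

Trees are stored in a flat array representation (parent pointers plus
branch lengths in Myr) that the likelihood machinery can vectorize over.
Ages run backward from the present: extant tips sit at age 0, fossil
tips at positive age, and the root at the tree height.  Newick text is
parsed with dendropy and converted into this representation; writing is
a direct recursive serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "RegimePainting",
    "NewickError",
    "GraftError",
    "SpecifierError",
    "read_newick",
    "write_newick",
    "graft_fossil",
    "make_hispanopithecus_trees",
    "paint_clades",
]

GHOST_LINEAGE_MYR = 1.0  # standardized ghost-lineage length for fossil grafts


class NewickError(ValueError):
    """Raised for malformed Newick input (syntax, lengths, labels)."""


class GraftError(ValueError):
    """Raised when a fossil cannot be attached to the requested lineage."""


class SpecifierError(KeyError):
    """Raised when a tip or clade specifier does not resolve."""


class PhyloTree:
    """Rooted tree with strictly positive branch lengths.

    Nodes are integer ids ``0..n_nodes-1``; the root has parent ``-1``
    and no branch length.  A *branch* is identified by its child node id.
    """

    def __init__(self, parent, blen, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = dict(labels)  # node id -> label (tips always labelled)
        self._validate()
        self._cache: dict = {}

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i == self.root:
                continue
            p = int(self.parent[i])
            if not 0 <= p < n:
                raise NewickError(f"node {i} has out-of-range parent {p}")
            if not np.isfinite(self.blen[i]) or self.blen[i] <= 0:
                raise NewickError(
                    f"branch above node {i} ({self.labels.get(i, i)!r}) must have "
                    f"a strictly positive length, got {self.blen[i]}"
                )
            children[p].append(i)
        self.children = children
        # reachability / acyclicity: walk up from every node
        for i in range(n):
            seen = set()
            j = i
            while j != self.root:
                if j in seen:
                    raise NewickError(f"cycle detected at node {j}")
                seen.add(j)
                j = int(self.parent[j])
        for i in range(n):
            # polytomies (e.g. star trees) are supported exactly by the
            # covariance machinery; unifurcations are degenerate and rejected
            if len(children[i]) == 1:
                raise NewickError(f"unifurcation at node {i}")
        tips = [i for i in range(n) if not children[i]]
        tip_labels = [self.labels.get(i, "") for i in tips]
        if any(not lab for lab in tip_labels):
            raise NewickError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        self._tips = tips

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        """Tip node ids in a stable (parse) order."""
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tips]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tip_id(self, label: str) -> int:
        for i in self._tips:
            if self.labels[i] == label:
                return i
        raise SpecifierError(f"no tip labelled {label!r}")

    def branches(self) -> list[int]:
        """All branch ids (child node ids), i.e. every node but the root."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (Myr)."""
        if "depths" not in self._cache:
            d = np.zeros(self.n_nodes)
            for i in self.preorder():
                if i != self.root:
                    d[i] = d[int(self.parent[i])] + self.blen[i]
            self._cache["depths"] = d
        return self._cache["depths"]

    @property
    def height(self) -> float:
        """Root age = maximum root-to-tip path length."""
        return float(self.depths()[self._tips].max())

    def ages(self) -> np.ndarray:
        """Node ages, backward from the present (deepest tip at age 0)."""
        return self.height - self.depths()

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.depths()[self._tips]
        return bool(np.ptp(d) <= tol * max(d.max(), 1.0))

    def preorder(self) -> list[int]:
        if "preorder" not in self._cache:
            order, stack = [], [self.root]
            while stack:
                i = stack.pop()
                order.append(i)
                stack.extend(reversed(self.children[i]))
            self._cache["preorder"] = order
        return list(self._cache["preorder"])

    def subtree_nodes(self, node: int) -> list[int]:
        """Node ids in the clade rooted at ``node`` (inclusive), preorder."""
        order, stack = [], [node]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def clade_tips(self, node: int) -> list[str]:
        return sorted(
            self.labels[i] for i in self.subtree_nodes(node) if not self.children[i]
        )

    def ancestors(self, node: int) -> list[int]:
        """Path root → ... → parent(node), excluding the node itself."""
        path = []
        i = node
        while i != self.root:
            i = int(self.parent[i])
            path.append(i)
        return path[::-1]

    def mrca(self, labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        ids = [self.tip_id(l) for l in labels]
        paths = [self.ancestors(i) + [i] for i in ids]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node
        d = self.depths()
        return max(common, key=lambda i: d[i])

    def shared_depth_matrix(self) -> np.ndarray:
        """S[i, j] = depth of MRCA(tip_i, tip_j); S[i, i] = tip depth."""
        if "shared" not in self._cache:
            n = self.n_tips
            d = self.depths()
            anc = [set(self.ancestors(t) + [t]) for t in self._tips]
            S = np.empty((n, n))
            for a in range(n):
                for b in range(a, n):
                    S[a, b] = S[b, a] = max(d[k] for k in anc[a] & anc[b])
            self._cache["shared"] = S
        return self._cache["shared"]

    def path_segments(self):
        """Flattened root-to-tip path segments, painting-independent.

        Returns (tip index, start depth, end depth, branch id) arrays
        over all tips; regime lookups can be layered on the branch ids.
        """
        if "segments" not in self._cache:
            d = self.depths()
            tip_idx, starts, ends, branch = [], [], [], []
            for k, t in enumerate(self._tips):
                path = self.ancestors(t)[1:] + [t]
                for b in path:
                    tip_idx.append(k)
                    starts.append(d[int(self.parent[b])])
                    ends.append(d[b])
                    branch.append(b)
            self._cache["segments"] = (
                np.array(tip_idx, dtype=int),
                np.array(starts),
                np.array(ends),
                np.array(branch, dtype=int),
            )
        return self._cache["segments"]

    # -- editing ---------------------------------------------------------

    def _edges(self):
        """Return (parent array copy, blen copy, labels copy) for rebuilding."""
        return self.parent.copy(), self.blen.copy(), dict(self.labels)

    def copy(self) -> "PhyloTree":
        return PhyloTree(*self._edges())

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                core = _quote(self.labels[i])
            else:
                inner = ",".join(rec(c) for c in self.children[i])
                core = f"({inner}){_quote(self.labels.get(i, ''))}"
            if i == self.root:
                return core
            return f"{core}:{self.blen[i]:.10g}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_tips} tips, height {self.height:.3g} Myr>"


def _quote(label: str) -> str:
    if label and any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths into a PhyloTree.

    Branch lengths are required on every edge except the root edge;
    internal node labels are preserved.  Zero or negative lengths and
    duplicate tip labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.full(len(nodes), np.nan)
    labels: dict[int, str] = {}
    for k, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[k] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else f"internal node {k}"
                raise NewickError(f"missing branch length above {who!r}")
            blen[k] = nd.edge.length
        lab = None
        if nd.taxon is not None:
            lab = nd.taxon.label
        elif nd.label:
            lab = nd.label
        if lab:
            labels[k] = lab
    return PhyloTree(parent, blen, labels)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def _host_branch(tree: PhyloTree, host) -> int:
    """Resolve a host-lineage specifier to a branch (child node) id.

    ``host`` is either a tip label (the branch is that tip's stem) or an
    unordered pair of tip labels (the stem of their MRCA).
    """
    if isinstance(host, str):
        node = tree.tip_id(host)
    else:
        host = list(host)
        if len(host) != 2:
            raise SpecifierError(
                "host specifier must be a tip name or a pair of tip names"
            )
        node = tree.mrca(host)
    if node == tree.root:
        raise SpecifierError("cannot attach along the root; specify a narrower clade")
    return node


def graft_fossil(
    tree: PhyloTree,
    fossil_name: str,
    fossil_age: float,
    host,
    ghost: float = GHOST_LINEAGE_MYR,
) -> PhyloTree:
    """Attach a fossil tip via a ghost lineage to a host branch.

    The fossil tip sits at ``fossil_age`` and hangs from a new internal
    node at ``fossil_age + ghost`` which must fall strictly inside the
    age span of the host branch.  All pre-existing path lengths are
    preserved.
    """
    if fossil_name in tree.tip_labels:
        raise GraftError(f"tip {fossil_name!r} already present")
    child = _host_branch(tree, host)
    ages = tree.ages()
    attach_age = fossil_age + ghost
    lo, hi = float(ages[child]), float(ages[int(tree.parent[child])])
    if not lo < attach_age < hi:
        raise GraftError(
            f"attachment age {attach_age:g} Myr outside host branch span "
            f"({lo:g}, {hi:g}) for {fossil_name!r}"
        )
    parent, blen, labels = tree._edges()
    n = len(parent)
    join, fossil = n, n + 1
    parent = np.concatenate([parent, [int(parent[child]), join]])
    blen = np.concatenate([blen, [hi - attach_age, attach_age - fossil_age]])
    parent[child] = join
    blen[child] = attach_age - lo
    labels[fossil] = fossil_name
    return PhyloTree(parent, blen, labels)


def make_hispanopithecus_trees(
    tree: PhyloTree,
    fossil_name: str = "Hispanopithecus_laietanus",
    fossil_age: float = 9.6,
    great_ape_clade=("Pongo_pygmaeus", "Homo_sapiens"),
    pongo_clade=("Pongo_abelii", "Pongo_pygmaeus"),
    hominine_clade=("Gorilla_gorilla", "Homo_sapiens"),
) -> dict[str, PhyloTree]:
    """Three alternative placements of a 9.6-Myr great-ape fossil.

    Returns trees with the fossil grafted as stem great ape, stem
    pongine and stem hominine.  Where the standard 1-Myr ghost lineage
    would land above the origin of the host stem (the great-ape stem is
    far older than the fossil), the fossil is attached at the midpoint
    of the host branch instead, with a correspondingly longer ghost
    lineage.
    """
    hosts = {
        "stem_great_ape": great_ape_clade,
        "stem_pongine": pongo_clade,
        "stem_hominine": hominine_clade,
    }
    out = {}
    for name, spec in hosts.items():
        child = _host_branch(tree, spec)
        ages = tree.ages()
        lo, hi = float(ages[child]), float(ages[int(tree.parent[child])])
        attach = fossil_age + GHOST_LINEAGE_MYR
        if not lo < attach < hi:
            if fossil_age >= hi:
                raise GraftError(
                    f"fossil age {fossil_age:g} predates the {name} lineage"
                )
            attach = 0.5 * (max(lo, fossil_age) + hi)
        out[name] = graft_fossil(
            tree, fossil_name, fossil_age, spec, ghost=attach - fossil_age
        )
    return out


@dataclass
class RegimePainting:
    """Assignment of every branch of a tree to an adaptive regime.

    ``branch_regime`` maps each branch (child node id) to a label;
    ``root_label`` is the regime the root lineage starts in.
    """

    tree: PhyloTree
    branch_regime: dict[int, str]
    root_label: str

    def __post_init__(self):
        missing = set(self.tree.branches()) - set(self.branch_regime)
        extra = set(self.branch_regime) - set(self.tree.branches())
        if missing or extra:
            raise ValueError(
                f"painting must cover every branch exactly (missing {sorted(missing)}, "
                f"extraneous {sorted(extra)})"
            )

    @property
    def labels(self) -> list[str]:
        """Ordered regime labels: root label first, then first appearance."""
        seen = [self.root_label]
        for b in sorted(self.branch_regime):
            lab = self.branch_regime[b]
            if lab not in seen:
                seen.append(lab)
        return seen

    @property
    def n_regimes(self) -> int:
        return len(self.labels)

    def relabel(self, mapping: dict[str, str]) -> "RegimePainting":
        return RegimePainting(
            self.tree,
            {b: mapping.get(l, l) for b, l in self.branch_regime.items()},
            mapping.get(self.root_label, self.root_label),
        )

    def as_table(self):
        """(child node id, parent id, regime label) rows, for CSV export."""
        return [
            (b, int(self.tree.parent[b]), self.branch_regime[b])
            for b in sorted(self.branch_regime)
        ]

    def to_dict(self) -> dict:
        return {
            "root_label": self.root_label,
            "branches": {str(b): l for b, l in self.branch_regime.items()},
        }


def uniform_painting(tree: PhyloTree, label: str = "global") -> RegimePainting:
    """Single-regime (OU1) painting."""
    return RegimePainting(tree, {b: label for b in tree.branches()}, label)


def paint_clades(tree: PhyloTree, clade_specs, root_label: str = "background") -> RegimePainting:
    """Paint crown groups with regime labels; innermost spec wins.

    ``clade_specs`` is a list of ``(label, tips)`` pairs, where ``tips``
    is a list of tip labels whose MRCA defines the clade.  The clade's
    stem branch and all branches below its MRCA receive the label (for
    a whole-tree spec there is no stem and every branch is painted).
    Distinct specs may share a label: that is how convergent regimes —
    e.g. Pan + Pongo attracted to one optimum — are expressed.
    """
    d = tree.depths()
    assignment: dict[int, tuple[float, str]] = {}
    for label, tips in clade_specs:
        node = tree.mrca(tips) if len(tips) > 1 else tree.tip_id(tips[0])
        clade_branches = [b for b in tree.subtree_nodes(node) if b != tree.root]
        depth = d[node]
        for b in clade_branches:
            prev = assignment.get(b)
            if prev is None or depth > prev[0]:  # innermost (deepest MRCA) wins
                assignment[b] = (depth, label)
    branch_regime = {
        b: assignment[b][1] if b in assignment else root_label
        for b in tree.branches()
    }
    return RegimePainting(tree, branch_regime, root_label)
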