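"""Timetrees, richness tables and their reconciliation.

Input conventions: an ultrametric rooted timetree in Newick with branch
lengths in millions of years and tips named for higher taxa (families,
orders, ...), plus a tab-separated richness table with header columns
``name`` and ``richness`` (and optionally ``source``).  Lineages known to
science but missing from the tree have their species counts folded into the
closest sampled sister tip, collapsing clades where necessary, so that every
described species is assigned to exactly one terminal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "CladeRecord",
    "CladeDataset",
    "ReconciliationReport",
    "read_timetree",
    "write_timetree",
    "stem_ages",
    "load_richness",
    "reconcile",
    "summarize",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates the timetree invariants."""


class TimeTree:
    """A rooted, binary, ultrametric tree with branch lengths in My.

    Thin wrapper around a :class:`dendropy.Tree` adding age bookkeeping
    (tips at age 0, root at age = root height) and the covariance matrices
    used by phylogenetic regression.
    """

    def __init__(self, tree: dendropy.Tree, *, validate: bool = True,
                 ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
                 require_ultrametric: bool = True,
                 allow_polytomies: bool = False) -> None:
        self._tree = tree
        self.ultrametric_tol = ultrametric_tol
        if validate:
            self._validate(require_ultrametric=require_ultrametric,
                           allow_polytomies=allow_polytomies)
        self._invalidate_cache()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "TimeTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree, **kwargs)

    def _invalidate_cache(self) -> None:
        self._depths = None
        self._root_height = None

    def _validate(self, require_ultrametric: bool,
                  allow_polytomies: bool) -> None:
        tree = self._tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeValidationError(
                    f"edge above {describe_node(edge.head_node)} has no length")
            if edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {edge.length} above "
                    f"{describe_node(edge.head_node)}")
        for node in tree.preorder_internal_node_iter():
            nchild = len(node.child_nodes())
            if nchild == 1:
                raise TreeValidationError("tree contains a unifurcation")
            if nchild > 2:
                if not allow_polytomies:
                    raise TreeValidationError(
                        "tree contains a polytomy at "
                        f"{describe_node(node)}; resolve it or pass "
                        "allow_polytomies=True to insert zero-length branches")
        if allow_polytomies:
            self._tree.resolve_polytomies(limit=2, update_bipartitions=False)
        if require_ultrametric:
            depths = self._leaf_depths()
            height = max(depths.values())
            if height <= 0:
                raise TreeValidationError("tree has zero height")
            spread = height - min(depths.values())
            if spread > self.ultrametric_tol * height:
                raise TreeValidationError(
                    f"tree is not ultrametric: tip depths span {spread:.6g} "
                    f"relative to root height {height:.6g} "
                    f"(tolerance {self.ultrametric_tol:g}); pass "
                    "require_ultrametric=False to override")

    # -- basic queries -----------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _leaf_depths(self) -> dict:
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                node._ca_depth = 0.0
            else:
                node._ca_depth = node.parent_node._ca_depth + (
                    node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._ca_depth
        return depths

    @property
    def root_height(self) -> float:
        if self._root_height is None:
            self._root_height = max(self._leaf_depths().values())
        return self._root_height

    def node_age(self, node) -> float:
        """Age (My before present) of a node; tips are at ~0."""
        if not hasattr(node, "_ca_depth"):
            self._leaf_depths()
        return self.root_height - node._ca_depth

    def stem_ages(self) -> dict[str, float]:
        """Stem age per tip: the age of the tip's parent node.

        On an ultrametric tree this equals the pendant branch length; for a
        child of the root it equals the root height.
        """
        self._leaf_depths()
        height = self.root_height
        out = {}
        for leaf in self._tree.leaf_node_iter():
            parent = leaf.parent_node
            if parent is None:
                out[leaf.taxon.label] = height
            else:
                out[leaf.taxon.label] = height - parent._ca_depth
        return out

    def vcv(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """Brownian-motion covariance: V[i, j] = depth of MRCA(i, j).

        ``order`` fixes the row/column order of tip labels (defaults to the
        tree's leaf iteration order).
        """
        if order is None:
            order = self.tip_labels
        index = {name: i for i, name in enumerate(order)}
        if len(index) != len(order):
            raise ValueError("duplicate labels in order")
        n = len(order)
        depths = self._leaf_depths()
        V = np.zeros((n, n))
        # postorder: each node carries the tip indices below it; pairs first
        # meeting at this node share its depth
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                node._ca_tips = ([index[label]] if label in index else [])
                if label in index:
                    V[index[label], index[label]] = depths[label]
                continue
            groups = [child._ca_tips for child in node.child_nodes()]
            depth = node._ca_depth
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        bb = groups[gj]
                        V[a, bb] = depth
                        V[bb, a] = depth
            node._ca_tips = [i for g in groups for i in g]
        missing = set(order) - set(depths)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        return V

    # -- editing -----------------------------------------------------------
    def clone(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1), validate=False,
                        ultrametric_tol=self.ultrametric_tol)

    def pruned_to(self, labels: Iterable[str]) -> "TimeTree":
        """A new tree restricted to ``labels`` (unifurcations suppressed)."""
        keep = set(labels)
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        tree = self._tree.extract_tree_with_taxa_labels(keep)
        return TimeTree(tree, validate=False,
                        ultrametric_tol=self.ultrametric_tol)

    # -- serialisation -----------------------------------------------------
    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".17g").strip()

    def write(self, path) -> None:
        Path(path).write_text(self.as_newick() + "\n")


def describe_node(node) -> str:
    if node.is_leaf():
        return f"tip {node.taxon.label!r}"
    tips = [leaf.taxon.label for leaf in node.leaf_iter()]
    return f"internal node above {{{', '.join(sorted(tips)[:3])}, ...}}"


def read_timetree(path, *, ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
                  require_ultrametric: bool = True,
                  allow_polytomies: bool = False) -> TimeTree:
    """Read a Newick timetree and validate the timetree invariants.

    Underscores in labels are preserved verbatim; bracketed comments
    (including NHX annotations) are stripped with a warning.
    """
    text = Path(path).read_text()
    if "[" in text:
        warnings.warn("bracketed comments in Newick input were stripped")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    return TimeTree(tree, ultrametric_tol=ultrametric_tol,
                    require_ultrametric=require_ultrametric,
                    allow_polytomies=allow_polytomies)


def write_timetree(tree: TimeTree, path) -> None:
    tree.write(path)


def stem_ages(tree: TimeTree) -> dict[str, float]:
    """Map from tip name to stem age (age of the tip's parent node)."""
    return tree.stem_ages()


@dataclass(frozen=True)
class CladeRecord:
    """One terminal clade: name, extant species count, optional stem age."""

    name: str
    richness: int
    stem_age: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.richness) != self.richness or self.richness < 1:
            raise ValueError(
                f"richness of {self.name!r} must be an integer >= 1, "
                f"got {self.richness!r}")
        object.__setattr__(self, "richness", int(self.richness))
        if self.stem_age is not None and self.stem_age <= 0:
            raise ValueError(f"stem age of {self.name!r} must be positive")


def load_richness(path) -> list[CladeRecord]:
    """Load a richness TSV (columns ``name``, ``richness``[, ``source``])."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"name", "richness"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"richness table must have columns {sorted(required)}, "
            f"found {list(df.columns)}")
    bad_rows = []
    records = []
    seen = set()
    for i, row in df.iterrows():
        name = row["name"]
        if name in seen:
            raise ValueError(f"duplicate clade name {name!r} at row {i}")
        seen.add(name)
        raw = row["richness"]
        try:
            value = float(raw)
            if not value.is_integer() or value < 1:
                raise ValueError
            richness = int(value)
        except (TypeError, ValueError):
            bad_rows.append((i, name, raw))
            continue
        source = row.get("source") if "source" in df.columns else None
        if source is not None and pd.isna(source):
            source = None
        records.append(CladeRecord(name=name, richness=richness,
                                   source=source))
    if bad_rows:
        listing = "; ".join(f"row {i} ({name!r}: {raw!r})"
                            for i, name, raw in bad_rows)
        raise ValueError(
            f"richness must be an integer >= 1 (extant clades only); "
            f"offending rows: {listing}")
    return records


@dataclass
class CladeDataset:
    """A timetree plus one richness record per tip (aligned by order)."""

    tree: TimeTree
    records: list[CladeRecord]

    def __post_init__(self) -> None:
        labels = self.tree.tip_labels
        names = [r.name for r in self.records]
        if names != labels:
            if sorted(names) == sorted(labels):
                lookup = {r.name: r for r in self.records}
                self.records = [lookup[x] for x in labels]
            else:
                raise ValueError(
                    "records and tree tips are not a bijection; "
                    f"tree-only: {sorted(set(labels) - set(names))[:5]}, "
                    f"record-only: {sorted(set(names) - set(labels))[:5]}")
        ages = self.tree.stem_ages()
        self.records = [replace(r, stem_age=ages[r.name])
                        for r in self.records]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def n_clades(self) -> int:
        return len(self.records)

    def richness_array(self) -> np.ndarray:
        return np.array([r.richness for r in self.records], dtype=np.int64)

    def stem_age_array(self) -> np.ndarray:
        return np.array([r.stem_age for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names,
            "stem_age": self.stem_age_array(),
            "richness": self.richness_array(),
        })

    def subset(self, labels: Iterable[str]) -> "CladeDataset":
        keep = set(labels)
        tree = self.tree.pruned_to(keep)
        records = [r for r in self.records if r.name in keep]
        return CladeDataset(tree=tree, records=records)


@dataclass
class ReconciliationReport:
    """Audit trail of a tree/table reconciliation."""

    merges: list = field(default_factory=list)
    pruned_without_richness: list = field(default_factory=list)
    unmatched_records: list = field(default_factory=list)
    unlocatable_missing: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @property
    def empty(self) -> bool:
        return not (self.merges or self.pruned_without_richness
                    or self.unmatched_records or self.unlocatable_missing)


def reconcile(tree: TimeTree, records: Sequence[CladeRecord],
              missing: Optional[Mapping[str, int]] = None,
              tie_break: str = "error",
              ) -> tuple[CladeDataset, ReconciliationReport]:
    """Align a timetree with a richness table.

    Tips without a richness record are pruned; if ``missing`` supplies a
    species count for such a tip, that count is added to the closest sister
    tip (smallest patristic distance) that has a record, collapsing the
    clade in the process — the surviving tip's stem age becomes the stem age
    of the merged clade.  Names (in ``records`` or ``missing``) matching no
    tip are flagged in the report rather than guessed at.

    ``tie_break``: "error" raises on equidistant sisters (e.g. the pruned
    tip's cherry partner sits in a polytomy); "alphabetical" picks the
    lexicographically smallest candidate deterministically.
    """
    if tie_break not in ("error", "alphabetical"):
        raise ValueError("tie_break must be 'error' or 'alphabetical'")
    missing = dict(missing or {})
    by_name = {r.name: r for r in records}
    tips = tree.tip_labels
    tipset = set(tips)
    matched = tipset & set(by_name)
    if not matched:
        raise ValueError("no overlap between tree tips and richness records")

    report = ReconciliationReport()
    report.unmatched_records = sorted(set(by_name) - tipset)
    report.unlocatable_missing = sorted(
        name for name in missing if name not in tipset)

    extra: dict[str, int] = {name: 0 for name in matched}
    to_prune = [t for t in tips if t not in by_name]
    if to_prune:
        pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
        for tip in to_prune:
            if tip not in missing:
                report.pruned_without_richness.append(tip)
                continue
            dists = {other: pdm.patristic_distance(taxa[tip], taxa[other])
                     for other in matched}
            dmin = min(dists.values())
            nearest = sorted(o for o, d in dists.items()
                             if abs(d - dmin) <= 1e-9 * max(dmin, 1.0))
            if len(nearest) > 1 and tie_break == "error":
                raise ValueError(
                    f"ambiguous closest sister for {tip!r}: {nearest}; "
                    "pass tie_break='alphabetical' to resolve")
            target = nearest[0]
            extra[target] += int(missing[tip])
            report.merges.append({
                "pruned": tip, "folded_into": target,
                "richness_added": int(missing[tip]),
            })
        pruned_tree = tree.pruned_to(matched)
    else:
        pruned_tree = tree

    new_records = []
    for name in pruned_tree.tip_labels:
        base = by_name[name]
        new_records.append(replace(base, richness=base.richness + extra[name]))
    dataset = CladeDataset(tree=pruned_tree, records=new_records)
    return dataset, report


def summarize(dataset: CladeDataset) -> dict:
    """Exact bookkeeping totals for a reconciled dataset."""
    ages = dataset.stem_age_array()
    return {
        "clade_count": dataset.n_clades,
        "species_total": int(dataset.richness_array().sum()),
        "age_min": float(ages.min()),
        "age_max": float(ages.max()),
    }
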