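"""Tumour clonal heterogeneity from subclone tree reconstructions.

A clone tree assigns each subclone alpha a cellular cancer fraction (CCF)
X^alpha — the fraction of tumour cells carrying that subclone's mutations —
with the pigeonhole constraint that a parent's CCF is at least the sum of
its direct descendants'.  The exclusive frequency of a subclone,

    x^alpha = X^alpha - sum_{beta in D(alpha)} X^beta,

is the fraction of cells belonging to exactly that subclone.  Tumour
heterogeneity is Shannon's entropy of the exclusive frequencies (natural
log), averaged arithmetically over the top-k trees of the ensemble ranked
by likelihood (k = 5 by default).  Tree inference itself is external; this
module consumes tree ensembles as structured input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .repertoire_io import ValidationError

__all__ = [
    "CloneTree",
    "TreeEnsemble",
    "exclusive_frequencies",
    "tree_entropy",
    "ensemble_entropy",
]

CCF_TOLERANCE = 1e-6
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class CloneTree:
    """Rooted subclone tree with per-node cellular cancer fractions.

    ``parent`` maps every non-root node to its parent; the root is the
    single node absent from the map's keys (or mapped to None).
    """

    nodes: tuple[Hashable, ...]
    parent: Mapping[Hashable, Hashable]
    ccf: Mapping[Hashable, float]
    likelihood: float = 0.0
    tree_id: str = ""

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise ValidationError("duplicate node ids")
        parent = {
            k: v for k, v in self.parent.items() if v is not None
        }
        roots = node_set - set(parent)
        if len(roots) != 1:
            raise ValidationError(
                f"tree must have exactly one root, found {sorted(map(str, roots))}"
            )
        for child, par in parent.items():
            if child not in node_set or par not in node_set:
                raise ValidationError(
                    f"edge {par}->{child} references unknown node"
                )
        # Acyclicity: walking up from every node must reach the root.
        root = next(iter(roots))
        for node in nodes:
            seen = set()
            while node != root:
                if node in seen:
                    raise ValidationError("cycle detected in tree")
                seen.add(node)
                node = parent[node]
        for node in nodes:
            x = self.ccf[node]
            if not 0.0 <= x <= 1.0 + CCF_TOLERANCE:
                raise ValidationError(
                    f"node {node}: CCF {x} outside [0, 1]"
                )
        for node in nodes:
            child_sum = sum(
                self.ccf[c] for c, p in parent.items() if p == node
            )
            if child_sum > self.ccf[node] + CCF_TOLERANCE:
                raise ValidationError(
                    f"node {node}: children's CCF sum {child_sum} exceeds "
                    f"own CCF {self.ccf[node]}"
                )
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "parent", dict(parent))
        object.__setattr__(self, "ccf", dict(self.ccf))

    @property
    def root(self) -> Hashable:
        return next(iter(set(self.nodes) - set(self.parent)))

    def children(self, node: Hashable) -> list[Hashable]:
        return [c for c, p in self.parent.items() if p == node]


@dataclass(frozen=True)
class TreeEnsemble:
    """An ordered, non-empty collection of candidate trees with likelihoods."""

    trees: tuple[CloneTree, ...]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("tree ensemble must be non-empty")
        object.__setattr__(self, "trees", tuple(self.trees))

    def __len__(self) -> int:
        return len(self.trees)

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping[str, object]]
    ) -> "TreeEnsemble":
        """Build from flat records: tree_id, likelihood, node_id, parent_id
        (empty/None for the root), ccf."""
        by_tree: dict[str, dict] = {}
        order: list[str] = []
        for rec in records:
            tid = str(rec["tree_id"])
            if tid not in by_tree:
                by_tree[tid] = {"likelihood": float(rec["likelihood"]),
                                "nodes": [], "parent": {}, "ccf": {}}
                order.append(tid)
            entry = by_tree[tid]
            node = str(rec["node_id"])
            par = rec.get("parent_id")
            if par is not None and not (
                isinstance(par, float) and math.isnan(par)
            ) and str(par) != "":
                entry["parent"][node] = str(par)
            entry["nodes"].append(node)
            entry["ccf"][node] = float(rec["ccf"])
        trees = [
            CloneTree(
                tuple(e["nodes"]), e["parent"], e["ccf"], e["likelihood"], tid
            )
            for tid, e in ((t, by_tree[t]) for t in order)
        ]
        return cls(tuple(trees))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TreeEnsemble":
        # node/parent ids stay strings; empty parent cells surface as NaN
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_records(frame.to_dict(orient="records"))

    @classmethod
    def from_json(cls, path: str | Path) -> "TreeEnsemble":
        return cls.from_records(json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for t in self.trees:
            for node in t.nodes:
                rows.append(
                    (t.tree_id, t.likelihood, node,
                     t.parent.get(node, ""), t.ccf[node])
                )
        pd.DataFrame(
            rows,
            columns=["tree_id", "likelihood", "node_id", "parent_id", "ccf"],
        ).to_csv(path, sep="\t", index=False)


def exclusive_frequencies(tree: CloneTree) -> dict[Hashable, float]:
    """x^alpha = X^alpha - sum over direct descendants of X^beta.

    Negative values within the CCF tolerance are clamped to zero; larger
    violations raise (they indicate an invalid tree).  The values sum to the
    root's CCF.
    """
    out = {}
    for node in tree.nodes:
        x = tree.ccf[node] - sum(
            tree.ccf[c] for c in tree.children(node)
        )
        if x < -CCF_TOLERANCE:
            raise ValidationError(
                f"node {node}: exclusive frequency {x} below tolerance"
            )
        out[node] = max(x, 0.0)
    return out


def tree_entropy(tree: CloneTree) -> float:
    """Shannon entropy -sum x^alpha ln x^alpha of the exclusive frequencies
    (natural log; 0 ln 0 = 0)."""
    return -sum(
        x * math.log(x)
        for x in exclusive_frequencies(tree).values()
        if x > 0.0
    )


def ensemble_entropy(
    ensemble: TreeEnsemble, top_k: int = DEFAULT_TOP_K
) -> float:
    """Arithmetic mean of tree entropies over the top_k trees by likelihood
    (all trees if the ensemble is smaller; ties at the boundary broken by
    input order)."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    ranked = sorted(
        range(len(ensemble.trees)),
        key=lambda i: (-ensemble.trees[i].likelihood, i),
    )[:top_k]
    entropies = [tree_entropy(ensemble.trees[i]) for i in ranked]
    return sum(entropies) / len(entropies)
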