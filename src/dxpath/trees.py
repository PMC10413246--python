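"""Disease trees and the temporal disease network.

Pathways surviving the final model are consolidated into a forest: triplets
sharing the first disease merge under one parent (root), shared
(first, second) prefixes merge at level 2, and the third diseases are
leaves. A person covers a node iff the root-to-node ordered path is a
strictly dated subsequence of their disease sequence; each node's dementia
probability is the case fraction of its covering persons.

Parents are ordered greedily by incremental newly-covered case count and
summarised by the cumulative covered case fraction curve; each parent keeps
its top-k children by dementia probability. Retained root→child→leaf paths
are finally aggregated into a directed temporal disease network whose edge
weights count the distinct case persons following the path; edges below the
case threshold are dropped AFTER aggregation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .features import FeatureKey, FeatureVocabulary
from .preprocessing import PersonTimeline, Triplet

logger = logging.getLogger(__name__)


@dataclass
class DiseaseTreeNode:
    """A node of a disease tree: root (level 1), child (2) or leaf (3)."""

    category: str
    level: int
    covered_cases: set[str] = field(default_factory=set)
    covered_all: set[str] = field(default_factory=set)
    children: dict[str, "DiseaseTreeNode"] = field(default_factory=dict)

    @property
    def n_cases_covered(self) -> int:
        return len(self.covered_cases)

    @property
    def n_total_covered(self) -> int:
        return len(self.covered_all)

    @property
    def dementia_probability(self) -> float:
        return self.n_cases_covered / self.n_total_covered if self.covered_all else float("nan")

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "level": self.level,
            "n_cases_covered": self.n_cases_covered,
            "n_total_covered": self.n_total_covered,
            "dementia_probability": self.dementia_probability,
            "children": [
                self.children[c].to_dict() for c in sorted(self.children)
            ],
        }


Forest = dict[str, DiseaseTreeNode]


def pathways_from_final_model(
    selected_keys: list[FeatureKey],
    vocabulary: FeatureVocabulary,
) -> set[Triplet]:
    """Screened triplets whose generated keys intersect the final selection."""
    out: set[Triplet] = set()
    for k in selected_keys:
        out.update(vocabulary.provenance.get(k, ()))
    if not out:
        logger.warning("final selection maps back to no pathways; forest will be empty")
    return out


def covers(date_of: dict[str, pd.Timestamp], path: tuple[str, ...]) -> bool:
    """True iff the ordered path is a strictly dated subsequence."""
    prev = None
    for cat in path:
        d = date_of.get(cat)
        if d is None or (prev is not None and not prev < d):
            return False
        prev = d
    return True


def build_trees(triplets: set[Triplet], timelines: list[PersonTimeline]) -> Forest:
    """Consolidate triplets into prefix-merged trees with coverage counts.

    Triplets sharing d1 merge under one root; shared (d1, d2) prefixes merge
    at level 2. Coverage sets are computed against the supplied timelines by
    strict-subsequence matching, so a child's covered sets are always
    subsets of its parent's.
    """
    forest: Forest = {}
    for d1, d2, d3 in sorted(triplets):
        root = forest.setdefault(d1, DiseaseTreeNode(d1, 1))
        child = root.children.setdefault(d2, DiseaseTreeNode(d2, 2))
        child.children.setdefault(d3, DiseaseTreeNode(d3, 3))

    paths: list[tuple[tuple[str, ...], DiseaseTreeNode]] = []
    for root in forest.values():
        paths.append(((root.category,), root))
        for child in root.children.values():
            paths.append(((root.category, child.category), child))
            for leaf in child.children.values():
                paths.append(((root.category, child.category, leaf.category), leaf))

    for tl in timelines:
        date_of = tl.date_of()
        for path, node in paths:
            if covers(date_of, path):
                node.covered_all.add(tl.person_id)
                if tl.is_case:
                    node.covered_cases.add(tl.person_id)
    return forest


def rank_children(node: DiseaseTreeNode, k: int = 5) -> DiseaseTreeNode:
    """Keep each parent's k children with the highest dementia probability.

    Ties are broken by higher covered case count, then lexicographic
    category. Applied recursively; the node is modified in place and
    returned.
    """

    def sort_key(c: DiseaseTreeNode):
        p = c.dementia_probability
        return (-(p if p == p else -1.0), -c.n_cases_covered, c.category)

    kept = sorted(node.children.values(), key=sort_key)[:k]
    node.children = {c.category: rank_children(c, k) for c in kept}
    return node


def rank_forest(forest: Forest, k: int = 5) -> Forest:
    """Apply :func:`rank_children` to every tree of the forest."""
    return {root: rank_children(node, k) for root, node in forest.items()}


@dataclass
class CoverageResult:
    """Greedy parent ordering with the cumulative covered-case curve."""

    parent_order: list[str]
    curve: list[float]  # cumulative covered case fraction after j parents
    marginal_cases: list[int]
    chosen_count: int


def cumulative_coverage(
    forest: Forest,
    case_ids: set[str] | list[str],
    epsilon: float = 0.001,
) -> CoverageResult:
    """Order parents greedily by newly covered cases; find the plateau.

    Curve point j is the fraction of all cases covered by the union of the
    first j parents' covered case sets. The chosen parent count is the
    number of parents taken before the first whose marginal gain falls
    below ``epsilon`` x (number of cases) — i.e. where the cumulative curve
    plateaus. The full curve is always returned so other cuts can be
    applied.
    """
    case_ids = set(case_ids)
    n_cases = len(case_ids)
    remaining = {root: node.covered_cases & case_ids for root, node in forest.items()}
    covered: set[str] = set()
    order: list[str] = []
    curve: list[float] = []
    marginals: list[int] = []
    while remaining:
        # max new coverage, ties toward lexicographically first root
        best = min(remaining, key=lambda r: (-len(remaining[r] - covered), r))
        gain = len(remaining[best] - covered)
        covered |= remaining.pop(best)
        order.append(best)
        marginals.append(gain)
        curve.append(len(covered) / n_cases if n_cases else float("nan"))
    chosen = len(order)
    threshold = epsilon * n_cases
    for j, gain in enumerate(marginals):
        if gain < threshold:
            chosen = j
            break
    return CoverageResult(parent_order=order, curve=curve, marginal_cases=marginals, chosen_count=chosen)


def retain_parents(forest: Forest, coverage: CoverageResult) -> Forest:
    """The forest restricted to the chosen greedy parents."""
    keep = set(coverage.parent_order[: coverage.chosen_count])
    return {root: node for root, node in forest.items() if root in keep}


def build_temporal_network(
    forest: Forest,
    min_cases: int = 50,
) -> nx.DiGraph:
    """Aggregate retained root→child→leaf pathways into a directed network.

    Each full pathway contributes its covering-case count to both of its
    edges (d1→d2 and d2→d3); weights are aggregated across pathways sharing
    an edge BEFORE the ``min_cases`` threshold is applied. Self-loops cannot
    arise because triplet categories are distinct.
    """
    weights: dict[tuple[str, str], int] = {}
    for root in forest.values():
        for child in root.children.values():
            for leaf in child.children.values():
                n = leaf.n_cases_covered  # cases following the full ordered path
                for edge in (
                    (root.category, child.category),
                    (child.category, leaf.category),
                ):
                    weights[edge] = weights.get(edge, 0) + n
    g = nx.DiGraph()
    for (u, v), w in sorted(weights.items()):
        if w >= min_cases:
            g.add_edge(u, v, weight=int(w))
    return g


def color_nodes(g: nx.DiGraph, category_class: dict[str, str] | None = None) -> nx.DiGraph:
    """Attach a category-class label to every node (for display colouring)."""
    for node in g.nodes:
        g.nodes[node]["category_class"] = (category_class or {}).get(node, "other")
    return g


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    # minimal DOT writer: node ids quoted, edge weights as labels/penwidth
    lines = ["digraph temporal_disease_network {"]
    for node in sorted(g.nodes):
        cls = g.nodes[node].get("category_class", "")
        lines.append(f'  "{node}" [category_class="{cls}"];')
    max_w = max((d["weight"] for _, _, d in g.edges(data=True)), default=1)
    for u, v, d in sorted(g.edges(data=True)):
        w = d["weight"]
        pen = 1.0 + 4.0 * w / max_w
        lines.append(f'  "{u}" -> "{v}" [weight={w}, label="{w}", penwidth={pen:.2f}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


SUPPORTED_FORMATS = ("graphml", "dot", "json", "csv")


def export_graph(obj, fmt: str, path: str | Path) -> Path:
    """Export a network (graphml/dot), forest (json) or curve (csv).

    Round-trip guarantees: GraphML re-imports with identical edges and
    weights; the JSON tree dump mirrors the in-memory node structure.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(obj, path)
    elif fmt == "dot":
        _write_dot(obj, path)
    elif fmt == "json":
        forest: Forest = obj
        payload = {root: forest[root].to_dict() for root in sorted(forest)}
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8")
    elif fmt == "csv":
        cov: CoverageResult = obj
        pd.DataFrame(
            {
                "parent": cov.parent_order,
                "marginal_cases": cov.marginal_cases,
                "cumulative_covered_fraction": cov.curve,
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {SUPPORTED_FORMATS}")
    return path


def plot_coverage_curve(coverage: CoverageResult, path: str | Path) -> Path:
    """Optional static plot of the cumulative covered case fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = range(1, len(coverage.curve) + 1)
    ax.step(xs, coverage.curve, where="post")
    if coverage.chosen_count:
        ax.axvline(coverage.chosen_count, color="red", linestyle="--", label=f"chosen = {coverage.chosen_count}")
        ax.legend()
    ax.set_xlabel("number of parent nodes")
    ax.set_ylabel("cumulative covered case fraction")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
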