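"""Modified agglomerative clustering of parameters with delta-pruning,
dendrogram export, and experiment screening.

The algorithm starts from singleton clusters (one per parameter) and
repeatedly merges the pair of clusters with the highest MI-CCA similarity,
computed over the clusters' *surviving* members.  Immediately after a merge
the delta-condition is verified inside the new cluster: while any member has
canonical correlation >= delta with the remaining members, the member with
the largest such correlation is removed (declared non-identifiable) and the
correlations are recomputed.  The linkage height of a merge is the normalised
average ``(1/m) sum (1 - rho_i^2)`` from the pre-merge CCA of the two
clusters, so perfectly compensated groups join at height 0 and orthogonal
ones at height 1.

Determinism: merge candidates are ranked by MI (capped values, arising from
rho = 1, outrank all finite ones and tie with each other), then by linkage
height ascending, then by the lexicographically smallest pair of member
indices; pruning removes one member at a time (largest rho; ties broken
toward the larger parameter index).

Parameters whose sensitivity norm fails the zeta-condition still participate
in clustering — the similarity picture is informative regardless — but are
excluded from the final identifiable set.  Linkage heights are recorded as
computed; the height functional carries no monotonicity guarantee, and
non-monotone steps are noted rather than corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cca import CcaResult, canonical_correlations, corr_with_rest, linkage_height, mutual_information
from .identifiability import delta_zeta_test, _check_thresholds
from .model import Experiment, OdeModel, SimulationError
from .sensitivity import SensitivityMatrix, build_sensitivity_matrix

__all__ = [
    "MergeRecord",
    "ClusterTree",
    "cluster_parameters",
    "export_tree",
    "ScreenEntry",
    "screen_experiments",
    "random_input_profiles",
]


@dataclass
class MergeRecord:
    """One agglomeration step."""

    step: int
    left: list[str]          # surviving members of the left cluster pre-merge
    right: list[str]
    height: float
    rhos: np.ndarray
    mi: float
    mi_capped: bool
    removed: list[str] = field(default_factory=list)  # delta-pruned at this step


@dataclass
class ClusterTree:
    """Merge history plus the final identifiability partition."""

    leaves: list[str]
    merges: list[MergeRecord]
    identifiable: list[str]
    non_identifiable: dict[str, str]  # parameter -> reason
    zeta_failed: list[str]
    delta: float
    zeta: float
    non_monotone_steps: list[int] = field(default_factory=list)

    def removed_parameters(self) -> list[str]:
        return [p for m in self.merges for p in m.removed]

    def merge_table(self) -> list[dict]:
        return [
            {
                "step": m.step,
                "left": list(m.left),
                "right": list(m.right),
                "height": m.height,
                "rhos": [float(r) for r in m.rhos],
                "mi": m.mi,
                "mi_capped": m.mi_capped,
                "removed": list(m.removed),
            }
            for m in self.merges
        ]


@dataclass
class _Cluster:
    members: list[int]       # surviving member indices, ascending
    min_index: int           # smallest index ever in the cluster (tie-break key)
    node: "_Node"


@dataclass
class _Node:
    name: str | None
    height: float
    children: tuple["_Node", "_Node"] | None
    removed_at: int | None = None  # step at which this leaf was pruned


def _pair_key(mi: float, capped: bool, height: float, a: "_Cluster", b: "_Cluster"):
    """Sort key: best merge candidate first."""
    lo, hi = sorted((a.min_index, b.min_index))
    return (-math.inf if capped else -mi, height, lo, hi)


def cluster_parameters(
    S: SensitivityMatrix,
    delta: float = 0.95,
    zeta: float = 1.0,
) -> ClusterTree:
    """Cluster parameters by MI-CCA similarity with delta-pruning.

    Returns the full merge history (heights, canonical correlations, pruned
    members per step) and the partition of parameters into identifiable and
    non-identifiable, with per-parameter reasons.
    """
    _check_thresholds(delta, zeta)
    l = S.n_params
    if l < 2:
        raise ValueError("clustering needs at least two parameters")
    names = S.param_names
    norms = S.column_norms()
    zeta_failed = [names[i] for i in range(l) if norms[i] <= zeta]

    clusters = [
        _Cluster([i], i, _Node(names[i], 0.0, None)) for i in range(l)
    ]
    merges: list[MergeRecord] = []
    removed_reason: dict[str, str] = {}
    non_monotone: list[int] = []
    step = 0
    prev_height = -np.inf

    while len(clusters) > 1:
        step += 1
        # rank all current cluster pairs by similarity
        best = None
        best_key = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                ca, cb = clusters[ai], clusters[bi]
                res = canonical_correlations(S, ca.members, cb.members)
                if np.any(np.isnan(res.rhos)):
                    raise RuntimeError(
                        f"NaN similarity between clusters "
                        f"{[names[i] for i in ca.members]} and "
                        f"{[names[i] for i in cb.members]}"
                    )
                mi = mutual_information(res)
                h = linkage_height(res)
                key = _pair_key(mi, res.capped, h, ca, cb)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (ai, bi, res, mi, h)
        ai, bi, res, mi, h = best
        ca, cb = clusters[ai], clusters[bi]
        record = MergeRecord(
            step=step,
            left=[names[i] for i in ca.members],
            right=[names[i] for i in cb.members],
            height=h,
            rhos=res.rhos.copy(),
            mi=mi,
            mi_capped=res.capped,
        )
        if h < prev_height - 1e-12:
            non_monotone.append(step)
        prev_height = h

        merged_members = sorted(ca.members + cb.members)
        pruned_leaf_nodes: dict[int, _Node] = {}

        # delta-pruning inside the merged cluster, one member at a time
        while len(merged_members) > 1:
            rhos_rest = []
            for i in merged_members:
                rest = [j for j in merged_members if j != i]
                rhos_rest.append(corr_with_rest(S, i, rest))
            worst = max(range(len(merged_members)),
                        key=lambda p: (rhos_rest[p], merged_members[p]))
            if rhos_rest[worst] < delta:
                break
            victim = merged_members.pop(worst)
            record.removed.append(names[victim])
            removed_reason[names[victim]] = f"delta-pruned at step {step}"

        merges.append(record)
        node = _Node(None, h, (ca.node, cb.node))
        _mark_removed(node, set(record.removed), step)
        new_cluster = _Cluster(merged_members, min(ca.min_index, cb.min_index), node)
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(new_cluster)

        if not merged_members:  # pragma: no cover - pruning always leaves >= 1
            raise RuntimeError("all parameters removed during pruning")

    root = clusters[0]
    survivors = [names[i] for i in root.members]
    identifiable = [p for p in survivors if p not in zeta_failed]
    non_identifiable = dict(removed_reason)
    for p in survivors:
        if p in zeta_failed:
            non_identifiable[p] = "zeta-fail"
    if not identifiable and not non_identifiable:  # pragma: no cover
        raise RuntimeError("empty clustering outcome")

    tree = ClusterTree(
        leaves=list(names),
        merges=merges,
        identifiable=identifiable,
        non_identifiable=non_identifiable,
        zeta_failed=zeta_failed,
        delta=delta,
        zeta=zeta,
        non_monotone_steps=non_monotone,
    )
    tree._root_node = root.node  # used by the Newick exporter
    return tree


def _mark_removed(node: _Node, removed: set[str], step: int) -> None:
    if node.children is None:
        if node.name in removed and node.removed_at is None:
            node.removed_at = step
        return
    for child in node.children:
        _mark_removed(child, removed, step)


# ---------------------------------------------------------------------------
# export


def _newick(node: _Node, parent_height: float) -> str:
    length = max(parent_height - node.height, 0.0)
    if node.children is None:
        tag = f"[&removed={node.removed_at}]" if node.removed_at is not None else ""
        return f"{node.name}{tag}:{length:.10g}"
    left, right = node.children
    return (
        f"({_newick(left, node.height)},{_newick(right, node.height)}):{length:.10g}"
    )


def export_tree(tree: ClusterTree, fmt: str = "newick") -> str:
    """Serialise a cluster tree.

    ``newick``: heights become branch lengths (a leaf pruned at step *s*
    carries a ``[&removed=s]`` comment tag).  ``json``: the merge table plus
    the identifiability partition, suitable for custom dendrogram plotting.
    """
    if fmt == "newick":
        root: _Node = tree._root_node
        if root.children is None:
            return f"{root.name}:0;"
        left, right = root.children
        body = f"({_newick(left, root.height)},{_newick(right, root.height)})"
        return body + ";"
    if fmt == "json":
        return json.dumps(
            {
                "schema": "micca-tree/1",
                "leaves": tree.leaves,
                "merges": tree.merge_table(),
                "identifiable": tree.identifiable,
                "non_identifiable": tree.non_identifiable,
                "zeta_failed": tree.zeta_failed,
                "delta": tree.delta,
                "zeta": tree.zeta,
                "non_monotone_steps": tree.non_monotone_steps,
            },
            indent=2,
        )
    raise ValueError(f"unknown export format {fmt!r}")


def plot_dendrogram(tree: ClusterTree, ax=None):
    """Draw the merge history as a dendrogram (pruned leaves in red).

    Convenience only; heights are drawn as recorded, including any
    non-monotone steps.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(tree.leaves) + 2, 4))

    root: _Node = tree._root_node
    x_positions: dict[int, float] = {}
    order: list[_Node] = []

    def collect(node: _Node):
        if node.children is None:
            order.append(node)
        else:
            collect(node.children[0])
            collect(node.children[1])

    collect(root)
    for k, leaf in enumerate(order):
        x_positions[id(leaf)] = float(k)

    def draw(node: _Node) -> tuple[float, float]:
        if node.children is None:
            x = x_positions[id(node)]
            return x, 0.0
        (xl, hl) = draw(node.children[0])
        (xr, hr) = draw(node.children[1])
        h = node.height
        ax.plot([xl, xl, xr, xr], [hl, h, h, hr], color="0.3", lw=1.2)
        return 0.5 * (xl + xr), h

    draw(root)
    pruned = set(tree.removed_parameters())
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([n.name for n in order], rotation=90)
    for label in ax.get_xticklabels():
        name = label.get_text()
        if name in pruned or name in tree.zeta_failed:
            label.set_color("red")
    ax.set_ylabel("linkage height  (1/m) Σ (1 − ρ²)")
    return ax


# ---------------------------------------------------------------------------
# experiment screening


@dataclass
class ScreenEntry:
    """Outcome of adding one candidate experiment to the base design."""

    index: int
    name: str
    n_identifiable: int
    gain: int
    identifiable: list[str]
    error: str | None = None


def screen_experiments(
    model: OdeModel,
    base: list[Experiment],
    candidates: list[Experiment],
    delta: float = 0.95,
    zeta: float = 1.0,
    log_scale: bool = True,
) -> list[ScreenEntry]:
    """Rank candidate experiments by identifiable-parameter count.

    For each candidate the sensitivity matrix of (base + candidate) is built
    and the global (delta, zeta) test run over all parameters.  Candidates
    whose simulation fails are skipped with the error recorded, not fatal.
    The ranking is sorted by count descending, ties broken by candidate
    index (ascending), so it is deterministic.
    """
    _check_thresholds(delta, zeta)
    S_base = build_sensitivity_matrix(model, base, log_scale=log_scale) if base else None
    base_count = 0
    if S_base is not None:
        base_count = sum(v.identifiable for v in delta_zeta_test(S_base, delta, zeta))

    entries: list[ScreenEntry] = []
    for idx, cand in enumerate(candidates):
        try:
            S = build_sensitivity_matrix(model, [*base, cand], log_scale=log_scale)
            verdicts = delta_zeta_test(S, delta, zeta)
            ident = [v.param for v in verdicts if v.identifiable]
            entries.append(
                ScreenEntry(idx, cand.name, len(ident), len(ident) - base_count, ident)
            )
        except (SimulationError, ValueError, KeyError) as exc:
            entries.append(ScreenEntry(idx, cand.name, -1, 0, [], error=str(exc)))
    ranked = sorted(
        [e for e in entries if e.error is None],
        key=lambda e: (-e.n_identifiable, e.index),
    )
    return ranked + [e for e in entries if e.error is not None]


def random_input_profiles(
    seed: int,
    n_profiles: int,
    t_grid: Sequence[float],
    amplitude_range: tuple[float, float] = (0.0, 1.0),
) -> list[Callable]:
    """Seeded piecewise-constant stimulation profiles for screening.

    Each profile holds a constant amplitude, drawn uniformly from
    ``amplitude_range``, on each interval of ``t_grid`` (and the last
    amplitude after the grid).  The grid points should be passed as the
    experiments' ``breakpoints`` so the solver restarts at the jumps.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    lo, hi = amplitude_range
    profiles = []
    for _ in range(n_profiles):
        amps = rng.uniform(lo, hi, size=t_grid.size)

        def profile(t, amps=amps, grid=t_grid):
            k = int(np.searchsorted(grid, t, side="right")) - 1
            return float(amps[np.clip(k, 0, amps.size - 1)])

        profiles.append(profile)
    return profiles
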