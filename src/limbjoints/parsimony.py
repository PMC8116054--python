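"""Parsimony mapping of the binary RLSI character on hominin phylogenies.

The RLSI is coded binary — ``high`` (ape-like, relatively large upper-limb
joints) vs ``low`` (human-like) — and mapped on alternative phylogenetic
hypotheses by unit-cost parsimony (Sankoff dynamic programming, valid on
polytomies). All most-parsimonious reconstructions (MPRs) are enumerated by
DP backtracking, and every state change on a branch is classified as a
*gain of low* (high parent, low child: independent origin of the human-like
condition) or a *reversal to high* (low parent, high child: re-evolution of
the ape-like condition from a human-like ancestor).

The ancestral (outgroup) condition is ``high``. The root prior is realised
as a virtual high-state stem ancestor above the root: a root reconstructed
as ``low`` pays for (and reports) a change on the stem branch. The question
the scenario report answers per topology: does *any* MPR explain the data
with a single origin of the human-like state and no reversals? If not, the
tree forces either homoplasy (multiple gains) or reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "Phylogeny",
    "CharacterAssignment",
    "Reconstruction",
    "ParsimonyResult",
    "parse_newick",
    "fitch_min_changes",
    "enumerate_mprs",
    "scenario_report",
]

STATES = ("high", "low")
_INF = float("inf")
MAX_INTERNAL = 25
MAX_MPRS = 100_000


def _normalize(name: str) -> str:
    return name.strip().replace(".", "").replace(" ", "_")


@dataclass
class _Node:
    id: str
    label: str | None
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Rooted tree (binary or polytomous) with uniquely labelled tips."""

    root: _Node
    label: str = ""

    def __post_init__(self) -> None:
        tips = [n.label for n in self.postorder() if n.is_leaf]
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_labels = tuple(tips)

    def postorder(self) -> Iterator[_Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.postorder() if not n.is_leaf)


def parse_newick(source: str, label: str = "") -> Phylogeny:
    """Parse a Newick string (or path contents) into a rooted phylogeny.

    Child order is preserved and polytomies are allowed; malformed input or
    duplicate tip labels raise with dendropy's diagnostic.
    """
    try:
        tree = dendropy.Tree.get(
            data=source, schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # normalise dendropy's error hierarchy
        raise ValueError(f"Newick parse error: {exc}") from exc
    counter = 0

    def convert(dnode) -> _Node:
        nonlocal counter
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        if children:
            node_id = f"node{counter}"
            counter += 1
        else:
            if not name:
                raise ValueError("unnamed tip in Newick input")
            node_id = name
        return _Node(node_id, name, children)

    return Phylogeny(convert(tree.seed_node), label=label)


@dataclass(frozen=True)
class CharacterAssignment:
    """Binary state per tip taxon; the outgroup/ancestral state is high."""

    states: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", dict(self.states))
        bad = {s for s in self.states.values() if s not in STATES}
        if bad:
            raise ValueError(f"states must be high/low, got {sorted(bad)}")

    def resolve(self, tree: Phylogeny) -> dict[str, str]:
        """Map each tip label of ``tree`` to its state (name-normalised)."""
        lookup = {_normalize(k): v for k, v in self.states.items()}
        out = {}
        missing = []
        for tip in tree.tip_labels:
            key = _normalize(tip)
            if key in lookup:
                out[tip] = lookup[key]
            else:
                missing.append(tip)
        if missing:
            raise ValueError(f"no state assigned for tips: {missing}")
        return out


def _sankoff_costs(tree: Phylogeny, tip_states: Mapping[str, str]):
    """Unit-cost Sankoff down-pass: node -> (cost_high, cost_low)."""
    costs: dict[str, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = tip_states[node.label]
            costs[node.id] = (0.0, _INF) if s == "high" else (_INF, 0.0)
        else:
            total = [0.0, 0.0]
            for child in node.children:
                ch, cl = costs[child.id]
                total[0] += min(ch, cl + 1.0)
                total[1] += min(ch + 1.0, cl)
            costs[node.id] = (total[0], total[1])
    return costs


def fitch_min_changes(
    tree: Phylogeny,
    chars: CharacterAssignment,
    root_prior: str | None = None,
) -> int:
    """Minimum number of state changes over all internal labelings.

    With ``root_prior`` set ('high'), the cost of a change on the virtual
    stem branch above the root is included.
    """
    if len(tree.tip_labels) < 2:
        raise ValueError("tree must have >= 2 tips")
    tip_states = chars.resolve(tree)
    ch, cl = _sankoff_costs(tree, tip_states)[tree.root.id]
    if root_prior is None:
        return int(min(ch, cl))
    if root_prior not in STATES:
        raise ValueError(f"invalid root prior {root_prior!r}")
    stem = (0.0, 1.0) if root_prior == "high" else (1.0, 0.0)
    return int(min(ch + stem[0], cl + stem[1]))


@dataclass(frozen=True)
class Reconstruction:
    """One MPR: state per node plus its change decomposition."""

    states: Mapping[str, str]    # node id (incl. tips) -> state
    n_changes: int
    gains_of_low: int
    reversals_to_high: int


@dataclass(frozen=True)
class ParsimonyResult:
    topology_label: str
    min_changes: int
    reconstructions: tuple[Reconstruction, ...]
    root_prior: str | None

    def __post_init__(self) -> None:
        for rec in self.reconstructions:
            if rec.n_changes != self.min_changes:
                raise ValueError("non-minimal reconstruction in result")
            if rec.gains_of_low + rec.reversals_to_high != rec.n_changes:
                raise ValueError("change decomposition does not sum")

    @property
    def n_mprs(self) -> int:
        return len(self.reconstructions)

    @property
    def min_gains(self) -> int:
        return min(r.gains_of_low for r in self.reconstructions)

    @property
    def min_reversals(self) -> int:
        return min(r.reversals_to_high for r in self.reconstructions)

    @property
    def single_origin_no_reversal(self) -> bool:
        """Does any MPR posit exactly one gain of low and zero reversals?"""
        return any(
            r.gains_of_low == 1 and r.reversals_to_high == 0
            for r in self.reconstructions
        )


def enumerate_mprs(
    tree: Phylogeny,
    chars: CharacterAssignment,
    root_prior: str | None = "high",
) -> ParsimonyResult:
    """Enumerate every most-parsimonious reconstruction.

    Backtracks through the Sankoff table: given a parent state, each child
    independently takes any state achieving min(child_cost + mismatch), so
    the cartesian product of per-node optimal choices is exactly the MPR
    set. Trees with more than 25 internal nodes are refused (use
    :func:`fitch_min_changes` for a count-only answer).
    """
    if tree.n_internal > MAX_INTERNAL:
        raise ValueError(
            f"{tree.n_internal} internal nodes > {MAX_INTERNAL}: "
            "enumeration refused, use fitch_min_changes for the count"
        )
    tip_states = chars.resolve(tree)
    costs = _sankoff_costs(tree, tip_states)

    def optimal_child_states(child_id: str, parent_state_idx: int) -> list[int]:
        ch, cl = costs[child_id]
        opts = (ch + (1.0 if parent_state_idx == 1 else 0.0),
                cl + (1.0 if parent_state_idx == 0 else 0.0))
        best = min(opts)
        return [i for i in (0, 1) if opts[i] == best]

    def expand(node: _Node, state_idx: int,
               partial: dict[str, str]) -> list[dict[str, str]]:
        partial = dict(partial)
        partial[node.id] = STATES[state_idx]
        results = [partial]
        for child in node.children:
            new_results = []
            for assignment in results:
                for ci in optimal_child_states(child.id, state_idx):
                    for sub in expand(child, ci, assignment):
                        new_results.append(sub)
                        if len(new_results) > MAX_MPRS:
                            raise RuntimeError("MPR enumeration exploded")
            results = new_results
        return results

    ch, cl = costs[tree.root.id]
    if root_prior is None:
        stem = (0.0, 0.0)
    elif root_prior == "high":
        stem = (0.0, 1.0)
    elif root_prior == "low":
        stem = (1.0, 0.0)
    else:
        raise ValueError(f"invalid root prior {root_prior!r}")
    totals = (ch + stem[0], cl + stem[1])
    min_changes = min(totals)

    assignments: list[dict[str, str]] = []
    for ri in (0, 1):
        if totals[ri] == min_changes:
            assignments.extend(expand(tree.root, ri, {}))

    recs = []
    for assignment in assignments:
        gains = reversals = 0
        if root_prior is not None and assignment[tree.root.id] != root_prior:
            if root_prior == "high":
                gains += 1
            else:
                reversals += 1
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                ps, cs = assignment[node.id], assignment[child.id]
                if ps == "high" and cs == "low":
                    gains += 1
                elif ps == "low" and cs == "high":
                    reversals += 1
                stack.append(child)
        recs.append(Reconstruction(assignment, gains + reversals,
                                   gains, reversals))
    return ParsimonyResult(tree.label, int(min_changes), tuple(recs),
                           root_prior)


def scenario_report(results: Sequence[ParsimonyResult]) -> dict:
    """Cross-topology summary of how the low state must be explained.

    For each topology: the minimum change count, the minimum number of
    gains and of reversals over MPRs, and whether any MPR achieves a single
    origin of low with zero reversals (i.e. the human-like condition could
    be homologous without reversals on that tree).
    """
    if not results:
        raise ValueError("no parsimony results to report")
    rows = []
    for res in results:
        rows.append({
            "topology": res.topology_label,
            "min_changes": res.min_changes,
            "n_mprs": res.n_mprs,
            "min_gains_of_low": res.min_gains,
            "min_reversals": res.min_reversals,
            "single_origin_no_reversal": res.single_origin_no_reversal,
        })
    lines = [
        "| topology | min changes | MPRs | min gains of low | min reversals "
        "| single origin, no reversal |",
        "|---|---|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            "| {topology} | {min_changes} | {n_mprs} | {min_gains_of_low} "
            "| {min_reversals} | {flag} |".format(
                flag="yes" if r["single_origin_no_reversal"] else "no", **r)
        )
    return {"topologies": rows, "markdown": "\n".join(lines)}
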