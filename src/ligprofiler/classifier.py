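"""Decision-tree strain typing and the minimal discriminating assay panel.

The classifier is a fixed two-stage protocol: a binary bind/no-bind
stage (AAR direct, then ThT/S5H and ThT/BTA competition) that splits the
eight reference polymorphs into five categories, followed by
quantitative stages — the OXI %BS1 class separating f65 from f110 and
K_d orderings (S5H, then AAR) separating the three patient-derived PMCA
polymorphs PD, MSA and DLB.  Profiles lacking a quantitative feature
fall back to the smallest reachable ambiguity set instead of guessing.

``minimal_assay_search`` enumerates assay subsets exhaustively in
increasing size (lexicographic in registry order) and returns the first
subset whose separations cover every fibril pair, together with a
per-assay separation certificate; minimality is proven by the
enumeration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assays import CANDIDATE_ASSAYS, DEFAULT_ASSAYS, ligands_of
from .profiles import LigandProfile

__all__ = [
    "TreeNode",
    "DecisionTree",
    "ProfileTable",
    "MinimalAssaySet",
    "reference_table",
    "reference_tree",
    "classify",
    "classify_with_path",
    "partition_binary",
    "minimal_assay_search",
    "count_ligands",
    "tree_to_dot",
]


@dataclass(frozen=True)
class TreeNode:
    feature: str
    branches: Mapping[object, "TreeNode | str"]
    assay: str = ""

    def leaves(self) -> frozenset[str]:
        out: set[str] = set()
        for child in self.branches.values():
            if isinstance(child, TreeNode):
                out |= child.leaves()
            else:
                out.add(child)
        return frozenset(out)


@dataclass(frozen=True)
class DecisionTree:
    root: TreeNode

    def labels(self) -> frozenset[str]:
        return self.root.leaves()


def reference_tree() -> DecisionTree:
    """The fixed identification protocol for the eight reference polymorphs."""
    pmca = TreeNode(
        "s5h_kd_rank",
        {
            "lowest": "PD",
            "other": TreeNode("aar_kd_rank", {"lower": "MSA", "higher": "DLB"},
                              assay="AAR-direct"),
        },
        assay="ThT/S5H",
    )
    denovo = TreeNode(
        "bta_bind",
        {
            False: "F",
            True: TreeNode("oxi_bs1_class", {"low": "f110", "high": "f65"},
                           assay="ThT/OXI"),
        },
        assay="ThT/BTA",
    )
    root = TreeNode(
        "aar_bind",
        {
            False: TreeNode("s5h_bind", {False: "R", True: "f91"}, assay="ThT/S5H"),
            True: TreeNode("s5h_bind", {True: pmca, False: denovo}, assay="ThT/S5H"),
        },
        assay="AAR-direct",
    )
    return DecisionTree(root)


def classify_with_path(
    profile: LigandProfile | Mapping[str, object], tree: DecisionTree | None = None
) -> tuple[str | frozenset[str], list[str]]:
    """Deterministic traversal; returns (label or ambiguity set, decision path)."""
    tree = tree or reference_tree()
    feats = profile.features() if isinstance(profile, LigandProfile) else dict(profile)
    node: TreeNode | str = tree.root
    path: list[str] = []
    while isinstance(node, TreeNode):
        value = feats.get(node.feature)
        if value not in node.branches:
            path.append(f"{node.feature}=? -> ambiguous {sorted(node.leaves())}")
            return node.leaves(), path
        path.append(f"{node.feature}={value}")
        node = node.branches[value]
    path.append(f"label={node}")
    return node, path


def classify(
    profile: LigandProfile | Mapping[str, object], tree: DecisionTree | None = None
) -> str | frozenset[str]:
    return classify_with_path(profile, tree)[0]


def tree_to_dot(tree: DecisionTree | None = None) -> str:
    """Graphviz DOT export of the decision tree."""
    tree = tree or reference_tree()
    lines = ["digraph decision_tree {", "  node [shape=box];"]
    counter = [0]

    def walk(node: TreeNode | str) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if isinstance(node, TreeNode):
            label = f"{node.feature}\\n[{node.assay}]" if node.assay else node.feature
            lines.append(f'  {nid} [label="{label}"];')
            for value, child in node.branches.items():
                cid = walk(child)
                lines.append(f'  {nid} -> {cid} [label="{value}"];')
        else:
            lines.append(f'  {nid} [label="{node}", shape=ellipse];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# reference profile table


@dataclass(frozen=True)
class ProfileTable:
    """Per-fibril feature table with a provenance tag for every cell.

    ``binary`` maps (fibril, assay) -> bound; ``ranks`` maps
    (fibril, assay) -> ordinal rank value; ``bs1_class`` maps fibril ->
    'low'/'high' for the ThT/OXI assay; ``sig_pairs`` records, per assay,
    the fibril pairs with a significance-backed quantitative difference.
    Pairs without recorded evidence are treated as NOT separable by that
    assay.
    """

    fibrils: tuple[str, ...]
    binary: Mapping[tuple[str, str], bool]
    ranks: Mapping[tuple[str, str], str]
    bs1_class: Mapping[str, str]
    sig_pairs: Mapping[str, frozenset[frozenset[str]]]
    provenance: Mapping[tuple[str, str, str], str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProfileTable":
        fibrils: list[str] = []
        binary: dict[tuple[str, str], bool] = {}
        ranks: dict[tuple[str, str], str] = {}
        bs1_class: dict[str, str] = {}
        sig_pairs: dict[str, set[frozenset[str]]] = {}
        provenance: dict[tuple[str, str, str], str] = {}
        for row in df.itertuples(index=False):
            fib, assay, feat, value, prov = (
                row.fibril, row.assay, row.feature, str(row.value), str(row.provenance)
            )
            if fib not in fibrils:
                fibrils.append(fib)
            provenance[(fib, assay, feat)] = prov
            if feat == "bind":
                binary[(fib, assay)] = value.lower() in ("yes", "true", "1")
            elif feat == "bs1_class":
                bs1_class[fib] = value
            elif feat == "kd_rank":
                ranks[(fib, assay)] = value
            elif feat == "kd_sig_vs":
                sig_pairs.setdefault(assay, set()).add(frozenset({fib, value}))
            else:
                raise ValueError(f"unknown feature {feat!r} in profile table")
        if len(fibrils) != len(set(fibrils)):
            raise ValueError("duplicate fibril rows")
        return cls(
            fibrils=tuple(fibrils),
            binary=binary,
            ranks=ranks,
            bs1_class=bs1_class,
            sig_pairs={a: frozenset(p) for a, p in sig_pairs.items()},
            provenance=provenance,
        )

    @classmethod
    def from_tsv(cls, path) -> "ProfileTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    def profiles(self) -> dict[str, LigandProfile]:
        """Expand the table into per-fibril classifier-ready profiles."""
        out = {}
        for fib in self.fibrils:
            bin_map = {a: v for (f, a), v in self.binary.items() if f == fib}
            ordinal: dict[str, str] = {}
            if fib in self.bs1_class:
                ordinal["oxi_bs1_class"] = self.bs1_class[fib]
            for (f, assay), rank in self.ranks.items():
                if f != fib:
                    continue
                if assay == "ThT/S5H":
                    ordinal["s5h_kd_rank"] = rank
                elif assay == "AAR-direct":
                    ordinal["aar_kd_rank"] = rank
            out[fib] = LigandProfile(fibril=fib, binary=bin_map, ordinal=ordinal)
        return out

    def separates(self, assay: str, fib_a: str, fib_b: str) -> bool:
        """True if the assay discriminates the two fibrils.

        Either the binary calls differ, or the assay carries a
        significance-backed quantitative difference (a recorded K_d pair,
        or %BS1 classes on opposite sides of the low/high split).
        """
        if assay not in DEFAULT_ASSAYS:
            raise KeyError(f"unknown assay {assay!r}")
        a = self.binary.get((fib_a, assay))
        b = self.binary.get((fib_b, assay))
        if a is not None and b is not None and a != b:
            return True
        if frozenset({fib_a, fib_b}) in self.sig_pairs.get(assay, frozenset()):
            return True
        if assay == "ThT/OXI":
            ca, cb = self.bs1_class.get(fib_a), self.bs1_class.get(fib_b)
            if ca is not None and cb is not None and ca != cb:
                return True
        return False


def reference_table() -> ProfileTable:
    """The shipped reference profile fixture for the eight polymorphs."""
    ref = resources.files("ligprofiler.data").joinpath("reference_profiles.tsv")
    with resources.as_file(ref) as path:
        return ProfileTable.from_tsv(path)


# ---------------------------------------------------------------------------
# combinatorics


def partition_binary(
    table: ProfileTable, assays: Iterable[str]
) -> list[frozenset[str]]:
    """Group fibrils by identical binary vectors over the chosen assays.

    The empty assay set yields a single group with every fibril.  Groups
    are returned sorted by (size, name) for determinism.
    """
    assays = list(assays)
    for a in assays:
        if a not in DEFAULT_ASSAYS:
            raise KeyError(f"unknown assay {a!r}")
    buckets: dict[tuple, set[str]] = {}
    for fib in table.fibrils:
        key = tuple(table.binary.get((fib, a)) for a in assays)
        buckets.setdefault(key, set()).add(fib)
    return sorted(
        (frozenset(g) for g in buckets.values()),
        key=lambda g: (len(g), sorted(g)),
    )


@dataclass(frozen=True)
class MinimalAssaySet:
    assays: tuple[str, ...]
    size: int
    feasible: bool
    certificate: Mapping[str, tuple[tuple[str, str], ...]]
    partition: tuple[frozenset[str], ...] | None = None


def _separated_pairs(table: ProfileTable, assay: str) -> set[frozenset[str]]:
    return {
        frozenset({a, b})
        for a, b in combinations(table.fibrils, 2)
        if table.separates(assay, a, b)
    }


def minimal_assay_search(
    table: ProfileTable, candidates: Sequence[str] | None = None
) -> MinimalAssaySet:
    """Exhaustive search for the smallest assay subset separating all pairs.

    Subsets are enumerated by increasing size, lexicographically in
    registry order, so the first feasible subset is a proven minimum with
    a deterministic tie-break.  If no subset is feasible the maximal
    achievable partition under all candidates is reported.
    """
    candidates = list(CANDIDATE_ASSAYS if candidates is None else candidates)
    pairs_by_assay = {a: _separated_pairs(table, a) for a in candidates}
    all_pairs = {frozenset({a, b}) for a, b in combinations(table.fibrils, 2)}

    def certificate(subset: Sequence[str]) -> dict[str, tuple[tuple[str, str], ...]]:
        return {
            a: tuple(sorted(tuple(sorted(p)) for p in pairs_by_assay[a]))
            for a in subset
        }

    for size in range(len(candidates) + 1):
        for subset in combinations(candidates, size):
            covered = set().union(*(pairs_by_assay[a] for a in subset)) if subset else set()
            if covered >= all_pairs:
                return MinimalAssaySet(
                    assays=tuple(subset),
                    size=size,
                    feasible=True,
                    certificate=certificate(subset),
                )
    # infeasible: report the finest partition all candidates achieve
    parent = {f: f for f in table.fibrils}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(table.fibrils, 2):
        if not any(frozenset({a, b}) in pairs_by_assay[c] for c in candidates):
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for f in table.fibrils:
        groups.setdefault(find(f), set()).add(f)
    partition = tuple(
        sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g))
    )
    return MinimalAssaySet(
        assays=tuple(candidates),
        size=len(candidates),
        feasible=False,
        certificate=certificate(candidates),
        partition=partition,
    )


def count_ligands(assay_ids: Iterable[str]) -> int:
    """Number of distinct ligands (reporters plus competitors) in a panel."""
    return len(ligands_of(assay_ids))
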