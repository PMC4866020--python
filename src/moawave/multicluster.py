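"""Tree-structured multi-cluster classification from recursive binary splits.

A grouping specification is a nested list of cluster labels, e.g.
``[["C1", "C3"], "C10"]``: the root separates {C1, C3} from {C10} with one
binary classifier, and each side is split further until single clusters
remain. At prediction time a sample descends from the root following the
binary decisions and receives the label of the leaf it lands in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .classifiers import SVMConfig, train_svm
from .errors import CoverageError, RangeError, ShapeError, StructureSpecError

#: fit(features, binary_labels in {0,1}, seed) -> object with .predict
NodeFactory = Callable[[np.ndarray, np.ndarray, int], object]

#: warn when one super-class at a node has fewer training samples than this
IMBALANCE_WARN_THRESHOLD = 5

StructureSpec = "str | list"  # nested lists of labels


def spec_labels(structure) -> tuple[str, ...]:
    """Leaf labels of a nested grouping spec, left-to-right."""
    if isinstance(structure, (list, tuple)):
        if len(structure) == 0:
            raise StructureSpecError("empty grouping in structure spec")
        out: list[str] = []
        for child in structure:
            out.extend(spec_labels(child))
        return tuple(out)
    return (str(structure),)


def spec_depth(structure) -> int:
    if not isinstance(structure, (list, tuple)):
        return 0
    return 1 + max(spec_depth(child) for child in structure)


def _validate_spec(structure) -> None:
    if isinstance(structure, (list, tuple)):
        if len(structure) == 1:
            # a singleton grouping is just its element
            _validate_spec(structure[0])
            return
        if len(structure) != 2:
            raise StructureSpecError(
                f"each grouping must have exactly two branches, got {len(structure)}"
            )
        for child in structure:
            _validate_spec(child)
    labels = spec_labels(structure)
    if len(set(labels)) != len(labels):
        raise StructureSpecError(f"duplicate labels in structure spec: {labels}")


@dataclass
class TreeNode:
    """Internal node: a fitted binary classifier splitting two label groups.

    Class 0 of the node classifier is the *left* group; decision ties
    therefore resolve to the group listed first in the spec.
    """

    left: "TreeNode | str"
    right: "TreeNode | str"
    left_labels: frozenset
    right_labels: frozenset
    model: object


@dataclass
class ClassificationTree:
    root: "TreeNode | str"
    labels: tuple[str, ...]
    n_features: int | None = None

    @property
    def n_internal_nodes(self) -> int:
        def count(node) -> int:
            if isinstance(node, TreeNode):
                return 1 + count(node.left) + count(node.right)
            return 0

        return count(self.root)


def _default_factory(features: np.ndarray, labels: np.ndarray, seed: int):
    return train_svm(features, labels, SVMConfig(seed=seed))


def _normalize(structure):
    # unwrap singleton groupings: ["C1"] -> "C1"
    if isinstance(structure, (list, tuple)):
        if len(structure) == 1:
            return _normalize(structure[0])
        return [_normalize(child) for child in structure]
    return str(structure)


def build_tree(
    structure,
    features: np.ndarray,
    labels: Sequence,
    factory: NodeFactory | None = None,
    seed: int = 0,
) -> ClassificationTree:
    """Fit one binary classifier per internal node of the grouping spec.

    Each node is trained only on the samples whose cluster belongs to its
    subtree, with labels collapsed to the node's two super-classes (0 for
    the left group, 1 for the right).
    """
    _validate_spec(structure)
    structure = _normalize(structure)
    factory = factory or _default_factory
    features = np.asarray(features, dtype=float)
    labels = np.asarray([str(l) for l in np.asarray(labels)])
    tree_labels = spec_labels(structure)
    present = set(labels)
    missing = [l for l in tree_labels if l not in present]
    if missing:
        raise CoverageError(f"labels in spec but absent from data: {missing}")

    counter = {"n": 0}

    def build(node_spec):
        if not isinstance(node_spec, list):
            return node_spec
        left_spec, right_spec = node_spec
        left_labels = frozenset(spec_labels(left_spec))
        right_labels = frozenset(spec_labels(right_spec))
        mask = np.isin(labels, list(left_labels | right_labels))
        binary = np.isin(labels[mask], list(right_labels)).astype(int)
        for side, count in (("left", np.sum(binary == 0)), ("right", np.sum(binary == 1))):
            if count < IMBALANCE_WARN_THRESHOLD:
                warnings.warn(
                    f"highly imbalanced node: {side} super-class has only {count} "
                    f"training samples",
                    stacklevel=2,
                )
        counter["n"] += 1
        model = factory(features[mask], binary, seed + counter["n"])
        return TreeNode(
            left=build(left_spec),
            right=build(right_spec),
            left_labels=left_labels,
            right_labels=right_labels,
            model=model,
        )

    root = build(structure)
    n_features = features.shape[1] if features.ndim == 2 else None
    return ClassificationTree(root=root, labels=tree_labels, n_features=n_features)


def tree_classify(tree: ClassificationTree, features: np.ndarray) -> np.ndarray:
    """Assign each sample the label of the leaf reached from the root."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    if single:
        features = features.reshape(1, -1)
    if tree.n_features is not None and features.shape[1] != tree.n_features:
        raise ShapeError(
            f"feature dimensionality {features.shape[1]} != training dimensionality "
            f"{tree.n_features}"
        )

    out = np.empty(features.shape[0], dtype=object)

    def descend(node, indices: np.ndarray) -> None:
        if not isinstance(node, TreeNode):
            out[indices] = node
            return
        decisions = np.asarray(node.model.predict(features[indices]))
        descend(node.left, indices[decisions == 0])
        descend(node.right, indices[decisions == 1])

    descend(tree.root, np.arange(features.shape[0]))
    out = out.astype(str)
    return out[0] if single else out


def enumerate_structures(labels: Sequence[str], max_depth: int | None = None, family: str = "all"):
    """All distinct full binary nestings of a small label set.

    Trees are deduplicated up to child order (``[A, B]`` equals ``[B, A]``);
    the returned specs are canonically ordered. ``max_depth`` filters by
    nesting depth. ``family="one_vs_rest"`` instead returns one spec per
    label: that label against a balanced canonical nesting of the rest.
    """
    labels = [str(l) for l in labels]
    if not 2 <= len(labels) <= 5:
        raise RangeError(f"structure enumeration supports 2..5 labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise StructureSpecError("labels must be unique")

    if family == "one_vs_rest":
        out = []
        for label in labels:
            rest = [l for l in labels if l != label]
            out.append([label, _balanced(rest)])
        return out
    if family != "all":
        raise RangeError(f"unknown family: {family!r}")

    def nestings(items: tuple[str, ...]):
        if len(items) == 1:
            yield items[0]
            return
        first, rest = items[0], items[1:]
        # enumerate subsets of rest joining `first` on the left side
        for bits in range(2 ** len(rest)):
            left = [first] + [rest[i] for i in range(len(rest)) if bits >> i & 1]
            right = [rest[i] for i in range(len(rest)) if not bits >> i & 1]
            if not right:
                continue
            for l_tree in nestings(tuple(left)):
                for r_tree in nestings(tuple(right)):
                    yield [l_tree, r_tree]

    seen = set()
    out = []
    for tree in nestings(tuple(labels)):
        key = _canonical_key(tree)
        if key in seen:
            continue
        seen.add(key)
        if max_depth is None or spec_depth(tree) <= max_depth:
            out.append(tree)
    return out


def _balanced(labels: list[str]):
    if len(labels) == 1:
        return labels[0]
    mid = (len(labels) + 1) // 2
    return [_balanced(labels[:mid]), _balanced(labels[mid:])]


def _canonical_key(structure):
    if not isinstance(structure, list):
        return structure
    keys = sorted((repr(_canonical_key(child)) for child in structure))
    return tuple(keys)
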