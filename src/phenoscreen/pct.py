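"""Multi-target predictive clustering trees (PCTs) and bagging ensembles.

A PCT is a binary decision tree over fingerprint bits that minimises the
within-leaf variance of a *vector* of targets — here the two phenotypic
readouts of the fibrosis screen, RFP (αSMA promoter activity) and EGFP
(collagen promoter activity), both as fold-over-control intensities.
Leaves predict the per-target mean (the cluster prototype).

A bagging ensemble grows one tree per bootstrap resample of the training
set; the ensemble prediction is the per-target mean over trees, and the
per-target *population standard deviation* of the individual-tree
predictions serves as a per-prediction reliability score (trees that
disagree flag an unreliable prediction).

Target variances are normalised by the full-training-set standard
deviation of each target so that RFP and EGFP contribute comparably to
the split criterion.  All variances are population (1/n) variances,
which keeps the split search exactly reproducible by brute-force oracles.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .chem import Fingerprint

N_TARGETS = 2  # (rfp, egfp)
_CONST_TOL = 1e-12


@dataclass(frozen=True)
class ScreenRecord:
    """One row of a screen: compound, fingerprint, two fold intensities."""

    id: str
    fingerprint: Fingerprint
    rfp: float
    egfp: float

    def __post_init__(self) -> None:
        if self.rfp < 0 or self.egfp < 0:
            raise ValueError("fold-over-control intensities must be >= 0")


class TrainingSet:
    """A list of :class:`ScreenRecord` plus per-target normalisation scales.

    ``target_scale`` is the population standard deviation of each target
    over the full set; a zero-variance target falls back to scale 1.0
    (with a warning) so the split criterion stays defined.
    """

    def __init__(self, records: Sequence[ScreenRecord]):
        if len(records) < 2:
            raise ValueError("a training set needs at least 2 records")
        nbits = records[0].fingerprint.nbits
        if any(r.fingerprint.nbits != nbits for r in records):
            raise ValueError("all fingerprints must share nbits")
        self.records: list[ScreenRecord] = list(records)
        self.nbits = nbits
        y = self.targets()
        scale = y.std(axis=0)  # population sd
        degenerate = scale <= 0.0
        if degenerate.any():
            warnings.warn(
                "zero-variance target(s) %s; falling back to scale 1.0"
                % np.flatnonzero(degenerate).tolist()
            )
            scale = np.where(degenerate, 1.0, scale)
        self.target_scale: np.ndarray = scale

    def __len__(self) -> int:
        return len(self.records)

    def targets(self) -> np.ndarray:
        """(n, 2) array of (rfp, egfp) targets."""
        return np.array([(r.rfp, r.egfp) for r in self.records], dtype=float)

    def feature_matrix(self) -> np.ndarray:
        """(n, nbits) float matrix of fingerprint bits."""
        return fingerprints_to_matrix(
            [r.fingerprint for r in self.records], self.nbits
        )


def fingerprints_to_matrix(
    fps: Sequence[Fingerprint], nbits: int
) -> np.ndarray:
    X = np.zeros((len(fps), nbits), dtype=float)
    for i, fp in enumerate(fps):
        if fp.nbits != nbits:
            raise ValueError(f"fingerprint nbits {fp.nbits} != {nbits}")
        X[i, list(fp.bits)] = 1.0
    return X


@dataclass(frozen=True)
class TreeParams:
    """Tree/ensemble hyperparameters (the conventional bagging defaults)."""

    min_leaf: int = 5
    max_depth: Optional[int] = None
    n_trees: int = 100
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")


@dataclass(frozen=True)
class Leaf:
    prototype: tuple[float, float]  # (mean rfp, mean egfp)
    count: int


@dataclass(frozen=True)
class Split:
    bit: int
    reduction: float  # normalised variance reduction achieved
    zero: "Node"  # branch for bit absent
    one: "Node"  # branch for bit present


Node = Union[Leaf, Split]


@dataclass(frozen=True)
class PCTree:
    root: Node
    nbits: int

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []
        stack: list[Node] = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, Leaf):
                out.append(node)
            else:
                stack.extend((node.zero, node.one))
        return out

    def splits(self) -> list[Split]:
        out: list[Split] = []
        stack: list[Node] = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, Split):
                out.append(node)
                stack.extend((node.zero, node.one))
        return out


@dataclass(frozen=True)
class Prediction:
    """Ensemble prediction with per-target reliability (tree-sd) scores."""

    rfp_mean: float
    egfp_mean: float
    rfp_sd: float
    egfp_sd: float

    def sd_for(self, target: str) -> float:
        if target == "rfp":
            return self.rfp_sd
        if target == "egfp":
            return self.egfp_sd
        raise ValueError(f"unknown target {target!r}")


# ---------------------------------------------------------------------------
# split criterion


def _as_scale(scale) -> np.ndarray:
    s = np.asarray(scale, dtype=float)
    if s.shape != (N_TARGETS,):
        raise ValueError("scale must have one component per target")
    if (s <= 0).any():
        raise ValueError("scale components must be > 0")
    return s


def target_variance(records: Sequence[ScreenRecord], scale) -> float:
    """Summed scale-normalised population variance of the two targets."""
    if len(records) == 0:
        raise ValueError("empty record set")
    s = _as_scale(scale)
    y = np.array([(r.rfp, r.egfp) for r in records], dtype=float)
    return float((y.var(axis=0) / s**2).sum())


def evaluate_split(
    records: Sequence[ScreenRecord],
    bit: int,
    scale,
    min_leaf: int = 1,
) -> float:
    """Variance reduction of splitting ``records`` on a fingerprint bit.

    Returns ``-inf`` when either branch is empty or smaller than
    ``min_leaf``.  This is the definitional (per-bit) computation; the
    tree grower uses an algebraically identical vectorised search.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    nbits = records[0].fingerprint.nbits
    if not (0 <= bit < nbits):
        raise ValueError(f"bit index {bit} out of range [0, {nbits})")
    ones = [r for r in records if bit in r.fingerprint.bits]
    zeros = [r for r in records if bit not in r.fingerprint.bits]
    if len(ones) < min_leaf or len(zeros) < min_leaf:
        return -math.inf
    n = len(records)
    total = target_variance(records, scale)
    cost = (len(zeros) / n) * target_variance(zeros, scale) + (
        len(ones) / n
    ) * target_variance(ones, scale)
    return total - cost


def _best_split_arrays(
    X: np.ndarray,
    Y: np.ndarray,
    idx: np.ndarray,
    scale: np.ndarray,
    min_leaf: int,
) -> Optional[tuple[int, float]]:
    """Vectorised argmax of variance reduction over all bits.

    Ties resolve to the lowest bit index (``argmax`` returns the first
    maximum; identical feature columns produce bitwise-identical scores).
    """
    ys = Y[idx]
    xs = X[idx]
    n = idx.size
    w = np.empty((2 * N_TARGETS + 1, n))
    w[:N_TARGETS] = ys.T
    w[N_TARGETS : 2 * N_TARGETS] = (ys**2).T
    w[-1] = 1.0
    m = w @ xs  # (5, nbits)
    s1 = m[:N_TARGETS]
    q1 = m[N_TARGETS : 2 * N_TARGETS]
    n1 = m[-1]
    n0 = n - n1
    s_tot = ys.sum(axis=0)
    q_tot = (ys**2).sum(axis=0)
    s0 = s_tot[:, None] - s1
    q0 = q_tot[:, None] - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        sse1 = q1 - s1**2 / n1
        sse0 = q0 - s0**2 / n0
        cost = ((sse1 + sse0) / scale[:, None] ** 2).sum(axis=0) / n
    total = float(((q_tot - s_tot**2 / n) / scale**2).sum() / n)
    reduction = total - cost
    admissible = (n1 >= min_leaf) & (n0 >= min_leaf)
    if not admissible.any():
        return None
    reduction = np.where(admissible, reduction, -np.inf)
    best_val = float(reduction.max())
    # ties (including float-noise ties between mathematically equal
    # reductions) resolve to the lowest bit index
    tol = 1e-12 * max(1.0, abs(best_val))
    bit = int(np.flatnonzero(reduction >= best_val - tol)[0])
    return bit, max(float(reduction[bit]), 0.0)


def best_split(
    records: Sequence[ScreenRecord],
    scale,
    min_leaf: int = 1,
) -> Optional[tuple[int, float]]:
    """Best (bit, variance reduction) over all bits, or None if no bit
    yields two branches of at least ``min_leaf`` records each."""
    s = _as_scale(scale)
    nbits = records[0].fingerprint.nbits
    X = fingerprints_to_matrix([r.fingerprint for r in records], nbits)
    Y = np.array([(r.rfp, r.egfp) for r in records], dtype=float)
    return _best_split_arrays(X, Y, np.arange(len(records)), s, min_leaf)


# ---------------------------------------------------------------------------
# tree induction


def _grow(
    X: np.ndarray,
    Y: np.ndarray,
    idx: np.ndarray,
    scale: np.ndarray,
    params: TreeParams,
    depth: int,
) -> Node:
    ys = Y[idx]
    prototype = (float(ys[:, 0].mean()), float(ys[:, 1].mean()))
    constant = bool((ys.max(axis=0) - ys.min(axis=0) <= _CONST_TOL).all())
    depth_capped = params.max_depth is not None and depth >= params.max_depth
    if constant or depth_capped or idx.size < 2 * params.min_leaf:
        return Leaf(prototype=prototype, count=int(idx.size))
    found = _best_split_arrays(X, Y, idx, scale, params.min_leaf)
    if found is None:
        return Leaf(prototype=prototype, count=int(idx.size))
    bit, reduction = found
    mask = X[idx, bit] > 0.5
    return Split(
        bit=bit,
        reduction=reduction,
        zero=_grow(X, Y, idx[~mask], scale, params, depth + 1),
        one=_grow(X, Y, idx[mask], scale, params, depth + 1),
    )


def grow_tree(
    records: Sequence[ScreenRecord],
    params: TreeParams,
    scale=None,
) -> PCTree:
    """Top-down induction of a single PCT.

    At each node the fingerprint bit with maximal normalised variance
    reduction is chosen (ties broken toward the lowest bit index); a node
    becomes a leaf when the targets are constant, the depth cap is hit,
    or no split leaves ``min_leaf`` records in both branches.  A split
    with zero reduction is still taken when admissible — necessary for
    XOR-like target structure, where no single bit reduces variance but
    a pair of bits fits exactly.
    """
    if len(records) == 0:
        raise ValueError("cannot grow a tree from zero records")
    nbits = records[0].fingerprint.nbits
    if scale is None:
        y = np.array([(r.rfp, r.egfp) for r in records], dtype=float)
        s = y.std(axis=0)
        scale = np.where(s <= 0, 1.0, s)
    s = _as_scale(scale)
    X = fingerprints_to_matrix([r.fingerprint for r in records], nbits)
    Y = np.array([(r.rfp, r.egfp) for r in records], dtype=float)
    if len(records) == 1:
        root: Node = Leaf(prototype=(float(Y[0, 0]), float(Y[0, 1])), count=1)
    else:
        root = _grow(X, Y, np.arange(len(records)), s, params, depth=0)
    return PCTree(root=root, nbits=nbits)


def predict_tree(tree: PCTree, fp: Fingerprint) -> tuple[float, float]:
    """Route a fingerprint to a leaf and return its prototype."""
    if fp.nbits != tree.nbits:
        raise ValueError(f"fingerprint nbits {fp.nbits} != tree {tree.nbits}")
    node = tree.root
    while isinstance(node, Split):
        node = node.one if node.bit in fp.bits else node.zero
    return node.prototype


def _predict_tree_batch(tree: PCTree, X: np.ndarray) -> np.ndarray:
    out = np.empty((X.shape[0], N_TARGETS))

    def walk(node: Node, idx: np.ndarray) -> None:
        if isinstance(node, Leaf):
            out[idx] = node.prototype
            return
        mask = X[idx, node.bit] > 0.5
        walk(node.zero, idx[~mask])
        walk(node.one, idx[mask])

    walk(tree.root, np.arange(X.shape[0]))
    return out


# ---------------------------------------------------------------------------
# bagging ensemble


@dataclass
class Ensemble:
    """Bagged PCTs; per-tree bootstrap indices retained for audit."""

    trees: list[PCTree]
    params: TreeParams
    seed: int
    bootstrap_indices: list[np.ndarray]
    nbits: int
    target_scale: np.ndarray = field(
        default_factory=lambda: np.ones(N_TARGETS)
    )

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValueError("ensemble needs at least one tree")
        if any(t.nbits != self.nbits for t in self.trees):
            raise ValueError("all trees must share nbits")


def fit_ensemble(
    ts: TrainingSet, params: TreeParams, seed: int
) -> Ensemble:
    """Fit a bagging ensemble: one PCT per bootstrap resample.

    Per-tree seeds are spawned from one root ``numpy.random.SeedSequence``
    so results do not depend on evaluation order; the same seed always
    yields bit-identical trees and bootstrap indices.
    """
    n = len(ts)
    X = ts.feature_matrix()
    Y = ts.targets()
    scale = ts.target_scale
    children = np.random.SeedSequence(seed).spawn(params.n_trees)
    trees: list[PCTree] = []
    boots: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        if params.bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        boots.append(idx)
        root = _grow(X, Y, idx, scale, params, depth=0)
        trees.append(PCTree(root=root, nbits=ts.nbits))
    return Ensemble(
        trees=trees,
        params=params,
        seed=seed,
        bootstrap_indices=boots,
        nbits=ts.nbits,
        target_scale=scale.copy(),
    )


def predict_ensemble(ens: Ensemble, fp: Fingerprint) -> Prediction:
    """Per-target mean and population sd of the individual-tree predictions."""
    if fp.nbits != ens.nbits:
        raise ValueError(f"fingerprint nbits {fp.nbits} != ensemble {ens.nbits}")
    preds = np.array([predict_tree(t, fp) for t in ens.trees])
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)  # population sd; 0 for a one-tree ensemble
    return Prediction(
        rfp_mean=float(mean[0]),
        egfp_mean=float(mean[1]),
        rfp_sd=float(sd[0]),
        egfp_sd=float(sd[1]),
    )


def predict_ensemble_many(
    ens: Ensemble, fps: Sequence[Fingerprint]
) -> list[Prediction]:
    """Vectorised :func:`predict_ensemble` over a fingerprint list."""
    if not fps:
        return []
    X = fingerprints_to_matrix(fps, ens.nbits)
    stacked = np.stack([_predict_tree_batch(t, X) for t in ens.trees])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    return [
        Prediction(
            rfp_mean=float(mean[i, 0]),
            egfp_mean=float(mean[i, 1]),
            rfp_sd=float(sd[i, 0]),
            egfp_sd=float(sd[i, 1]),
        )
        for i in range(len(fps))
    ]


# ---------------------------------------------------------------------------
# JSON serialisation


def _node_to_dict(node: Node) -> dict:
    if isinstance(node, Leaf):
        return {"leaf": {"prototype": list(node.prototype), "count": node.count}}
    return {
        "bit": node.bit,
        "reduction": node.reduction,
        "zero": _node_to_dict(node.zero),
        "one": _node_to_dict(node.one),
    }


def _node_from_dict(d: dict) -> Node:
    if "leaf" in d:
        proto = d["leaf"]["prototype"]
        return Leaf(prototype=(float(proto[0]), float(proto[1])), count=int(d["leaf"]["count"]))
    return Split(
        bit=int(d["bit"]),
        reduction=float(d["reduction"]),
        zero=_node_from_dict(d["zero"]),
        one=_node_from_dict(d["one"]),
    )


def ensemble_to_json(ens: Ensemble) -> str:
    doc = {
        "format": "phenoscreen-ensemble",
        "version": 1,
        "nbits": ens.nbits,
        "seed": ens.seed,
        "params": {
            "min_leaf": ens.params.min_leaf,
            "max_depth": ens.params.max_depth,
            "n_trees": ens.params.n_trees,
            "bootstrap": ens.params.bootstrap,
        },
        "target_scale": ens.target_scale.tolist(),
        "bootstrap_indices": [idx.tolist() for idx in ens.bootstrap_indices],
        "trees": [_node_to_dict(t.root) for t in ens.trees],
    }
    return json.dumps(doc)


def ensemble_from_json(text: str) -> Ensemble:
    doc = json.loads(text)
    if doc.get("format") != "phenoscreen-ensemble":
        raise ValueError("not a phenoscreen ensemble document")
    params = TreeParams(**doc["params"])
    nbits = int(doc["nbits"])
    trees = [PCTree(root=_node_from_dict(t), nbits=nbits) for t in doc["trees"]]
    return Ensemble(
        trees=trees,
        params=params,
        seed=int(doc["seed"]),
        bootstrap_indices=[np.array(i, dtype=int) for i in doc["bootstrap_indices"]],
        nbits=nbits,
        target_scale=np.array(doc["target_scale"], dtype=float),
    )
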