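"""Maximum-likelihood Mk reconstruction of binary characters on a species tree.

A binary character (here: presence/absence of a septin paralog Group in a
taxon) evolves along the species tree under a two-state continuous-time
Markov chain with gain rate ``q01`` and loss rate ``q10``:

    Q = [[-q01, q01],
         [q10, -q10]],     P(t) = exp(Qt).

MK1 constrains the rates equal; MK2 leaves them independent.  Likelihoods
are computed by Felsenstein pruning, ancestral "proportional likelihoods"
are normalized marginal posteriors from an up-down pass, and MK1 vs MK2 is
compared with a likelihood-ratio (Wilks) test on one degree of freedom.  A
node's state is called resolved when one state carries more than 95% of the
proportional likelihood.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalFailureError,
)

__all__ = [
    "MkModel",
    "CharacterMatrix",
    "NodeReconstruction",
    "transition_matrix",
    "mk_log_likelihood",
    "fit_mk",
    "marginal_reconstruction",
    "wilks_test",
    "RESOLVED_THRESHOLD",
]

#: A node is "resolved" when one state exceeds this proportional likelihood.
RESOLVED_THRESHOLD = 0.95

RATE_BOUNDS = (1e-8, 1e3)


@dataclass(frozen=True)
class MkModel:
    kind: str  # "MK1" | "MK2"
    q01: float
    q10: float

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise InvalidParameterError("Mk rates must be non-negative")
        if self.kind == "MK1" and not math.isclose(self.q01, self.q10, rel_tol=1e-12):
            raise InvalidParameterError("MK1 requires q01 == q10")
        if self.kind not in ("MK1", "MK2"):
            raise InvalidParameterError(f"unknown Mk model kind {self.kind!r}")


@dataclass(frozen=True)
class NodeReconstruction:
    node: str
    p0: float
    p1: float
    resolved: bool


class CharacterMatrix:
    """Taxa x characters binary matrix; entries 0, 1 or '?' (missing)."""

    def __init__(self, data: pd.DataFrame):
        bad = set(np.unique(data.values.astype(str))) - {"0", "1", "?"}
        if bad:
            raise InvalidInputError(f"character states must be 0/1/?: found {sorted(bad)}")
        self.data = data.astype(str)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def column(self, character: str) -> dict[str, str]:
        return self.data[character].to_dict()

    @classmethod
    def from_tsv(cls, path: str) -> "CharacterMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon")


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form P(t) = exp(Qt) for the two-state chain."""
    r = q01 + q10
    if r == 0.0 or t == 0.0:
        return np.eye(2)
    e = math.exp(-r * t)
    return np.array(
        [
            [(q10 + q01 * e) / r, q01 * (1.0 - e) / r],
            [q10 * (1.0 - e) / r, (q01 + q10 * e) / r],
        ]
    )


def _as_state_array(
    tree: dendropy.Tree, character: Union[Mapping[str, object], pd.Series]
) -> dict[str, np.ndarray]:
    """Leaf label -> (n_chars, 2) conditional likelihood rows."""
    if isinstance(character, pd.Series):
        character = character.to_dict()
    columns: dict[str, list] = {}
    for taxon, state in character.items():
        columns[taxon] = state if isinstance(state, (list, tuple, np.ndarray)) else [state]
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in columns:
            raise InvalidInputError(f"no character state for leaf {label!r}")
        rows = []
        for s in columns[label]:
            s = str(s)
            if s == "0":
                rows.append([1.0, 0.0])
            elif s == "1":
                rows.append([0.0, 1.0])
            elif s == "?":
                rows.append([1.0, 1.0])
            else:
                raise InvalidInputError(f"invalid state {s!r} for leaf {label!r}")
        out[label] = np.array(rows)
    return out


def _root_prior(model: MkModel, root_prior: str) -> np.ndarray:
    if root_prior == "uniform":
        return np.array([0.5, 0.5])
    if root_prior == "stationary":
        r = model.q01 + model.q10
        if r == 0.0:
            return np.array([0.5, 0.5])
        return np.array([model.q10 / r, model.q01 / r])
    raise InvalidParameterError(f"unknown root prior {root_prior!r}")


class _FlatTree:
    """Flattened postorder view of a tree for repeated pruning passes.

    Built once per optimization; avoids re-walking the dendropy object on
    every likelihood evaluation.
    """

    def __init__(self, tree: dendropy.Tree, leaf_rows: Mapping[str, np.ndarray]):
        nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_chars = next(iter(leaf_rows.values())).shape[0]
        self.entries: list[tuple[Optional[np.ndarray], list[tuple[int, float]]]] = []
        for node in nodes:
            if node.is_leaf():
                self.entries.append((leaf_rows[node.taxon.label], []))
            else:
                kids = [
                    (self.index[id(ch)], ch.edge.length or 0.0)
                    for ch in node.child_nodes()
                ]
                self.entries.append((None, kids))

    def prune(self, model: MkModel) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Partial likelihoods and log-scalers per node, (n_chars, 2) each."""
        partials: list[np.ndarray] = [None] * len(self.entries)  # type: ignore
        logscale: list[np.ndarray] = [None] * len(self.entries)  # type: ignore
        zeros = np.zeros(self.n_chars)
        for i, (rows, kids) in enumerate(self.entries):
            if rows is not None:
                partials[i] = rows
                logscale[i] = zeros
                continue
            acc = np.ones((self.n_chars, 2))
            scale = np.zeros(self.n_chars)
            for j, length in kids:
                P = transition_matrix(model.q01, model.q10, length)
                acc = acc * (partials[j] @ P.T)
                scale = scale + logscale[j]
            m = acc.max(axis=1)
            safe = np.where(m > 0.0, m, 1.0)
            partials[i] = acc / safe[:, None]
            logscale[i] = scale + np.log(safe)
        return partials, logscale

    def loglik(self, model: MkModel, prior: np.ndarray) -> float:
        partials, logscale = self.prune(model)
        per_char = (partials[-1] * prior).sum(axis=1)
        if np.any(per_char <= 0.0):
            return -math.inf
        return float((np.log(per_char) + logscale[-1]).sum())


def mk_log_likelihood(
    tree: dendropy.Tree,
    character: Union[Mapping[str, object], pd.Series],
    model: MkModel,
    root_prior: str = "uniform",
) -> float:
    """Log-likelihood of one character (or, vectorized, several pooled
    characters passed as per-leaf sequences) by Felsenstein pruning."""
    flat = _FlatTree(tree, _as_state_array(tree, character))
    return flat.loglik(model, _root_prior(model, root_prior))


def fit_mk(
    tree: dendropy.Tree,
    characters: Union[Mapping[str, object], pd.Series, CharacterMatrix],
    kind: str = "MK1",
    root_prior: str = "uniform",
    n_starts: int = 5,
) -> tuple[MkModel, float]:
    """Maximum-likelihood rate estimation, pooled over all given characters.

    Rates are optimized within ``RATE_BOUNDS`` on a log scale from
    ``n_starts`` log-spaced starting points.
    """
    if isinstance(characters, CharacterMatrix):
        pooled = {t: list(characters.data.loc[t]) for t in characters.taxa}
    else:
        pooled = characters
    flat = _FlatTree(tree, _as_state_array(tree, pooled))

    lo, hi = RATE_BOUNDS
    log_lo, log_hi = math.log(lo), math.log(hi)

    def negll(logq: np.ndarray) -> float:
        if kind == "MK1":
            model = MkModel("MK1", math.exp(logq[0]), math.exp(logq[0]))
        else:
            model = MkModel("MK2", math.exp(logq[0]), math.exp(logq[1]))
        ll = flat.loglik(model, _root_prior(model, root_prior))
        return -ll if math.isfinite(ll) else 1e300

    starts = np.linspace(math.log(1e-4), math.log(10.0), n_starts)
    best: Optional[tuple[float, np.ndarray]] = None
    if kind == "MK1":
        res = minimize_scalar(
            lambda x: negll(np.array([x])),
            bounds=(log_lo, log_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if math.isfinite(res.fun):
            best = (float(res.fun), np.array([res.x]))
        for s in starts:
            r = minimize(negll, x0=np.array([s]), method="L-BFGS-B", bounds=[(log_lo, log_hi)])
            if math.isfinite(r.fun) and (best is None or r.fun < best[0]):
                best = (float(r.fun), r.x)
    elif kind == "MK2":
        # A bounded solve along the equal-rates diagonal seeds MK2 at (or
        # above) the MK1 optimum, guaranteeing the nesting lnL2 >= lnL1.
        diag = minimize_scalar(
            lambda x: negll(np.array([x, x])),
            bounds=(log_lo, log_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        seed_starts = [float(diag.x)] if math.isfinite(diag.fun) else []
        if math.isfinite(diag.fun):
            best = (float(diag.fun), np.array([diag.x, diag.x]))
        for s in list(starts) + seed_starts:
            r = minimize(
                negll,
                x0=np.array([s, s]),
                method="L-BFGS-B",
                bounds=[(log_lo, log_hi)] * 2,
            )
            if math.isfinite(r.fun) and (best is None or r.fun < best[0]):
                best = (float(r.fun), r.x)
    else:
        raise InvalidParameterError(f"unknown Mk model kind {kind!r}")
    if best is None:
        raise NumericalFailureError(f"{kind} optimization failed from all starts")
    fun, x = best
    if kind == "MK1":
        q = math.exp(float(x[0]))
        return MkModel("MK1", q, q), -fun
    return MkModel("MK2", math.exp(float(x[0])), math.exp(float(x[1]))), -fun


def marginal_reconstruction(
    tree: dendropy.Tree,
    character: Union[Mapping[str, object], pd.Series],
    model: MkModel,
    root_prior: str = "uniform",
) -> list[NodeReconstruction]:
    """Marginal posterior state probabilities at every internal node.

    Uses the up-down algorithm: the downward (pruning) partials are combined
    with upward partials carrying the information outside each node's
    subtree; the product, normalized, is the proportional likelihood.
    Internal nodes are labelled ``nd1..`` in postorder when unlabelled.
    """
    leaf_rows = _as_state_array(tree, character)
    prior = _root_prior(model, root_prior)
    flat = _FlatTree(tree, leaf_rows)
    if flat.n_chars != 1:
        raise InvalidInputError("marginal_reconstruction expects a single character")
    flat_partials, _ = flat.prune(model)
    partials = {id(n): flat_partials[flat.index[id(n)]] for n in tree.postorder_node_iter()}
    n_chars = 1

    _ensure_internal_labels(tree)
    up: dict[int, np.ndarray] = {id(tree.seed_node): np.tile(prior, (n_chars, 1))}
    out: list[NodeReconstruction] = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent = node.parent_node
            sib_prod = up[id(parent)].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                Ps = transition_matrix(model.q01, model.q10, sib.edge.length or 0.0)
                sib_prod = sib_prod * (partials[id(sib)] @ Ps.T)
            P = transition_matrix(model.q01, model.q10, node.edge.length or 0.0)
            u = sib_prod @ P
            m = u.max(axis=1)
            up[id(node)] = u / np.where(m > 0.0, m, 1.0)[:, None]
        if not node.is_leaf():
            joint = partials[id(node)] * up[id(node)]
            total = joint.sum(axis=1)
            if np.any(total <= 0.0):
                raise NumericalFailureError("zero marginal likelihood at a node")
            post = (joint / total[:, None])[0]
            out.append(
                NodeReconstruction(
                    node=node.label,
                    p0=float(post[0]),
                    p1=float(post[1]),
                    resolved=bool(post.max() > RESOLVED_THRESHOLD),
                )
            )
    return out


def _ensure_internal_labels(tree: dendropy.Tree) -> None:
    """Assign deterministic postorder labels nd1.. to unlabelled internals."""
    i = 0
    for node in tree.postorder_internal_node_iter():
        i += 1
        if node.label is None:
            node.label = f"nd{i}"


def wilks_test(lnl_mk1: float, lnl_mk2: float) -> tuple[float, float]:
    """Likelihood-ratio test of MK2 against nested MK1 (chi-square, df=1)."""
    if lnl_mk2 < lnl_mk1 - 1e-6:
        raise InvalidInputError(
            f"MK2 log-likelihood ({lnl_mk2}) below MK1 ({lnl_mk1}): models are nested"
        )
    stat = max(0.0, 2.0 * (lnl_mk2 - lnl_mk1))
    return stat, float(chi2.sf(stat, df=1))


def write_reconstruction(recs: Sequence[NodeReconstruction], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node", "P0", "P1", "resolved"])
        for r in recs:
            w.writerow([r.node, f"{r.p0:.6f}", f"{r.p1:.6f}", int(r.resolved)])
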