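"""Balanced training-set construction, with optional expression matching.

Two sampling modes mirror the two classification problems the binding model
is trained on:

``uncontrolled``
    keep every positive sequence (window overlapping a ChIP-seq peak) and
    draw the same number of negatives uniformly among non-overlapping
    windows;

``expression_controlled``
    restrict positives to windows of expressed genes (expression > 0) and
    draw negatives whose expression distribution matches the positives',
    so the model cannot simply learn an open-vs-closed chromatin surrogate.

"Similar expression level" is implemented as quantile-bin matching on
log1p expression with a configurable number of bins; bins short of
negative candidates borrow from the nearest bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("uncontrolled", "expression_controlled")


@dataclass
class LabeledDataset:
    """A balanced feature matrix + labels, with sampling provenance."""

    X: pd.DataFrame
    y: np.ndarray
    ids: list
    mode: str
    seed: int
    provenance: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=bool)
        if len(self.y) != len(self.X) or len(self.ids) != len(self.X):
            raise ValueError("X, y and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in dataset")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        n_pos, n_neg = int(self.y.sum()), int((~self.y).sum())
        if n_pos != n_neg:
            raise ValueError(
                f"dataset must be balanced; got {n_pos} positives, {n_neg} negatives"
            )

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "label": self.y.astype(int),
             "mode": self.mode, "seed": self.seed}
        )


def sample_uncontrolled(labels, ids, seed: int) -> np.ndarray:
    """Indices of all positives plus an equal number of random negatives."""
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) == 0:
        raise ValueError("no positive sequences")
    if len(neg) < len(pos):
        raise ValueError(
            f"not enough negatives: {len(neg)} candidates for {len(pos)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen_neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, chosen_neg]))


def sample_expression_controlled(
    labels, ids, expression: dict, seed: int, n_bins: int = 10
) -> np.ndarray:
    """Indices of expressed positives plus expression-matched negatives.

    Positives with zero expression are excluded.  Candidate negatives are
    assigned to log1p-expression quantile bins defined on the positives and
    sampled bin-by-bin to the positive count; shortfalls borrow from the
    nearest bins (logged).
    """
    labels = np.asarray(labels, dtype=bool)
    ids = list(ids)
    expr = np.array([float(expression.get(i, 0.0)) for i in ids])
    n_missing = sum(1 for i in ids if i not in expression)
    if n_missing:
        logger.warning(
            "expression missing for %d/%d ids; treated as 0", n_missing, len(ids)
        )
    pos = np.flatnonzero(labels & (expr > 0))
    if len(pos) == 0:
        raise ValueError("no positive sequences with non-zero expression")
    neg = np.flatnonzero(~labels)
    if len(neg) < len(pos):
        raise ValueError(
            f"not enough negatives: {len(neg)} candidates for {len(pos)} positives"
        )
    rng = np.random.default_rng(seed)
    log_expr = np.log1p(expr)
    edges = np.quantile(log_expr[pos], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # degenerate distributions collapse bins
    if len(edges) < 2:        # all positives share one expression value
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])

    def bin_of(values):
        # interior bins [e_i, e_{i+1}); everything outside clipped inward
        b = np.searchsorted(edges, values, side="right") - 1
        return np.clip(b, 0, len(edges) - 2)

    pos_bins = bin_of(log_expr[pos])
    neg_bins = bin_of(log_expr[neg])
    n_b = len(edges) - 1
    remaining = {b: list(rng.permutation(neg[neg_bins == b])) for b in range(n_b)}
    chosen: list[int] = []
    for b in range(n_b):
        need = int((pos_bins == b).sum())
        take = remaining[b][:need]
        remaining[b] = remaining[b][len(take):]
        shortfall = need - len(take)
        if shortfall:
            logger.info(
                "expression bin %d short of %d negatives; borrowing from neighbours",
                b, shortfall,
            )
        dist = 1
        while shortfall > 0 and dist < n_b:
            for nb in (b - dist, b + dist):
                if shortfall <= 0 or not (0 <= nb < n_b):
                    continue
                extra = remaining[nb][:shortfall]
                remaining[nb] = remaining[nb][len(extra):]
                take.extend(extra)
                shortfall -= len(extra)
            dist += 1
        if shortfall > 0:
            raise ValueError("exhausted negative candidates during bin matching")
        chosen.extend(int(i) for i in take)
    return np.sort(np.concatenate([pos, np.array(chosen, dtype=int)]))


def make_dataset(
    X: pd.DataFrame,
    labels,
    mode: str = "uncontrolled",
    seed: int = 0,
    expression: dict | None = None,
    n_bins: int = 10,
    provenance: str = "",
) -> LabeledDataset:
    """Sample a balanced :class:`LabeledDataset` from a labeled feature matrix."""
    ids = list(X.index)
    if mode == "uncontrolled":
        idx = sample_uncontrolled(labels, ids, seed)
    elif mode == "expression_controlled":
        if expression is None:
            raise ValueError("expression table required for expression_controlled mode")
        idx = sample_expression_controlled(labels, ids, expression, seed, n_bins)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels, dtype=bool)
    return LabeledDataset(
        X=X.iloc[idx],
        y=labels[idx],
        ids=[ids[i] for i in idx],
        mode=mode,
        seed=seed,
        provenance=provenance,
    )


def read_expression_table(path, aggregate: str = "mean") -> dict:
    """Two-column (id, value) TSV, or id + several replicate columns.

    Replicates are combined with ``mean`` (the default, as for CAGE
    replicates) or ``sum`` (as for aggregating mature-miRNA expression to a
    pri-miRNA).
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    values = df.iloc[:, 1:]
    agg = values.mean(axis=1) if aggregate == "mean" else values.sum(axis=1)
    if (agg < 0).any():
        raise ValueError(f"{path}: negative expression values")
    out: dict = {}
    for key, val in zip(df.iloc[:, 0], agg):
        if key in out:
            out[key] = (out[key] + val) / 2 if aggregate == "mean" else out[key] + val
        else:
            out[key] = float(val)
    return out


def write_expression_table(expression: dict, path, cell_type: str = "") -> None:
    with open(path, "w") as fh:
        header = f"id\t{cell_type or 'expression'}\n"
        fh.write(header)
        for k, v in expression.items():
            fh.write(f"{k}\t{v:g}\n")
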