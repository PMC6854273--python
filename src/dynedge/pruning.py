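"""Iterative network pruning, input-significance scoring and left-right
symmetry assessment.

Pruning tests each remaining input component (or hidden unit) by zeroing
its signal and evaluating the SSE loss over the training set; the component
whose omission raises the loss least is removed permanently together with
its parameters, the network is retrained briefly, and the cycle repeats
until one component remains.  For product features a product *term* is
removed as a group across all columns at once.

Significance over a sample of independently pruned networks follows the
final-ten convention: in each trace the last surviving component scores 10,
the one removed last 9, and so on down to 1; components absent from a
trace's final ten score 0 there.  Scores are averaged over the sample with
occurrence counts.

Because the training corpus is mirror-symmetric (every scenario appears
with its left-right reflection at equal frequency), an optimally selected
input set should be closed under reflection; the symmetry report pairs each
component with its mirror image and tabulates the score defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .earlyvision import column_names
from .edgenet import EdgeNetwork, TrainConfig, _activate, score, train

__all__ = [
    "PruneTrace",
    "prune_step",
    "prune_full",
    "significance_scores",
    "mirror_component",
    "symmetry_report",
]


def _forward_parts(net: EdgeNetwork, X: np.ndarray):
    A1 = X @ net.W1.T + net.b1
    H = _activate(A1, net.use_table)
    out = _activate(H @ net.W2 + net.b2, net.use_table)
    return A1, H, out


def _loss_from_A1(net: EdgeNetwork, A1: np.ndarray, y: np.ndarray) -> float:
    H = _activate(A1, net.use_table)
    out = _activate(H @ net.W2 + net.b2, net.use_table)
    return float(0.5 * np.sum((out - y) ** 2))


def prune_step(net: EdgeNetwork, X, y, candidates: dict, mode: str = "input"):
    """Identify the least significant candidate by omission loss.

    ``candidates`` maps a component name to the input-column indices it
    covers (mode "input"; a group may span several columns) or to a hidden
    unit index (mode "hidden").  Returns ``(name, increments)`` where
    increments is a name-indexed Series of loss increases relative to the
    intact network.  Ties break toward the candidate listed first.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to prune")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    A1, H, out = _forward_parts(net, X)
    base = float(0.5 * np.sum((out - y) ** 2))
    increments = {}
    if mode == "input":
        for name, idxs in candidates.items():
            delta = np.zeros_like(A1)
            for i in np.atleast_1d(idxs):
                delta += np.outer(X[:, i], net.W1[:, i])
            increments[name] = _loss_from_A1(net, A1 - delta, y) - base
    elif mode == "hidden":
        for name, j in candidates.items():
            j = int(np.atleast_1d(j)[0])
            a2 = H @ net.W2 + net.b2 - net.W2[j] * H[:, j]
            o = _activate(a2, net.use_table)
            increments[name] = float(0.5 * np.sum((o - y) ** 2)) - base
    else:
        raise ValueError("mode must be 'input' or 'hidden'")
    series = pd.Series(increments)
    best = min(increments, key=lambda k: increments[k])
    return best, series


def _drop_input_positions(net: EdgeNetwork, positions) -> EdgeNetwork:
    keep = np.setdiff1d(np.arange(net.n_inputs), np.atleast_1d(positions))
    out = net.copy()
    out.W1 = np.ascontiguousarray(net.W1[:, keep])
    if net.feature_names is not None:
        out.feature_names = [net.feature_names[i] for i in keep]
    return out


def _drop_hidden_position(net: EdgeNetwork, j: int) -> EdgeNetwork:
    keep = np.setdiff1d(np.arange(net.n_hidden), [j])
    out = net.copy()
    out.W1 = np.ascontiguousarray(net.W1[keep])
    out.b1 = net.b1[keep].copy()
    out.W2 = net.W2[keep].copy()
    return out


@dataclass
class PruneTrace:
    """Record of one full pruning run."""

    mode: str
    component_names: list  # full universe, in canonical order
    removal_order: list = field(default_factory=list)
    loss_increments: list = field(default_factory=list)
    scores: list = field(default_factory=list)  # training score after each retrain
    n_remaining: list = field(default_factory=list)  # components left after each step

    @property
    def survivor(self) -> str:
        removed = set(self.removal_order)
        return next(c for c in self.component_names if c not in removed)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removed": self.removal_order,
                "loss_increment": self.loss_increments,
                "score_after_retrain": self.scores,
                "n_remaining": self.n_remaining,
            }
        )


def prune_full(
    net: EdgeNetwork,
    X,
    y,
    mode: str = "input",
    groups: dict | None = None,
    retrain_epochs: int = 150,
    cfg: TrainConfig | None = None,
) -> PruneTrace:
    """Alternate omission-based pruning and retraining down to one component.

    ``groups`` (mode "input" only) maps component names to original input
    column indices; by default every column is its own component, named
    after ``net.feature_names``.  The network must already discriminate on
    the given data: a chance-level network is rejected.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if score(net, X, y) < 0.55:
        raise ValueError("refusing to prune an untrained network (chance-level score)")
    base_cfg = cfg or TrainConfig()
    retrain_seeds = np.random.SeedSequence(base_cfg.seed).generate_state(8192)
    net = net.copy()

    if mode == "input":
        if groups is None:
            names = net.feature_names or [f"in{i}" for i in range(net.n_inputs)]
            groups = {name: [i] for i, name in enumerate(names)}
        active = {name: list(np.atleast_1d(idx)) for name, idx in groups.items()}
        active_cols = sorted({i for idxs in active.values() for i in idxs})
    elif mode == "hidden":
        active = {f"H{j}": j for j in range(net.n_hidden)}
    else:
        raise ValueError("mode must be 'input' or 'hidden'")

    trace = PruneTrace(mode, list(active))
    step = 0
    while len(active) > 1:
        if mode == "input":
            pos = {orig: k for k, orig in enumerate(active_cols)}
            candidates = {n: [pos[i] for i in idxs] for n, idxs in active.items()}
            Xa = X[:, active_cols]
        else:
            hid = sorted(active.values())
            posh = {orig: k for k, orig in enumerate(hid)}
            candidates = {n: posh[j] for n, j in active.items()}
            Xa = X
        best, increments = prune_step(net, Xa, y, candidates, mode)
        if mode == "input":
            net = _drop_input_positions(net, candidates[best])
            for i in active[best]:
                active_cols.remove(i)
            Xa = X[:, active_cols]
        else:
            net = _drop_hidden_position(net, candidates[best])
        del active[best]
        rcfg = TrainConfig(
            eta0=base_cfg.eta0,
            etae=base_cfg.etae,
            epochs=retrain_epochs,
            seed=int(retrain_seeds[step]),
        )
        net, _ = train(net, Xa, y, rcfg)
        trace.removal_order.append(best)
        trace.loss_increments.append(float(increments[best]))
        trace.scores.append(score(net, Xa, y))
        trace.n_remaining.append(len(active))
        step += 1
    return trace


def significance_scores(traces) -> pd.DataFrame:
    """Final-ten significance ranking over a sample of pruning traces.

    Per trace the survivor scores 10, the last-removed component 9, down
    to 1 for the component removed ninth from the end; everything else
    scores 0.  Returns a DataFrame (component, score, occurrences) sorted
    by descending mean score.
    """
    traces = list(traces)
    universe = sorted(traces[0].component_names)
    for t in traces:
        if sorted(t.component_names) != universe:
            raise ValueError("traces cover mismatched component universes")
    per_trace = []
    for t in traces:
        order = list(t.removal_order) + [t.survivor]
        scores = {c: 0.0 for c in universe}
        depth = min(10, len(order))
        for rank, comp in enumerate(order[-depth:], start=11 - depth):
            scores[comp] = float(rank)
        per_trace.append(scores)
    rows = []
    for comp in universe:
        vals = np.array([s[comp] for s in per_trace])
        rows.append(
            dict(component=comp, score=vals.mean(), occurrences=int((vals > 0).sum()))
        )
    frame = pd.DataFrame(rows).sort_values(
        ["score", "component"], ascending=[False, True], ignore_index=True
    )
    return frame


# ---------------------------------------------------------------------------
# left-right symmetry
# ---------------------------------------------------------------------------


def _mirror_column(col: str, n_columns: int) -> str:
    cols = column_names(n_columns)
    return cols[len(cols) - 1 - cols.index(col)]


def mirror_component(name: str, n_columns: int) -> str:
    """Name of the component's left-right reflection.

    ON/OFF, sustained/transient and delay are preserved; column positions
    reflect about the array midline.  For inter-column products the factor
    order flips so the left factor stays first.  Raises for components with
    no defined mirror (e.g. hidden units).
    """
    if "*" in name:
        a, b = name.split("*")
        if "-" in a and "-" in b:  # inter-column product
            sig_a, col_a = a.rsplit("-", 1)
            sig_b, col_b = b.rsplit("-", 1)
            return f"{sig_b}-{_mirror_column(col_b, n_columns)}*{sig_a}-{_mirror_column(col_a, n_columns)}"
        if "-" in b:  # intra-column product: SIG*SIG-Col
            pair, col = b.rsplit("-", 1)
            return f"{a}*{pair}-{_mirror_column(col, n_columns)}"
        raise ValueError(f"no mirror defined for component {name!r}")
    if "-" in name:
        sig, col = name.rsplit("-", 1)
        return f"{sig}-{_mirror_column(col, n_columns)}"
    raise ValueError(f"no mirror defined for component {name!r}")


def symmetry_report(ranking: pd.DataFrame, n_columns: int) -> pd.DataFrame:
    """Pair each ranked component with its mirror and score the asymmetry.

    ``ranking`` is a significance_scores frame.  The report lists each
    component with its mirror, both scores, whether it is its own mirror,
    and the symmetry defect |score - mirror score|.
    """
    scores = dict(zip(ranking["component"], ranking["score"]))
    rows = []
    for comp, s in scores.items():
        mirror = mirror_component(comp, n_columns)
        ms = scores.get(mirror, 0.0)
        rows.append(
            dict(
                component=comp,
                mirror=mirror,
                score=s,
                mirror_score=ms,
                self_mirror=mirror == comp,
                defect=abs(s - ms),
            )
        )
    return pd.DataFrame(rows)
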