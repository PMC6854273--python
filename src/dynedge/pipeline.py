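"""End-to-end experiment orchestration.

This module turns scenario catalogs into labeled signal corpora (stimulus
synthesis -> optics -> early-vision cascade -> 10 ms averaging ->
normalization), assembles feature datasets, and runs the training regimens:

* FIXED: edges fixed midway between the two central receptors; 8-receptor
  array; raw signals or correlation products from the central 2/4/6 columns.
* MOVING: edges sweeping at 50 deg/s; 6-receptor array; raw signals only;
  outputs recorded only while an edge crosses the central pair, with
  50%-overlapped windows.
* COMBINED: the moving corpus augmented with an equal-sized, scenario-
  stratified subset of the fixed-edge data, full-field data doubled.
* SINGLE_EDGE_TYPE: one edge class pair against the full mixture of
  full-field stimuli at equal priors, trained from weights learned on the
  full corpus.

The reference corpus sizes are 72,000 + 72,000 outputs (1,440 s) for the
fixed-edge universe and 20,000 + 20,000 for the moving-edge universe; a
corpus ``scale`` shrinks every scenario count proportionally, preserving
all frequency ratios.  Everything is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from . import stimgen
from .earlyvision import (
    Cascade,
    apply_gains,
    calibrate_gains,
    central_columns,
    make_products,
    product_terms,
    raw_feature_names,
)
from .edgenet import TrainConfig, score, split_dataset, train
from .optics import blur_matrix
from .stimgen import (
    DT,
    EdgeKinematics,
    FixedEdgeScene,
    FullFieldScene,
    ImageKind,
    MovingEdgeScene,
    build_fixed_edge_catalog,
    build_moving_edge_catalog,
)

__all__ = [
    "SignalCorpus",
    "LabeledDataset",
    "ExperimentConfig",
    "Regimen",
    "RegimenResult",
    "generate_fixed_corpus",
    "generate_moving_corpus",
    "corpus_features",
    "train_sample",
    "cross_generalize",
    "single_edge_type_dataset",
    "combined_dataset",
    "run_regimen",
    "desk_train_config",
    "DESK_SCALE",
]

#: reference (scale 1.0) output counts per corpus half
FIXED_HALF = 72_000
MOVING_HALF = 20_000
WINDOW = 0.010  # s
BURN_IN = 2.0  # s
CHUNK = 4096  # simulation steps per block
#: desk-scale replication conditions: 15% corpus, shortened SGD protocol
DESK_SCALE = 0.15


def desk_train_config(seed: int) -> TrainConfig:
    """Shortened multi-start protocol used for desk-scale replication."""
    return TrainConfig(epochs=200, n_starts=5, start_epochs=25, seed=seed)


@dataclass
class SignalCorpus:
    """Normalized, 10 ms-averaged early-vision signals with labels."""

    signals: np.ndarray  # (N, n_receptors, 8)
    y: np.ndarray  # (N,) 1 = edge present
    meta: pd.DataFrame
    gains: np.ndarray
    n_receptors: int
    dt: float = DT

    def __len__(self) -> int:
        return self.signals.shape[0]


@dataclass
class LabeledDataset:
    """Feature vectors with binary edge labels and scenario metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    feature_names: list

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(
            self.X[idx], self.y[idx], self.meta.iloc[idx].reset_index(drop=True),
            self.feature_names,
        )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _simulate_scene(scene, n_receptors, burn_steps, chunk=CHUNK):
    """Per-step early-vision signals for the post-burn-in part of a scene."""
    M = blur_matrix(scene.n_pixels, scene.pixel_pitch, n_receptors)
    cascade = Cascade(n_receptors, scene.dt)
    out = np.empty((scene.n_steps - burn_steps, n_receptors, 8))
    for t0 in range(0, scene.n_steps, chunk):
        t1 = min(t0 + chunk, scene.n_steps)
        drive = scene.frames(t0, t1) @ M
        sig = cascade.process(drive)
        lo = max(t0, burn_steps)
        if lo < t1:
            out[lo - burn_steps : t1 - burn_steps] = sig[lo - t0 :]
    return out


def _window_means(signals, starts, win):
    csum = np.cumsum(signals, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros((1,) + signals.shape[1:]), csum], axis=0)
    return (csum[starts + win] - csum[starts]) / win


def _meta_rows(spec, n, scene_id, **extra):
    base = dict(
        label=int(spec.present),
        scenario=spec.label,
        left=spec.left_class.label,
        right=spec.right_class.label,
        kinematics=spec.kinematics.value,
        scene=scene_id,
    )
    base.update(extra)
    return [dict(base, window=i) for i in range(n)]


def _fixed_half_count(scale: float) -> int:
    """Scaled fixed-corpus half size, kept divisible by all 36+60 units."""
    return 180 * max(1, int(round(FIXED_HALF * scale / 180)))


def _moving_half_count(scale: float) -> int:
    """Scaled moving-corpus half; divisible by 24 so window quotas pair up."""
    return 24 * max(1, int(round(MOVING_HALF * scale / 24)))


def generate_fixed_corpus(
    scale: float = 1.0,
    seed: int = 0,
    n_receptors: int = 8,
    gains: Optional[np.ndarray] = None,
    burn_in: float = BURN_IN,
) -> SignalCorpus:
    """Generate the fixed-edge corpus (edge + full-field halves, 50/50).

    One scene is synthesized per catalog entry, long enough to record the
    entry's output count in successive 10 ms windows after burn-in.  When
    ``gains`` is None the normalization is calibrated on this corpus's own
    positive excursions and the resulting gains are stored on the corpus.
    """
    catalog = build_fixed_edge_catalog(2 * _fixed_half_count(scale))
    ss = np.random.SeedSequence([seed, 101])
    seeds = ss.spawn(len(catalog.entries))
    win = int(round(WINDOW / DT))
    burn_steps = int(round(burn_in / DT))
    blocks, meta = [], []
    for scene_id, (entry, scene_seed) in enumerate(zip(catalog.entries, seeds)):
        spec = entry.spec
        n_steps = burn_steps + entry.count * win
        if spec.present:
            scene = FixedEdgeScene(
                spec.left_class, spec.right_class, n_steps, n_receptors, scene_seed
            )
        else:
            scene = FullFieldScene(
                spec.left_class, n_steps, n_receptors, scene_seed
            )
        sig = _simulate_scene(scene, n_receptors, burn_steps)
        starts = np.arange(entry.count) * win
        blocks.append(_window_means(sig, starts, win))
        speed = spec.left_class.speed or spec.right_class.speed
        meta.extend(_meta_rows(spec, entry.count, scene_id, speed=speed))
    signals = np.concatenate(blocks, axis=0)
    if gains is None:
        gains = calibrate_gains(signals)
    signals = apply_gains(signals, gains)
    frame = pd.DataFrame(meta)
    return SignalCorpus(signals, frame["label"].to_numpy(np.int8), frame, gains, n_receptors)


def generate_moving_corpus(
    scale: float = 1.0,
    seed: int = 0,
    n_receptors: int = 6,
    gains: Optional[np.ndarray] = None,
    burn_in: float = BURN_IN,
) -> SignalCorpus:
    """Generate the moving-edge corpus.

    Edge outputs are recorded only while an edge is passing between the two
    central receptors, in 50%-overlapped 10 ms windows (5 ms stride); each
    ordered class pair fills an exact window quota, so both left/right
    assignments of every pair are equally represented.  Pass the ``gains``
    calibrated on the fixed corpus to keep all corpora on one scale.
    """
    catalog = build_moving_edge_catalog(2 * _moving_half_count(scale))
    if gains is None:
        raise ValueError("moving corpus requires normalization gains (calibrate on the fixed corpus)")
    win = int(round(WINDOW / DT))
    stride = win // 2
    burn_steps = int(round(burn_in / DT))
    ss = np.random.SeedSequence([seed, 202])
    edge_entries = catalog.edge_entries
    # group mirrored ordered entries into one alternating scene per unordered pair
    pairs = {}
    for e in edge_entries:
        key = frozenset([e.spec.left_class, e.spec.right_class])
        pairs.setdefault(key, []).append(e)
    seeds = ss.spawn(len(pairs) + len(catalog.no_edge_entries))
    blocks, meta = [], []
    scene_id = 0
    for (key, entries), scene_seed in zip(sorted(pairs.items(), key=lambda kv: sorted(c.label for c in kv[0])), seeds):
        class_a, class_b = sorted(key, key=lambda c: c.label)
        quota = {e.spec.label: e.count for e in entries}
        n_windows = sum(quota.values())
        segment_steps = int(round(stimgen.SEGMENT_DEG / (stimgen.EDGE_SPEED * DT)))
        n_steps = burn_steps + (n_windows // 2 + 3) * segment_steps + win
        scene = MovingEdgeScene(class_a, class_b, n_steps, n_receptors, scene_seed)
        starts, lefts, rights = scene.record_starts(
            burn_steps, scene.n_steps - win, win, stride
        )
        sig = _simulate_scene(scene, n_receptors, burn_steps)
        taken_starts, taken_specs = [], []
        for t, left, right in zip(starts, lefts, rights):
            spec = stimgen.EdgeSpec(
                True, EdgeKinematics.MOVING, left, right, stimgen.EDGE_SPEED
            )
            if quota.get(spec.label, 0) > 0:
                quota[spec.label] -= 1
                taken_starts.append(t - burn_steps)
                taken_specs.append(spec)
        if any(quota.values()):
            raise RuntimeError("moving-edge scene too short to fill window quotas")
        means = _window_means(sig, np.asarray(taken_starts), win)
        blocks.append(means)
        for spec in taken_specs:
            meta.extend(_meta_rows(spec, 1, scene_id, speed=stimgen.EDGE_SPEED))
        scene_id += 1
    for entry, scene_seed in zip(catalog.no_edge_entries, seeds[len(pairs):]):
        spec = entry.spec
        n_steps = burn_steps + (entry.count - 1) * stride + win
        scene = FullFieldScene(spec.left_class, n_steps, n_receptors, scene_seed)
        sig = _simulate_scene(scene, n_receptors, burn_steps)
        starts = np.arange(entry.count) * stride
        blocks.append(_window_means(sig, starts, win))
        meta.extend(
            _meta_rows(spec, entry.count, scene_id, speed=spec.left_class.speed)
        )
        scene_id += 1
    signals = apply_gains(np.concatenate(blocks, axis=0), gains)
    frame = pd.DataFrame(meta)
    frame["window"] = np.arange(len(frame))
    return SignalCorpus(signals, frame["label"].to_numpy(np.int8), frame, gains, n_receptors)


# ---------------------------------------------------------------------------
# features and regimens
# ---------------------------------------------------------------------------


def corpus_features(corpus: SignalCorpus, n_columns: int, mode: str = "raw") -> LabeledDataset:
    """Feature vectors from the ``n_columns`` central visual units.

    ``mode`` "raw" gives the 8 signals per column (8n features); mode
    "products" gives the 28 intra-column + 64 adjacent-pair correlation
    products (120/304/488 features for 2/4/6 columns).
    """
    sel = central_columns(corpus.signals, n_columns)
    if mode == "raw":
        X = sel.reshape(len(corpus), -1)
        names = raw_feature_names(n_columns)
    elif mode == "products":
        X = make_products(sel, n_columns)
        names = [t["name"] for t in product_terms(n_columns)]
    else:
        raise ValueError("mode must be 'raw' or 'products'")
    return LabeledDataset(np.ascontiguousarray(X), corpus.y.copy(), corpus.meta.copy(), names)


@dataclass
class RegimenResult:
    """Sample of independently trained networks plus their scores."""

    nets: list
    train_scores: np.ndarray
    test_scores: np.ndarray
    histories: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    data: LabeledDataset

    def summary(self) -> dict:
        return dict(
            train_mean=float(self.train_scores.mean()),
            train_sd=float(self.train_scores.std(ddof=1)) if len(self.train_scores) > 1 else 0.0,
            test_mean=float(self.test_scores.mean()),
            test_sd=float(self.test_scores.std(ddof=1)) if len(self.test_scores) > 1 else 0.0,
        )


def train_sample(
    data: LabeledDataset,
    cfg: TrainConfig,
    n_networks: int = 5,
    n_hidden: int = 32,
    init_nets: Optional[list] = None,
) -> RegimenResult:
    """Train a sample of networks on one 3/4-1/4 split of a dataset.

    All networks share the split; they differ in initialization and
    pattern-order seeds.  ``init_nets`` switches to continuation training
    (no multi-start) from the given weight sets, as used for the
    single-edge-type regimen.
    """
    ss = np.random.SeedSequence([cfg.seed, 303])
    split_seed, *net_seeds = ss.spawn(n_networks + 1)
    train_idx, test_idx = split_dataset(data.X, data.y, split_seed, cfg.train_fraction)
    Xtr, ytr = data.X[train_idx], data.y[train_idx]
    Xte, yte = data.X[test_idx], data.y[test_idx]
    nets, histories = [], []
    for k in range(n_networks):
        kcfg = TrainConfig(
            eta0=cfg.eta0,
            etae=cfg.etae,
            epochs=cfg.epochs,
            n_starts=cfg.n_starts,
            start_epochs=cfg.start_epochs,
            seed=net_seeds[k],
            train_fraction=cfg.train_fraction,
        )
        init = None if init_nets is None else init_nets[k]
        net, hist = train(init, Xtr, ytr, kcfg, n_hidden=n_hidden)
        net.feature_names = list(data.feature_names)
        nets.append(net)
        histories.append(hist)
    train_scores = np.array([score(n, Xtr, ytr) for n in nets])
    test_scores = np.array([score(n, Xte, yte) for n in nets])
    return RegimenResult(nets, train_scores, test_scores, histories, train_idx, test_idx, data)


def cross_generalize(result: RegimenResult, other: LabeledDataset) -> float:
    """Sample-mean score of trained networks on another regimen's data."""
    if other.X.shape[1] != result.data.X.shape[1]:
        raise ValueError("feature dimensions do not match")
    return float(np.mean([score(n, other.X, other.y) for n in result.nets]))


def _stratified_sample(meta: pd.DataFrame, idx: np.ndarray, n: int, rng) -> np.ndarray:
    """Scenario-stratified subsample of ``idx`` with exact total ``n``."""
    groups = meta.iloc[idx].groupby("scenario").indices
    keys = sorted(groups)
    sizes = np.array([len(groups[k]) for k in keys], dtype=float)
    exact = sizes * (n / sizes.sum())
    take = np.floor(exact).astype(int)
    rem = n - take.sum()
    order = np.argsort(-(exact - take))
    take[order[:rem]] += 1
    chosen = []
    for k, t in zip(keys, take):
        sub = idx[groups[k]]
        chosen.append(sub[rng.permutation(len(sub))[:t]])
    return np.sort(np.concatenate(chosen))


def single_edge_type_dataset(
    corpus: SignalCorpus,
    kinds: frozenset,
    seed: int = 0,
    n_columns: int = 4,
) -> LabeledDataset:
    """Subset corpus for one edge type vs. the full full-field mixture.

    ``kinds`` is the unordered pair of :class:`ImageKind` forming the edge
    (e.g. {FLICKER, STATIC}); both left/right assignments and all catalog
    speeds of that pair are included.  Full-field patterns of every class
    are subsampled (scenario-stratified) to the same total as the edge
    patterns, preserving the 50% edge prior.
    """
    data = corpus_features(corpus, n_columns, "raw")
    meta = data.meta
    kind_of = {}
    for kind in ImageKind:
        kind_of[kind.value] = kind
    left_kinds = meta["left"].str.split("@").str[0].map(kind_of)
    right_kinds = meta["right"].str.split("@").str[0].map(kind_of)
    is_pair = np.array(
        [
            bool(l is not None and r is not None and frozenset([l, r]) == kinds)
            for l, r in zip(left_kinds, right_kinds)
        ]
    )
    edge_idx = np.flatnonzero((data.y == 1) & is_pair)
    if edge_idx.size == 0:
        raise ValueError("no edge scenarios match the requested pair")
    ff_idx = np.flatnonzero(data.y == 0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    ff_take = _stratified_sample(meta, ff_idx, edge_idx.size, rng)
    keep = np.sort(np.concatenate([edge_idx, ff_take]))
    return data.subset(keep)


def combined_dataset(
    fixed: SignalCorpus,
    moving: SignalCorpus,
    n_columns: int = 6,
    seed: int = 0,
) -> LabeledDataset:
    """Joint fixed+moving training set.

    The complete moving-edge corpus is augmented with an equal-sized,
    scenario-stratified subset of the fixed-edge data (all edge scenario
    classes represented) and the full-field half is doubled the same way.
    Features are raw signals from the ``n_columns`` central units of each
    array.  The meta column ``origin`` records the source corpus.
    """
    dm = corpus_features(moving, n_columns, "raw")
    df = corpus_features(fixed, n_columns, "raw")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    n_edge = int((dm.y == 1).sum())
    n_ff = int((dm.y == 0).sum())
    fix_edge = _stratified_sample(df.meta, np.flatnonzero(df.y == 1), n_edge, rng)
    fix_ff = _stratified_sample(df.meta, np.flatnonzero(df.y == 0), n_ff, rng)
    fix_keep = np.sort(np.concatenate([fix_edge, fix_ff]))
    dfix = df.subset(fix_keep)
    meta_m = dm.meta.copy()
    meta_m["origin"] = "moving"
    meta_f = dfix.meta.copy()
    meta_f["origin"] = "fixed"
    X = np.concatenate([dm.X, dfix.X], axis=0)
    y = np.concatenate([dm.y, dfix.y])
    meta = pd.concat([meta_m, meta_f], ignore_index=True)
    return LabeledDataset(X, y, meta, dm.feature_names)


# ---------------------------------------------------------------------------
# top-level regimen runner
# ---------------------------------------------------------------------------


class Regimen(Enum):
    FIXED = "fixed"
    MOVING = "moving"
    COMBINED = "combined"
    SINGLE_EDGE_TYPE = "single_edge_type"


@dataclass
class ExperimentConfig:
    """Declarative description of one training experiment."""

    regimen: Regimen = Regimen.FIXED
    n_columns: int = 2
    feature_mode: str = "raw"
    scale: float = DESK_SCALE
    seed: int = 0
    n_networks: int = 5
    n_hidden: int = 32
    train: TrainConfig = field(default_factory=lambda: desk_train_config(0))
    edge_kinds: Optional[frozenset] = None  # SINGLE_EDGE_TYPE only

    def __post_init__(self):
        if isinstance(self.regimen, str):
            self.regimen = Regimen(self.regimen)
        if self.regimen in (Regimen.MOVING, Regimen.COMBINED) and self.feature_mode != "raw":
            raise ValueError("moving and combined regimens use raw features only")


def run_regimen(cfg: ExperimentConfig, fixed: Optional[SignalCorpus] = None,
                moving: Optional[SignalCorpus] = None) -> dict:
    """Generate (or reuse) the corpora a regimen needs, train the network
    sample and return a report dict with per-network and summary scores."""
    if fixed is None:
        fixed = generate_fixed_corpus(cfg.scale, cfg.seed)
    needs_moving = cfg.regimen in (Regimen.MOVING, Regimen.COMBINED)
    if needs_moving and moving is None:
        moving = generate_moving_corpus(cfg.scale, cfg.seed, gains=fixed.gains)
    tcfg = cfg.train
    if cfg.regimen is Regimen.FIXED:
        data = corpus_features(fixed, cfg.n_columns, cfg.feature_mode)
        result = train_sample(data, tcfg, cfg.n_networks, cfg.n_hidden)
    elif cfg.regimen is Regimen.MOVING:
        data = corpus_features(moving, cfg.n_columns, "raw")
        result = train_sample(data, tcfg, cfg.n_networks, cfg.n_hidden)
    elif cfg.regimen is Regimen.COMBINED:
        data = combined_dataset(fixed, moving, cfg.n_columns, cfg.seed)
        result = train_sample(data, tcfg, cfg.n_networks, cfg.n_hidden)
    else:
        if cfg.edge_kinds is None:
            raise ValueError("SINGLE_EDGE_TYPE requires edge_kinds")
        full = corpus_features(fixed, cfg.n_columns, "raw")
        base = train_sample(full, tcfg, cfg.n_networks, cfg.n_hidden)
        data = single_edge_type_dataset(fixed, cfg.edge_kinds, cfg.seed, cfg.n_columns)
        cont = TrainConfig(
            eta0=tcfg.eta0, etae=tcfg.etae, epochs=tcfg.epochs, seed=tcfg.seed
        )
        result = train_sample(data, cont, cfg.n_networks, cfg.n_hidden,
                              init_nets=base.nets)
    report = result.summary()
    report["train_scores"] = result.train_scores.tolist()
    report["test_scores"] = result.test_scores.tolist()
    report["n_patterns"] = len(result.data)
    report["regimen"] = cfg.regimen.value
    report["_result"] = result
    return report


# ---------------------------------------------------------------------------
# desk-scale replication of the study's headline conditions
# ---------------------------------------------------------------------------


def desk_replication(seed: int, scale: float = DESK_SCALE, keep_objects: bool = False) -> dict:
    """Recompute the study's headline scores at desk scale, from scratch.

    Generates the fixed- and moving-edge corpora at the given scale, trains
    five-network samples under the shortened multi-start protocol
    (200 epochs) for every condition, and returns the scores as fractions:

    - ``fixed2_test`` / ``fixed4_test`` / ``fixed6_test``: raw-signal
      networks on the fixed-edge holdout, by receptive-field size.
    - ``single_static_train``: single-edge-type networks (flicker vs
      static), training score; ``single_dynamic_train``: same for the
      flicker vs leftward-motion pair.  Both continue from weights learned
      on the full 4-column corpus.
    - ``cross_fixed_to_moving`` / ``cross_moving_to_fixed``: six-column
      networks evaluated on the opposite regimen's training data.
    - ``combined_fixed_train`` / ``combined_moving_train``: jointly
      trained six-column networks scored on the fixed- and moving-origin
      portions of their training set.

    Every quantity also records the number of patterns it was measured on
    (key suffix ``_n``).  ``keep_objects`` additionally returns corpora and
    trained samples for further analysis.
    """
    ss = np.random.SeedSequence([seed, 909])
    sub = [int(s) for s in ss.generate_state(12)]
    out: dict = {"scale": scale, "seed": seed}

    fixed = generate_fixed_corpus(scale, seed=sub[0])
    moving = generate_moving_corpus(scale, seed=sub[1], gains=fixed.gains)
    d2 = corpus_features(fixed, 2, "raw")
    d4 = corpus_features(fixed, 4, "raw")
    d6 = corpus_features(fixed, 6, "raw")
    dm = corpus_features(moving, 6, "raw")

    res2 = train_sample(d2, desk_train_config(sub[2]))
    res4 = train_sample(d4, desk_train_config(sub[3]))
    res6 = train_sample(d6, desk_train_config(sub[4]))
    resm = train_sample(dm, desk_train_config(sub[5]))
    out["fixed2_test"] = float(res2.test_scores.mean())
    out["fixed2_test_n"] = len(res2.test_idx)
    out["fixed4_test"] = float(res4.test_scores.mean())
    out["fixed4_test_n"] = len(res4.test_idx)
    out["fixed6_test"] = float(res6.test_scores.mean())
    out["fixed6_test_n"] = len(res6.test_idx)
    out["fixed2_sd"] = float(res2.test_scores.std(ddof=1))
    out["fixed4_sd"] = float(res4.test_scores.std(ddof=1))
    out["moving6_train"] = float(resm.train_scores.mean())
    out["moving6_test"] = float(resm.test_scores.mean())
    out["moving6_test_n"] = len(resm.test_idx)

    # cross-generalization on the opposite regimen's training portion
    mov_train = dm.subset(resm.train_idx)
    fix_train = d6.subset(res6.train_idx)
    out["cross_fixed_to_moving"] = cross_generalize(res6, mov_train)
    out["cross_fixed_to_moving_n"] = len(mov_train)
    out["cross_moving_to_fixed"] = cross_generalize(resm, fix_train)
    out["cross_moving_to_fixed_n"] = len(fix_train)

    # combined regimen, scored by origin on the training portion
    dc = combined_dataset(fixed, moving, 6, seed=sub[6])
    resc = train_sample(dc, desk_train_config(sub[7]))
    tr_meta = dc.meta.iloc[resc.train_idx]
    for origin, key in (("fixed", "combined_fixed_train"), ("moving", "combined_moving_train")):
        idx = resc.train_idx[np.flatnonzero((tr_meta["origin"] == origin).to_numpy())]
        out[key] = float(
            np.mean([score(n, dc.X[idx], dc.y[idx]) for n in resc.nets])
        )
        out[key + "_n"] = len(idx)

    # single-edge-type regimens, continued from the full-corpus networks
    cont = TrainConfig(epochs=200, seed=sub[8])
    d_static = single_edge_type_dataset(
        fixed, frozenset({ImageKind.FLICKER, ImageKind.STATIC}), sub[9]
    )
    res_s = train_sample(d_static, cont, init_nets=res4.nets)
    out["single_static_train"] = float(res_s.train_scores.mean())
    out["single_static_train_n"] = len(res_s.train_idx)
    d_dyn = single_edge_type_dataset(
        fixed, frozenset({ImageKind.FLICKER, ImageKind.MOTION_LEFT}), sub[10]
    )
    res_d = train_sample(d_dyn, cont, init_nets=res4.nets)
    out["single_dynamic_train"] = float(res_d.train_scores.mean())
    out["single_dynamic_train_n"] = len(res_d.train_idx)

    if keep_objects:
        out["_objects"] = dict(
            fixed=fixed, moving=moving, d2=d2, d4=d4, d6=d6, dm=dm,
            res2=res2, res4=res4, res6=res6, resm=resm, resc=resc, dc=dc,
            res_single_static=res_s, res_single_dynamic=res_d,
        )
    return out
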