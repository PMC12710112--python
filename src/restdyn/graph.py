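"""Time-resolved community structure, graph cartography and brain states.

Each MTD coupling slice is partitioned with signed Louvain (best of
``n_restarts`` randomised runs).  From the partition, two node-level
cartography measures are computed on the positive couplings only:

* participation coefficient B(i, t) = 1 - sum_s (kappa_is / k_i)^2 —
  0 when all of a node's positive coupling lies in its own module,
  approaching 1 - 1/m for coupling spread evenly over m modules;
* module degree z-score W(i, t) — the node's within-module strength
  standardised against its module's distribution (0 for degenerate
  modules).

Cohort-mean B and W per time window are clustered (k-means, k = 2) into
integrated (high participation) and segregated states, whose dwell times
and transition counts summarise the temporal architecture of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._louvain import louvain_signed, modularity_signed
from .dynamics import CouplingTensor
from .io import ParcelMetadata, ValidationError

__all__ = [
    "CommunityTrajectory",
    "CartographyTrace",
    "StateSequence",
    "StateSummary",
    "time_resolved_partition",
    "node_cartography",
    "classify_states",
    "classify_states_cohort",
    "state_statistics",
    "subject_graph_summary",
]

INTEGRATED = "integrated"
SEGREGATED = "segregated"


@dataclass
class CommunityTrajectory:
    partitions: np.ndarray  # n_regions × T' module ids
    q_trace: np.ndarray  # T'
    gamma: float
    louvain_seed: int
    degenerate_windows: list[int] = field(default_factory=list)


@dataclass
class CartographyTrace:
    B: np.ndarray  # n_regions × T' participation coefficients
    W: np.ndarray  # n_regions × T' module degree z-scores
    zero_strength_flags: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class StateSequence:
    labels: np.ndarray  # T' array of INTEGRATED / SEGREGATED
    centroids: dict[str, tuple[float, float]]  # state -> (mean-B, mean-W)
    kmeans_seed: int
    tie_broken: bool = False


@dataclass
class StateSummary:
    dwell_windows: dict[str, float]
    dwell_seconds: dict[str, float]
    n_transitions: int
    fraction_time: dict[str, float]
    undefined_states: set[str] = field(default_factory=set)


def time_resolved_partition(
    coupling: CouplingTensor,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> CommunityTrajectory:
    """Louvain partition of every coupling slice, best Q of ``n_restarts``.

    An all-zero slice gets the all-singletons partition with Q = 0 and is
    flagged in ``degenerate_windows``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    vals = coupling.values
    if not np.isfinite(vals).all():
        raise ValidationError("coupling tensor contains non-finite values")
    n, _, t_len = vals.shape
    partitions = np.empty((n, t_len), dtype=np.int64)
    q_trace = np.empty(t_len)
    degenerate: list[int] = []
    rng = np.random.default_rng(seed)
    for t in range(t_len):
        W = vals[:, :, t].copy()
        np.fill_diagonal(W, 0.0)
        if not W.any():
            partitions[:, t] = np.arange(n)
            q_trace[t] = 0.0
            degenerate.append(t)
            continue
        best_q = -np.inf
        best_labels = None
        for _ in range(n_restarts):
            labels = louvain_signed(W, gamma=gamma, rng=rng)
            q = modularity_signed(W, labels, gamma=gamma)
            if q > best_q:
                best_q = q
                best_labels = labels
        partitions[:, t] = best_labels
        q_trace[t] = best_q
    return CommunityTrajectory(
        partitions=partitions,
        q_trace=q_trace,
        gamma=gamma,
        louvain_seed=seed,
        degenerate_windows=degenerate,
    )


def node_cartography(
    coupling: CouplingTensor, trajectory: CommunityTrajectory
) -> CartographyTrace:
    """Participation coefficient and module degree z-score per node/window.

    Both measures use positive couplings only; B is set to 0 (and flagged)
    for nodes with zero positive strength, and W is 0 wherever the module's
    within-strength standard deviation vanishes (singleton or uniform
    modules).
    """
    vals = coupling.values
    n, _, t_len = vals.shape
    if trajectory.partitions.shape != (n, t_len):
        raise ValidationError("partition shape does not match coupling tensor")
    B = np.zeros((n, t_len))
    Wz = np.zeros((n, t_len))
    flags: list[tuple[int, int]] = []
    rows = np.arange(n)
    for t in range(t_len):
        P = np.clip(vals[:, :, t], 0.0, None)
        np.fill_diagonal(P, 0.0)
        labels = trajectory.partitions[:, t]
        n_comm = labels.max() + 1
        onehot = np.zeros((n, n_comm))
        onehot[rows, labels] = 1.0
        kappa = P @ onehot  # strength of node i into module s
        k = kappa.sum(axis=1)
        ok = k > 0
        frac = np.zeros_like(kappa)
        frac[ok] = kappa[ok] / k[ok, None]
        B[:, t] = np.where(ok, 1.0 - (frac**2).sum(axis=1), 0.0)
        for i in np.flatnonzero(~ok):
            flags.append((int(i), t))
        own = kappa[rows, labels]
        counts = np.bincount(labels, minlength=n_comm).astype(float)
        mean_c = np.bincount(labels, weights=own, minlength=n_comm) / counts
        second = np.bincount(labels, weights=own**2, minlength=n_comm) / counts
        var_c = np.clip(second - mean_c**2, 0.0, None)
        sd_c = np.sqrt(var_c)
        scale = np.maximum(np.abs(own), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (own - mean_c[labels]) / sd_c[labels]
        degenerate = sd_c[labels] <= 1e-12 * np.maximum(scale, 1.0)
        Wz[:, t] = np.where(degenerate, 0.0, z)
    return CartographyTrace(B=B, W=Wz, zero_strength_flags=flags)


def _zscore_features(feats: np.ndarray) -> np.ndarray:
    """z-score feature columns; a zero-variance column is left at zero."""
    sd = feats.std(axis=0)
    tol = 1e-12 * np.maximum(1.0, np.abs(feats).max(axis=0))
    degenerate = sd <= tol
    if degenerate.all():
        raise ValidationError("zero variance in both state features")
    z = np.zeros_like(feats)
    nz = ~degenerate
    z[:, nz] = (feats[:, nz] - feats[:, nz].mean(axis=0)) / sd[nz]
    return z


def _mode_filter(binary: np.ndarray, window: int) -> np.ndarray:
    """Majority filter over a centred window; ties keep the current label."""
    if window <= 1:
        return binary
    half = window // 2
    out = binary.copy()
    csum = np.concatenate([[0], np.cumsum(binary)])
    for i in range(binary.size):
        lo, hi = max(0, i - half), min(binary.size, i + half + 1)
        frac = (csum[hi] - csum[lo]) / (hi - lo)
        if frac > 0.5:
            out[i] = 1
        elif frac < 0.5:
            out[i] = 0
    return out


def _label_clusters(
    assign: np.ndarray, mean_b: np.ndarray, mean_w: np.ndarray, k: int
):
    cent_b = np.array([mean_b[assign == c].mean() for c in range(k)])
    cent_w = np.array([mean_w[assign == c].mean() for c in range(k)])
    tie = bool(abs(cent_b[0] - cent_b[1]) <= 1e-12)
    integrated = int(np.argmin(cent_w)) if tie else int(np.argmax(cent_b))
    centroids = {
        INTEGRATED: (float(cent_b[integrated]), float(cent_w[integrated])),
        SEGREGATED: (float(cent_b[1 - integrated]), float(cent_w[1 - integrated])),
    }
    return integrated, centroids, tie


def classify_states(
    cartography: CartographyTrace,
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
    smooth_window: int = 0,
) -> StateSequence:
    """k-means classification of windows into integrated/segregated states.

    The per-window feature vector is (node-mean B, node-mean W), z-scored
    across time before clustering.  Because module degree z-scores sum to
    zero within every module, the node-mean W feature typically has
    (near-)zero variance; a zero-variance feature is left at zero rather
    than erroring, and an error is raised only when both features are
    degenerate.  The cluster whose centroid has the higher raw mean-B is
    labelled integrated; exact ties break to the lower mean-W.

    ``smooth_window`` > 1 applies a centred majority filter to the label
    sequence, suppressing state transitions shorter than the coupling
    estimator's temporal resolution (normally set to the MTD window).
    """
    if k != 2:
        raise NotImplementedError("the state taxonomy is two-state (k = 2)")
    mean_b = cartography.B.mean(axis=0)
    mean_w = cartography.W.mean(axis=0)
    t_len = mean_b.size
    if t_len < 2 * k:
        raise ValidationError(f"need at least {2 * k} windows, got {t_len}")
    z = _zscore_features(np.column_stack([mean_b, mean_w]))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(z)
    integrated_cluster, centroids, tie = _label_clusters(assign, mean_b, mean_w, k)
    binary = _mode_filter((assign == integrated_cluster).astype(int), smooth_window)
    labels = np.where(binary == 1, INTEGRATED, SEGREGATED)
    return StateSequence(
        labels=labels, centroids=centroids, kmeans_seed=seed, tie_broken=tie
    )


def classify_states_cohort(
    cartographies: list[CartographyTrace],
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
    smooth_window: int = 0,
) -> list[StateSequence]:
    """Pooled two-state classification across a cohort.

    Windows of all subjects are clustered together (features z-scored over
    the pooled windows, one shared pair of centroids), then split back into
    per-subject state sequences.  Unlike per-subject clustering, this
    remains well-posed for a subject who happens to spend the whole scan in
    a single state.
    """
    if k != 2:
        raise NotImplementedError("the state taxonomy is two-state (k = 2)")
    if not cartographies:
        raise ValidationError("empty cohort")
    mean_b = np.concatenate([c.B.mean(axis=0) for c in cartographies])
    mean_w = np.concatenate([c.W.mean(axis=0) for c in cartographies])
    if mean_b.size < 2 * k:
        raise ValidationError(f"need at least {2 * k} pooled windows")
    z = _zscore_features(np.column_stack([mean_b, mean_w]))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(z)
    integrated_cluster, centroids, tie = _label_clusters(assign, mean_b, mean_w, k)
    out: list[StateSequence] = []
    start = 0
    for cart in cartographies:
        t_len = cart.B.shape[1]
        sub = (assign[start : start + t_len] == integrated_cluster).astype(int)
        start += t_len
        sub = _mode_filter(sub, smooth_window)
        labels = np.where(sub == 1, INTEGRATED, SEGREGATED)
        out.append(
            StateSequence(
                labels=labels, centroids=centroids, kmeans_seed=seed, tie_broken=tie
            )
        )
    return out


def _run_lengths(labels: np.ndarray) -> dict[str, list[int]]:
    runs: dict[str, list[int]] = {}
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.setdefault(str(labels[start]), []).append(i - start)
            start = i
    return runs


def state_statistics(states: StateSequence, tr_seconds: float) -> StateSummary:
    """Mean dwell time per state, transition count and time fractions."""
    labels = states.labels
    if labels.size == 0:
        raise ValidationError("empty state sequence")
    runs = _run_lengths(labels)
    n_transitions = int((labels[1:] != labels[:-1]).sum())
    dwell_windows: dict[str, float] = {}
    fractions: dict[str, float] = {}
    undefined: set[str] = set()
    for state in (INTEGRATED, SEGREGATED):
        if state in runs:
            dwell_windows[state] = float(np.mean(runs[state]))
            fractions[state] = float((labels == state).sum() / labels.size)
        else:
            dwell_windows[state] = float("nan")
            fractions[state] = 0.0
            undefined.add(state)
    dwell_seconds = {s: d * tr_seconds for s, d in dwell_windows.items()}
    return StateSummary(
        dwell_windows=dwell_windows,
        dwell_seconds=dwell_seconds,
        n_transitions=n_transitions,
        fraction_time=fractions,
        undefined_states=undefined,
    )


def subject_graph_summary(
    trajectory: CommunityTrajectory,
    cartography: CartographyTrace,
    meta: ParcelMetadata | None = None,
    region_labels: list[str] | None = None,
) -> dict[str, float]:
    """Scalar per-subject summaries handed to group inference.

    Time-means of Q, node-mean B and node-mean W; with metadata, also the
    per-network time-mean of the node-mean B and W.
    """
    out = {
        "mean_Q": float(trajectory.q_trace.mean()),
        "mean_B": float(cartography.B.mean()),
        "mean_W": float(cartography.W.mean()),
    }
    if meta is not None:
        if region_labels is None:
            raise ValueError("network summaries need the tensor's region labels")
        net_of = meta.network_of()
        for net in meta.networks:
            rows = [i for i, lab in enumerate(region_labels) if net_of.get(lab) == net]
            if rows:
                out[f"mean_B_{net}"] = float(cartography.B[rows].mean())
                out[f"mean_W_{net}"] = float(cartography.W[rows].mean())
    return out
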