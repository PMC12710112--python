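"""Static functional connectivity and its network-level aggregations.

Static FC is the Pearson correlation of two regions' BOLD series over the
full scan.  Four aggregation levels are provided: whole-cortex mean,
network-to-cortex mean, internetwork (block) means including within-network
self-pairs, and seed-to-network means for the subcortical NBM/LC/BG seeds.
Self-correlations (the matrix diagonal) are excluded from every average.
By default averages are taken on raw r; Fisher-z averaging is available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ParcellatedSeries, ParcelMetadata, ValidationError

__all__ = [
    "ConnectivityMatrix",
    "NetworkAggregates",
    "fc_matrix",
    "network_aggregates",
    "seed_to_network_fc",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region × region Pearson correlation matrix (diagonal = 1)."""

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-10:
            raise ValidationError("correlations must lie in [-1, 1]")
        self.values = v

    def index_of(self, labels: list[str]) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.region_labels)}
        missing = [lab for lab in labels if lab not in lookup]
        if missing:
            raise ValidationError(f"matrix lacks regions: {missing[:5]}")
        return np.array([lookup[lab] for lab in labels], dtype=int)


@dataclass
class NetworkAggregates:
    """The four aggregation levels of a static FC matrix.

    ``internetwork`` is keyed by sorted network-name pairs; the self-pair
    ``(N, N)`` is the within-network mean.  A within-network value for a
    single-region network is undefined and reported in
    ``undefined_within`` instead (NaN in the mapping).
    """

    whole_cortex_fc: float
    network_to_cortex_fc: dict[str, float]
    internetwork_fc: dict[tuple[str, str], float]
    seed_to_network_fc: dict[tuple[str, str], float] = field(default_factory=dict)
    undefined_within: set[str] = field(default_factory=set)
    fisher_z: bool = False


def _mean(values: np.ndarray, fisher_z: bool) -> float:
    if fisher_z:
        z = np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))
        return float(np.tanh(z.mean()))
    return float(values.mean())


def fc_matrix(series: ParcellatedSeries) -> ConnectivityMatrix:
    """Pearson correlation of every region pair over the full scan."""
    x = series.values
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [series.region_labels[i] for i in dead[:5]]
        raise ValidationError(f"zero-variance regions: {names}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(series.region_labels))


def network_aggregates(
    fc: ConnectivityMatrix, meta: ParcelMetadata, fisher_z: bool = False
) -> NetworkAggregates:
    """Aggregate a cortical FC matrix to whole-cortex / network level.

    whole-cortex: mean over all unordered distinct cortical pairs.
    network-to-cortex(N): mean over nodes i in N of the mean of fc(i, j)
    over all cortical j ≠ i (the network's own pairs included; only the
    self-node is excluded).
    internetwork(N, M), N ≠ M: mean over all pairs i in N, j in M.
    within-network(N): mean over unordered distinct pairs inside N;
    undefined (NaN, flagged) when N has a single region.
    """
    cortical = meta.cortical_labels
    if not cortical:
        raise ValidationError("metadata has no cortical regions")
    idx = fc.index_of(cortical)
    sub = fc.values[np.ix_(idx, idx)]
    n = len(cortical)
    if n < 2:
        raise ValidationError("need at least two cortical regions")
    off = ~np.eye(n, dtype=bool)

    whole = _mean(sub[np.triu_indices(n, k=1)], fisher_z)

    net_of = meta.network_of()
    networks = meta.networks
    members: dict[str, np.ndarray] = {}
    for net in networks:
        m = np.array([i for i, lab in enumerate(cortical) if net_of[lab] == net])
        if m.size == 0:
            raise ValidationError(f"empty network {net!r}")
        members[net] = m

    net_to_cortex: dict[str, float] = {}
    for net, m in members.items():
        rows = sub[m]  # each row: node's correlations to all cortical nodes
        node_means = (rows.sum(axis=1) - 1.0) / (n - 1)  # drop the self r=1
        if fisher_z:
            # average at the node level on z scale for consistency
            per_node = [
                _mean(np.delete(sub[i], i), True) for i in m
            ]
            net_to_cortex[net] = _mean(np.array(per_node), True)
        else:
            net_to_cortex[net] = float(node_means.mean())

    internetwork: dict[tuple[str, str], float] = {}
    undefined: set[str] = set()
    for a_i, net_a in enumerate(networks):
        for net_b in networks[a_i:]:
            ma, mb = members[net_a], members[net_b]
            if net_a == net_b:
                if ma.size < 2:
                    undefined.add(net_a)
                    internetwork[(net_a, net_b)] = float("nan")
                    continue
                block = sub[np.ix_(ma, ma)]
                vals = block[np.triu_indices(ma.size, k=1)]
            else:
                vals = sub[np.ix_(ma, mb)].ravel()
            key = tuple(sorted((net_a, net_b)))
            internetwork[key] = _mean(vals, fisher_z)

    return NetworkAggregates(
        whole_cortex_fc=whole,
        network_to_cortex_fc=net_to_cortex,
        internetwork_fc=internetwork,
        undefined_within=undefined,
        fisher_z=fisher_z,
    )


def seed_to_network_fc(
    fc_with_seeds: ConnectivityMatrix,
    meta: ParcelMetadata,
    fisher_z: bool = False,
) -> dict[tuple[str, str], float]:
    """Mean FC from each subcortical seed to the nodes of each network."""
    seeds = meta.seed_labels
    if not seeds:
        raise ValidationError("metadata declares no subcortical seeds")
    seed_idx = fc_with_seeds.index_of(seeds)
    cortical = meta.cortical_labels
    cort_idx = fc_with_seeds.index_of(cortical)
    net_of = meta.network_of()
    seed_name = dict(
        zip(
            meta.frame.loc[meta.frame["role"] == "subcortical_seed", "region_label"],
            meta.frame.loc[meta.frame["role"] == "subcortical_seed", "network"],
        )
    )
    out: dict[tuple[str, str], float] = {}
    for s_lab, s_i in zip(seeds, seed_idx):
        row = fc_with_seeds.values[s_i, cort_idx]
        for net in meta.networks:
            m = np.array([k for k, lab in enumerate(cortical) if net_of[lab] == net])
            out[(seed_name[s_lab], net)] = _mean(row[m], fisher_z)
    return out
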