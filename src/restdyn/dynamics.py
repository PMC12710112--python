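"""Time-resolved dynamics: configuration similarity and MTD coupling.

Two families of measures:

* spatial-configuration similarity — the T × T matrix of Pearson
  correlations between whole-brain activity patterns at pairs of
  timepoints.  Local similarity (S_L) is the mean over consecutive-pair
  entries and indexes how stationary the configuration is from one TR to
  the next; global similarity (S_G) is the mean over all off-diagonal
  entries and indexes configuration variability over the whole scan.

* multiplication of temporal derivatives (MTD) — a time-resolved coupling
  estimate.  Each region's series is z-scored, first-differenced, and the
  pointwise product of two regions' derivatives is normalised by the
  product of their derivative standard deviations, then smoothed with a
  centred simple moving average (default window 15 TRs, truncated at the
  scan edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ParcellatedSeries, ValidationError

__all__ = ["SimilarityResult", "CouplingTensor", "spatial_similarity", "mtd_coupling"]


@dataclass
class SimilarityResult:
    similarity_matrix: np.ndarray  # T × T, symmetric, unit diagonal
    s_local: float
    s_global: float


@dataclass
class CouplingTensor:
    """Windowed MTD coupling, region × region × derivative timepoint."""

    values: np.ndarray  # n_regions × n_regions × (T - 1)
    window_length: int
    tr_seconds: float
    region_labels: list[str]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


def spatial_similarity(
    series: ParcellatedSeries, cortical_only: bool = False, meta=None
) -> SimilarityResult:
    """Correlate whole-brain spatial configurations across timepoints.

    With ``cortical_only`` the configuration vectors are restricted to the
    cortical regions of ``meta``.
    """
    x = series.values
    labels = series.region_labels
    if cortical_only:
        if meta is None:
            raise ValueError("cortical_only requires parcel metadata")
        keep = set(meta.cortical_labels)
        rows = [i for i, lab in enumerate(labels) if lab in keep]
        x = x[rows]
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 regions for spatial similarity")
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 timepoints")
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(f"constant spatial pattern at timepoint {flat[0]}")
    sim = np.corrcoef(x.T)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    t = sim.shape[0]
    s_local = float(np.diagonal(sim, offset=1).mean())
    s_global = float(sim[np.triu_indices(t, k=1)].mean())
    return SimilarityResult(sim, s_local, s_global)


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along the last axis with truncated edges."""
    t = x.shape[-1]
    half = window // 2
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    lo = np.maximum(np.arange(t) - half, 0)
    hi = np.minimum(np.arange(t) + half + 1, t)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def mtd_coupling(
    series: ParcellatedSeries,
    window_length: int = 15,
    demean_derivatives: bool = True,
    edge_mode: str = "truncate",
) -> CouplingTensor:
    """Multiplication-of-temporal-derivatives coupling tensor.

    For regions i, j and derivative timepoint t the raw score is
    ``Δi(t)·Δj(t) / (σ(Δi)·σ(Δj))`` where Δ is the first difference of the
    z-scored series and σ its whole-scan (population) standard deviation.
    The stored tensor is the centred moving average of the raw score over
    ``window_length`` derivative points.  With ``demean_derivatives`` the
    derivative mean is removed before both the products and σ, which makes
    the time-averaged self-coupling exactly 1.

    ``edge_mode='truncate'`` shortens windows near the scan edges;
    ``'valid'`` drops edge windows instead.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if edge_mode not in ("truncate", "valid"):
        raise ValueError("edge_mode must be 'truncate' or 'valid'")
    x = series.values
    if x.shape[1] < window_length + 1:
        raise ValidationError(
            f"need at least window_length+1={window_length + 1} timepoints, "
            f"got {x.shape[1]}"
        )
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(
            f"zero-variance region {series.region_labels[dead[0]]!r}"
        )
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    d = np.diff(z, axis=1)
    if demean_derivatives:
        d = d - d.mean(axis=1, keepdims=True)
    dsd = d.std(axis=1)
    dead = np.flatnonzero(dsd <= 1e-12 * np.abs(d).max(initial=1.0))
    if dead.size:
        raise ValidationError(
            f"zero derivative variance in region {series.region_labels[dead[0]]!r}"
        )
    dn = d / dsd[:, None]
    raw = np.einsum("it,jt->ijt", dn, dn)
    if edge_mode == "truncate":
        smooth = _moving_average_truncated(raw, window_length)
    else:
        half = window_length // 2
        smooth = _moving_average_truncated(raw, window_length)
        smooth = smooth[..., half : raw.shape[-1] - half]
    return CouplingTensor(
        values=smooth,
        window_length=window_length,
        tr_seconds=series.tr_seconds,
        region_labels=list(series.region_labels),
    )
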