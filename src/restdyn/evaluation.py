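"""Planted-truth recovery experiments and worked-example checks.

These routines exercise the pipeline end-to-end on synthetic data whose
generating parameters are known, and return the recovered quantities so
they can be compared against the planted values.  They are used by the
acceptance test suite and by ``scripts/acceptance.py``; none of them read
anything from disk.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from ._louvain import louvain_signed, modularity_signed
from .dynamics import mtd_coupling, spatial_similarity
from .graph import (
    INTEGRATED,
    SEGREGATED,
    classify_states,
    classify_states_cohort,
    node_cartography,
    time_resolved_partition,
)
from .inference import (
    CohortDesign,
    cox_conversion,
    cross_sectional_glm,
    fdr_adjust,
    longitudinal_lmm,
)
from .io import ParcellatedSeries, ParcelMetadata
from .receptors import dominance_analysis, spearman_map_correlation
from .simulate import (
    SimulationSpec,
    StateSchedule,
    simulate_bold_cohort,
    simulate_outcomes,
    simulate_receptor_maps,
)
from .static import fc_matrix, network_aggregates

__all__ = [
    "exhaustive_best_partition",
    "participation_bruteforce",
    "module_zscore_bruteforce",
    "two_clique_modularity",
    "louvain_vs_exhaustive_gap",
    "cartography_bruteforce_gap",
    "mtd_worked_examples",
    "similarity_worked_examples",
    "static_identity_gap",
    "state_recovery_experiment",
    "lmm_slope_recovery",
    "glm_coverage",
    "glm_type1_error",
    "cox_hr_coverage",
    "cox_null_mean_hr",
    "receptor_rho_recovery",
    "dominance_sum_gap",
    "bh_worked_examples_gap",
    "visual_deficit_top_rate",
]


# ---------------------------------------------------------------------------
# brute-force graph oracles


def _set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1)


def exhaustive_best_partition(W: np.ndarray, gamma: float = 1.0):
    """Globally optimal signed modularity by set-partition enumeration (n <= 10)."""
    n = W.shape[0]
    if n > 10:
        raise ValueError("exhaustive search limited to 10 nodes")
    best_q, best_labels = -np.inf, None
    for labels in _set_partitions(n):
        q = modularity_signed(W, labels, gamma=gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, float(best_q)


def participation_bruteforce(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Participation coefficient by direct formula loops (positive weights)."""
    n = W.shape[0]
    P = np.clip(np.asarray(W, float), 0.0, None).copy()
    np.fill_diagonal(P, 0.0)
    out = np.zeros(n)
    for i in range(n):
        k_i = P[i].sum()
        if k_i == 0:
            out[i] = 0.0
            continue
        acc = 0.0
        for s in np.unique(labels):
            kappa = P[i, labels == s].sum()
            acc += (kappa / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def module_zscore_bruteforce(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Module degree z-score by direct formula loops (positive weights)."""
    n = W.shape[0]
    P = np.clip(np.asarray(W, float), 0.0, None).copy()
    np.fill_diagonal(P, 0.0)
    own = np.array([P[i, labels == labels[i]].sum() for i in range(n)])
    out = np.zeros(n)
    for s in np.unique(labels):
        members = np.flatnonzero(labels == s)
        mu = own[members].mean()
        sd = own[members].std()
        for i in members:
            out[i] = 0.0 if sd <= 1e-12 * max(1.0, abs(own[i])) else (own[i] - mu) / sd
    return out


def two_clique_graph(clique_size: int = 3) -> np.ndarray:
    n = 2 * clique_size
    W = np.zeros((n, n))
    for blk in (range(clique_size), range(clique_size, n)):
        for i in blk:
            for j in blk:
                if i != j:
                    W[i, j] = 1.0
    return W


def two_clique_modularity(seed: int = 0) -> float:
    """Louvain Q on two disconnected 3-cliques (hand value: 0.5)."""
    W = two_clique_graph()
    labels = louvain_signed(W, rng=seed)
    return modularity_signed(W, labels)


def louvain_vs_exhaustive_gap(
    seed: int, n_graphs: int = 10, n_nodes: int = 6, n_restarts: int = 10
) -> float:
    """max(Q_louvain - Q_exhaustive) over random signed graphs (must be <= 0)."""
    rng = np.random.default_rng(seed)
    worst = -np.inf
    for _ in range(n_graphs):
        A = rng.normal(size=(n_nodes, n_nodes))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        _, q_star = exhaustive_best_partition(W)
        q_best = max(
            modularity_signed(W, louvain_signed(W, rng=rng))
            for _ in range(n_restarts)
        )
        worst = max(worst, q_best - q_star)
    return float(worst)


def cartography_bruteforce_gap(seed: int, n_graphs: int = 10, n_nodes: int = 12):
    """Max |vectorized - brute force| for B and W on random toy graphs."""
    from .dynamics import CouplingTensor
    from .graph import CommunityTrajectory

    rng = np.random.default_rng(seed)
    gap_b = gap_w = 0.0
    for _ in range(n_graphs):
        A = rng.normal(size=(n_nodes, n_nodes))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = rng.integers(0, 3, size=n_nodes)
        tensor = CouplingTensor(
            values=W[:, :, None],
            window_length=1,
            tr_seconds=1.0,
            region_labels=[f"r{i}" for i in range(n_nodes)],
        )
        traj = CommunityTrajectory(
            partitions=labels[:, None],
            q_trace=np.zeros(1),
            gamma=1.0,
            louvain_seed=0,
        )
        cart = node_cartography(tensor, traj)
        gap_b = max(gap_b, np.abs(cart.B[:, 0] - participation_bruteforce(W, labels)).max())
        gap_w = max(gap_w, np.abs(cart.W[:, 0] - module_zscore_bruteforce(W, labels)).max())
    return float(gap_b), float(gap_w)


# ---------------------------------------------------------------------------
# worked examples


def _toy_series(values: np.ndarray, tr: float = 1.0) -> ParcellatedSeries:
    return ParcellatedSeries(
        subject_id="toy",
        visit_id="V1",
        tr_seconds=tr,
        values=np.asarray(values, dtype=float),
        region_labels=[f"r{i}" for i in range(np.asarray(values).shape[0])],
    )


def mtd_worked_examples(seed: int, t_noise: int = 5000) -> dict[str, float]:
    """In-phase, anti-phase and independent-noise MTD couplings."""
    x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    pair = _toy_series(np.vstack([x, x]))
    tensor = mtd_coupling(pair, window_length=3)
    inphase = float(tensor.values[0, 1].mean())
    anti = _toy_series(np.vstack([x, -x]))
    antiphase = float(mtd_coupling(anti, window_length=3).values[0, 1].mean())
    rng = np.random.default_rng(seed)
    noise = _toy_series(rng.standard_normal((2, t_noise)))
    noise_mean = float(mtd_coupling(noise, window_length=15).values[0, 1].mean())
    return {
        "inphase_coupling": inphase,
        "inphase_min": float(tensor.values[0, 1].min()),
        "inphase_max": float(tensor.values[0, 1].max()),
        "antiphase_coupling": antiphase,
        "noise_time_mean": noise_mean,
    }


def similarity_worked_examples() -> dict[str, float]:
    p = np.array([1.0, -0.5, 2.0])
    constant = _toy_series(np.tile(p[:, None], (1, 5)))
    res_const = spatial_similarity(constant)
    alternating = _toy_series(np.column_stack([p, -p, p, -p]))
    res_alt = spatial_similarity(alternating)
    return {
        "constant_s_local": res_const.s_local,
        "constant_s_global": res_const.s_global,
        "alternating_s_local": res_alt.s_local,
        "alternating_s_global": res_alt.s_global,
    }


def static_identity_gap(seed: int, n_matrices: int = 100, n_regions: int = 24) -> float:
    """Whole-cortex FC vs pair-count-weighted mean of block means (exact identity)."""
    from .static import ConnectivityMatrix

    rng = np.random.default_rng(seed)
    networks = ["n1", "n2", "n3", "n4"]
    sizes = [4, 6, 6, 8]
    rows = []
    labels = []
    for net, sz in zip(networks, sizes):
        for k in range(sz):
            lab = f"{net}_r{k}"
            labels.append(lab)
            rows.append(
                {"region_label": lab, "role": "cortical", "network": net,
                 "hemisphere": "L"}
            )
    meta = ParcelMetadata(pd.DataFrame(rows))
    worst = 0.0
    for _ in range(n_matrices):
        a = rng.uniform(-1, 1, size=(n_regions, n_regions))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        fc = ConnectivityMatrix(np.clip(r, -1, 1), labels)
        agg = network_aggregates(fc, meta)
        total_pairs = 0
        acc = 0.0
        for i, na in enumerate(networks):
            for nb in networks[i:]:
                key = tuple(sorted((na, nb)))
                sa, sb = sizes[i], sizes[networks.index(nb)]
                n_pairs = sa * (sa - 1) // 2 if na == nb else sa * sb
                acc += n_pairs * agg.internetwork_fc[key]
                total_pairs += n_pairs
        worst = max(worst, abs(agg.whole_cortex_fc - acc / total_pairs))
    return float(worst)


# ---------------------------------------------------------------------------
# planted-state recovery (dynamic pipeline end-to-end)


def state_recovery_experiment(
    seed: int,
    n_subjects: int = 20,
    n_regions: int = 80,
    n_timepoints: int = 500,
    window_length: int = 15,
    n_restarts: int = 10,
    gamma: float = 1.5,
) -> dict[str, float]:
    """Recover the planted integrated/segregated regimes from MTD cartography.

    The Louvain resolution defaults to 1.5 here, matching the planted module
    scale (modules of n/8 nodes in a dense weighted graph are merged at the
    default resolution of 1 under windowed-estimate noise; see the methods
    note).  Returns the pooled window-label agreement with the planted
    regimes, the relative error of the pooled recovered mean dwell time
    against the realized ground-truth dwell, and the fraction of subjects
    whose mean participation is strictly higher during planted integrated
    windows.
    """
    spec = SimulationSpec(
        n_cases=n_subjects,
        n_controls=0,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        network_sizes=None,
        include_seeds=False,
        group_effect=0.0,
        seed=seed,
    )
    cohort = simulate_bold_cohort(spec)
    carts = []
    truths = []
    for s in cohort.series:
        key = f"{s.subject_id}__{s.visit_id}"
        regimes = np.asarray(cohort.ground_truth["regime_labels"][key])
        tensor = mtd_coupling(s, window_length=window_length)
        traj = time_resolved_partition(
            tensor, gamma=gamma, seed=seed, n_restarts=n_restarts
        )
        carts.append(node_cartography(tensor, traj))
        truths.append(
            np.where(regimes[: tensor.n_windows] == 1, INTEGRATED, SEGREGATED)
        )
    # pooled two-state clustering with label smoothing at the coupling
    # estimator's temporal resolution (see methods note)
    state_seqs = classify_states_cohort(
        carts, seed=seed, smooth_window=window_length
    )
    agree = 0
    total = 0
    rec_runs: list[int] = []
    true_runs: list[int] = []
    b_contrast_ok = 0
    n_contrast = 0
    for cart, states, truth in zip(carts, state_seqs, truths):
        agree += int((states.labels == truth).sum())
        total += len(truth)
        rec_runs.extend(_runs(states.labels))
        true_runs.extend(_runs(truth))
        mean_b = cart.B.mean(axis=0)
        in_mask = truth == INTEGRATED
        if in_mask.any() and (~in_mask).any():
            n_contrast += 1
            if mean_b[in_mask].mean() > mean_b[~in_mask].mean():
                b_contrast_ok += 1
    rec_dwell = float(np.mean(rec_runs))
    true_dwell = float(np.mean(true_runs))
    return {
        "agreement": agree / total,
        "recovered_dwell": rec_dwell,
        "true_dwell": true_dwell,
        "dwell_rel_error": abs(rec_dwell - true_dwell) / true_dwell,
        "b_contrast_rate": b_contrast_ok / max(n_contrast, 1),
    }


def _runs(labels: np.ndarray) -> list[int]:
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append(i - start)
            start = i
    return out


# ---------------------------------------------------------------------------
# inference recovery experiments


def _covariate_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(66, 7, size=n),
            "sex": np.where(rng.random(n) < 0.6, "M", "F"),
            "education": rng.normal(14, 3, size=n),
        }
    )


def lmm_slope_recovery(
    seed: int,
    n_seeds: int = 100,
    slope: float = -0.002,
    n_subjects: int = 40,
    visit_months: tuple[float, ...] = (0.0, 24.0, 48.0),
    intercept_sd: float = 0.1,
    resid_sd: float = 0.05,
) -> dict[str, float]:
    """Fraction of replicates recovering the planted monthly slope.

    Success = correct sign and estimate within ±50% of the planted value.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        cov = _covariate_frame(rng, n_subjects)
        rows = []
        y = []
        b = rng.normal(0, intercept_sd, size=n_subjects)
        for i in range(n_subjects):
            for months in visit_months:
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "months_from_baseline": months,
                        "age": cov["age"][i],
                        "sex": cov["sex"][i],
                        "education": cov["education"][i],
                    }
                )
                y.append(0.5 + b[i] + slope * months + rng.normal(0, resid_sd))
        frame = pd.DataFrame(rows)
        res = longitudinal_lmm(
            pd.Series(y), frame, CohortDesign(outcome="metric")
        )
        if np.sign(res.estimate) == np.sign(slope) and abs(res.estimate - slope) <= 0.5 * abs(slope):
            hits += 1
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def _glm_frame(rng: np.random.Generator, n: int, beta: float) -> tuple[pd.Series, pd.DataFrame]:
    cov = _covariate_frame(rng, n)
    group = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
    y = beta * (group == "case") + rng.standard_normal(n)
    frame = cov.copy()
    frame["subject_id"] = [f"s{i}" for i in range(n)]
    frame["group"] = group
    return pd.Series(y, index=frame["subject_id"]), frame


def glm_coverage(seed: int, n_reps: int = 100, beta: float = 0.5, n: int = 200) -> float:
    """Fraction of replicates whose 95% CI covers the planted group effect."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        y, frame = _glm_frame(rng, n, beta)
        res = cross_sectional_glm(y, frame, CohortDesign(outcome="metric"))
        lo, hi = res.conf_int
        hits += int(lo <= beta <= hi)
    return hits / n_reps


def glm_type1_error(seed: int, n_reps: int = 1000, n: int = 200, alpha: float = 0.05) -> float:
    """Null rejection rate of the group term at the given alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        y, frame = _glm_frame(rng, n, beta=0.0)
        res = cross_sectional_glm(y, frame, CohortDesign(outcome="metric"))
        rejections += int(res.p_value < alpha)
    return rejections / n_reps


def _cox_cohort(measure: pd.Series, outcomes: pd.DataFrame) -> pd.DataFrame:
    frame = outcomes.copy()
    frame["group"] = "case"
    frame["visit_id"] = "V1"
    frame["months_from_baseline"] = 0.0
    frame["age"] = 65.0
    frame["sex"] = "M"
    frame["education"] = 14.0
    return frame


def cox_hr_coverage(
    seed: int,
    n_reps: int = 100,
    hazard_ratio: float = 1.66,
    n: int = 500,
    censor_rate: float = 0.6,
) -> float:
    """Fraction of replicates whose fitted 95% CI covers the planted HR/SD."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        measure = pd.Series(
            rng.standard_normal(n), index=[f"s{i}" for i in range(n)]
        )
        outcomes = simulate_outcomes(
            measure,
            log_hazard_per_sd=math.log(hazard_ratio),
            censor_rate=censor_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = cox_conversion(measure, _cox_cohort(measure, outcomes))
        lo, hi = res.hazard_ratio_ci
        hits += int(lo <= hazard_ratio <= hi)
    return hits / n_reps


def cox_null_mean_hr(
    seed: int, n_reps: int = 20, n: int = 500, censor_rate: float = 0.6
) -> float:
    """Mean fitted HR over a null seed batch (no planted effect)."""
    rng = np.random.default_rng(seed)
    hrs = []
    for _ in range(n_reps):
        measure = pd.Series(
            rng.standard_normal(n), index=[f"s{i}" for i in range(n)]
        )
        outcomes = simulate_outcomes(
            measure,
            log_hazard_per_sd=0.0,
            censor_rate=censor_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = cox_conversion(measure, _cox_cohort(measure, outcomes))
        hrs.append(res.hazard_ratio)
    return float(np.mean(hrs))


# ---------------------------------------------------------------------------
# receptor mapping


def receptor_rho_recovery(
    seed: int, planted_rho: float = 0.5, n_regions: int = 400
) -> float:
    """Empirical Spearman rho of a planted-correlation receptor map."""
    rng = np.random.default_rng(seed)
    effect = pd.Series(
        rng.standard_normal(n_regions),
        index=[f"r{i}" for i in range(n_regions)],
    )
    table = simulate_receptor_maps(
        effect, planted_rho=planted_rho, n_maps=1,
        seed=int(rng.integers(2**31 - 1)),
    )
    res = spearman_map_correlation(effect, table)
    return float(res.correlations["rho"].iloc[0])


def dominance_sum_gap(seed: int, n_regions: int = 400, n_maps: int = 5) -> float:
    """|sum of dominance weights - full-model R²| on random maps."""
    rng = np.random.default_rng(seed)
    effect = pd.Series(
        rng.standard_normal(n_regions), index=[f"r{i}" for i in range(n_regions)]
    )
    table = simulate_receptor_maps(
        effect,
        planted_rho=list(rng.uniform(-0.5, 0.5, size=n_maps)),
        n_maps=n_maps,
        seed=int(rng.integers(2**31 - 1)),
    )
    res = dominance_analysis(effect, table)
    return abs(sum(res.dominance.values()) - res.total_r2)


def bh_worked_examples_gap() -> float:
    """Max deviation from the hand-worked BH adjustments."""
    got1 = fdr_adjust([0.005, 0.02, 0.04])
    got2 = fdr_adjust([0.01, 0.02, 0.03])
    expect1 = np.array([0.015, 0.03, 0.04])
    expect2 = np.array([0.03, 0.03, 0.03])
    return float(
        max(np.abs(got1 - expect1).max(), np.abs(got2 - expect2).max())
    )


# ---------------------------------------------------------------------------
# end-to-end directional property


def visual_deficit_top_rate(
    seed: int,
    n_seeds: int = 20,
    n_cases: int = 20,
    n_controls: int = 20,
    n_regions: int = 80,
    n_timepoints: int = 300,
) -> float:
    """Fraction of seeds in which the planted within-visual deficit is the
    most significant internetwork contrast (smallest GLM p over 36 cells)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        spec = SimulationSpec(
            n_cases=n_cases,
            n_controls=n_controls,
            n_regions=n_regions,
            n_timepoints=n_timepoints,
            include_seeds=False,
            seed=int(rng.integers(2**31 - 1)),
        )
        cohort = simulate_bold_cohort(spec)
        meta = cohort.metadata
        per_subject: dict[str, dict] = {}
        for s in cohort.series:
            agg = network_aggregates(fc_matrix(s), meta)
            per_subject[s.subject_id] = agg.internetwork_fc
        frame = cohort.cohort.frame
        design = CohortDesign(outcome="fc")
        best_p, best_cell = np.inf, None
        cells = sorted(next(iter(per_subject.values())).keys())
        for cell in cells:
            metric = pd.Series(
                {sid: vals[cell] for sid, vals in per_subject.items()}
            )
            res = cross_sectional_glm(metric, frame, design)
            if res.p_value < best_p:
                best_p, best_cell = res.p_value, cell
        if best_cell == ("visual", "visual"):
            hits += 1
    return hits / n_seeds
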