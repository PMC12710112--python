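"""Synthetic cohort generation with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, not haemodynamics: BOLD is zero-mean Gaussian with a block
covariance built from one global factor (between-network coupling) and one
factor per network (within-network coupling).  A two-state Markov schedule
switches the global factor's weight between an integrated regime (elevated
between-network coupling) and a segregated regime (suppressed
between-network coupling).  Case status, visit month and a subject-level
random intercept perturb the within-network couplings, receptor maps are
planted with a chosen population Spearman correlation to a regional effect
map via a Gaussian rank copula, and conversion times follow an exponential
proportional-hazards model on a z-scored baseline measure.

Defaults mirror the modelled cohort where its composition is known (41
cases / 38 controls, 400 cortical regions in eight networks, NBM/LC/BG
seeds, planted hazard ratio 1.66 per SD, roughly 60% censoring) and are
otherwise field-realistic choices documented in the methods note.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CANONICAL_RECEPTOR_MAPS,
    CohortTable,
    ParcelMetadata,
    ParcellatedSeries,
    ReceptorTable,
    write_cohort_table,
    write_parcel_metadata,
    write_parcellated_series,
    write_receptor_table,
)

__all__ = [
    "SpecError",
    "StateSchedule",
    "SimulationSpec",
    "SyntheticCohort",
    "simulate_bold_cohort",
    "simulate_receptor_maps",
    "simulate_outcomes",
    "DEFAULT_NETWORKS",
    "DEFAULT_RECEPTOR_RHO",
]

DEFAULT_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "temporal",
    "frontoparietal",
    "default_mode",
)

#: Planted Spearman correlations between the regional effect map and each
#: receptor map; the cholinergic/noradrenergic transporters carry the
#: strongest planted association and the dopaminergic maps are near-null.
DEFAULT_RECEPTOR_RHO = {
    "A4B2": 0.10,
    "M1": 0.0,
    "VAChT": 0.17,
    "D1": -0.03,
    "D2": -0.05,
    "DAT": 0.07,
    "NET": 0.17,
}

_SEED_NETWORK_MAP = {"NBM": "limbic", "LC": "visual", "BG": "somatomotor"}


class SpecError(ValueError):
    """A simulation specification is internally inconsistent."""


@dataclass
class StateSchedule:
    """Two-state Markov regime switching on timepoints.

    ``integrated_coupling`` / ``segregated_coupling`` are the between-network
    correlations in the two regimes; ``integrated_within_r`` /
    ``segregated_within_r`` are the corresponding within-network correlations
    (``None`` falls back to the spec's ``within_network_r``).  The integrated
    regime has elevated between-network coupling with weakened module
    structure; the segregated regime has elevated within-network and
    suppressed between-network coupling.  ``mean_dwell`` is the expected
    regime run length in timepoints (geometric dwell, stay probability
    1 - 1/dwell).
    """

    integrated_coupling: float = 0.30
    segregated_coupling: float = 0.02
    mean_dwell: float = 100.0
    integrated_within_r: float | None = 0.40
    segregated_within_r: float | None = 0.65


@dataclass
class SimulationSpec:
    n_cases: int = 41
    n_controls: int = 38
    n_regions: int = 400
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    network_sizes: tuple[int, ...] | None = None
    network_names: tuple[str, ...] = DEFAULT_NETWORKS
    within_network_r: float = 0.5
    between_network_r: float = 0.05
    state_schedule: StateSchedule | None = dc_field(default_factory=StateSchedule)
    group_effect: float = 0.10  # within-visual coupling deficit in cases
    affected_network: str = "visual"
    longitudinal_slope: float = -0.002  # within-coupling change per month, cases
    subject_coupling_sd: float = 0.02  # random intercept on within couplings
    visit_months: tuple[float, ...] = (0.0,)
    include_seeds: bool = True
    seed_loading_r: float = 0.3
    log_hazard_per_sd: float = -math.log(1.66)
    censor_rate: float = 0.6
    baseline_hazard_per_month: float = math.log(2) / 60.0
    receptor_rho: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_RECEPTOR_RHO)
    )
    seed: int = 0

    def resolved_network_sizes(self) -> tuple[int, ...]:
        if self.network_sizes is not None:
            return tuple(self.network_sizes)
        k = len(self.network_names)
        base, rem = divmod(self.n_regions, k)
        return tuple(base + (1 if i < rem else 0) for i in range(k))

    def validate(self) -> None:
        sizes = self.resolved_network_sizes()
        if len(sizes) != len(self.network_names):
            raise SpecError("one size per network required")
        if sum(sizes) != self.n_regions:
            raise SpecError(
                f"network sizes sum to {sum(sizes)}, expected {self.n_regions}"
            )
        if not 0 <= self.within_network_r < 1:
            raise SpecError("within_network_r must lie in [0, 1)")
        if self.affected_network not in self.network_names:
            raise SpecError(f"unknown affected network {self.affected_network!r}")
        if not 0 <= self.censor_rate <= 1:
            raise SpecError("censor_rate must lie in [0, 1]")
        sizes_arr = np.array(sizes)
        for a, w in self.regime_couplings():
            if not 0 <= a < 1:
                raise SpecError(f"between-network coupling {a} outside [0, 1)")
            if not 0 <= w < 1:
                raise SpecError(f"within-network coupling {w} outside [0, 1)")
            if w - a < -1e-12:
                raise SpecError(
                    "implied covariance not positive semi-definite: within-network "
                    f"coupling {w} below the between-network coupling {a}"
                )
            # explicit PSD check of the implied covariance for this regime
            sigma = self._implied_covariance(a, w - a, sizes_arr)
            min_eig = np.linalg.eigvalsh(sigma).min()
            if min_eig < -1e-8:
                raise SpecError(f"implied covariance has eigenvalue {min_eig:.3e}")
        if self.state_schedule is not None and self.state_schedule.mean_dwell < 1:
            raise SpecError("mean_dwell must be >= 1 timepoint")

    def regime_couplings(self) -> list[tuple[float, float]]:
        """(between, within) correlation pairs, segregated first then integrated."""
        if self.state_schedule is None:
            return [(self.between_network_r, self.within_network_r)]
        ss = self.state_schedule
        wi = ss.integrated_within_r if ss.integrated_within_r is not None else self.within_network_r
        ws = ss.segregated_within_r if ss.segregated_within_r is not None else self.within_network_r
        return [(ss.segregated_coupling, ws), (ss.integrated_coupling, wi)]

    @staticmethod
    def _implied_covariance(a: float, b: float, sizes: np.ndarray) -> np.ndarray:
        n = int(sizes.sum())
        sigma = np.full((n, n), a)
        start = 0
        for sz in sizes:
            sigma[start : start + sz, start : start + sz] = a + b
            start += sz
        np.fill_diagonal(sigma, 1.0)
        return sigma


@dataclass
class SyntheticCohort:
    series: list[ParcellatedSeries]
    metadata: ParcelMetadata
    receptors: ReceptorTable
    cohort: CohortTable
    ground_truth: dict

    def to_directory(self, path: str | Path) -> None:
        """Write the cohort in the layout the IO loaders expect."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        series_dir = path / "series"
        series_dir.mkdir(exist_ok=True)
        for s in self.series:
            write_parcellated_series(s, series_dir / f"{s.subject_id}__{s.visit_id}.tsv")
        write_parcel_metadata(self.metadata, path / "metadata.tsv")
        write_receptor_table(self.receptors, path / "receptors.tsv")
        write_cohort_table(self.cohort, path / "cohort.tsv")
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(_jsonify(self.ground_truth), fh, indent=1)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _markov_regimes(
    rng: np.random.Generator, t_len: int, mean_dwell: float
) -> np.ndarray:
    """0 = segregated, 1 = integrated; geometric dwell with the given mean."""
    stay = 1.0 - 1.0 / mean_dwell
    labels = np.empty(t_len, dtype=np.int8)
    labels[0] = rng.integers(2)
    flips = rng.random(t_len - 1) > stay
    for t in range(1, t_len):
        labels[t] = labels[t - 1] ^ flips[t - 1]
    return labels


def _build_metadata(spec: SimulationSpec) -> ParcelMetadata:
    rows = []
    sizes = spec.resolved_network_sizes()
    for net, sz in zip(spec.network_names, sizes):
        for k in range(sz):
            rows.append(
                {
                    "region_label": f"{net}_{k + 1:03d}",
                    "role": "cortical",
                    "network": net,
                    "hemisphere": "L" if k % 2 == 0 else "R",
                }
            )
    if spec.include_seeds:
        for seed_name in _SEED_NETWORK_MAP:
            rows.append(
                {
                    "region_label": seed_name,
                    "role": "subcortical_seed",
                    "network": seed_name,
                    "hemisphere": "bilateral",
                }
            )
    return ParcelMetadata(pd.DataFrame(rows))


def _simulate_visit(
    rng: np.random.Generator,
    spec: SimulationSpec,
    within_by_network: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One visit's region × time matrix, seed rows, and regime labels."""
    t_len = spec.n_timepoints
    sizes = np.array(spec.resolved_network_sizes())
    pairs = spec.regime_couplings()
    if spec.state_schedule is None:
        regimes = np.zeros(t_len, dtype=np.int8)
        pairs = pairs * 2
    else:
        regimes = _markov_regimes(rng, t_len, spec.state_schedule.mean_dwell)
    a_by_regime = np.array([pairs[0][0], pairs[1][0]])
    w_by_regime = np.array([pairs[0][1], pairs[1][1]])
    a_t = a_by_regime[regimes]
    w_t = w_by_regime[regimes]
    g = rng.standard_normal(t_len)
    f = rng.standard_normal((len(sizes), t_len))
    eps = rng.standard_normal((spec.n_regions, t_len))
    x = np.empty((spec.n_regions, t_len))
    offsets = within_by_network - spec.within_network_r
    start = 0
    for n_i, sz in enumerate(sizes):
        # subject/case/time shifts to within coupling bottom out at the
        # global coupling level (b >= 0 keeps the covariance PSD)
        b_t = np.clip(w_t + offsets[n_i] - a_t, 0.0, None)
        resid = np.clip(1.0 - a_t - b_t, 0.0, None)
        block = (
            np.sqrt(a_t) * g
            + np.sqrt(b_t) * f[n_i]
            + np.sqrt(resid) * eps[start : start + sz]
        )
        x[start : start + sz] = block
        start += sz
    seed_rows = np.empty((0, t_len))
    if spec.include_seeds:
        seed_rows = np.empty((len(_SEED_NETWORK_MAP), t_len))
        net_index = {net: i for i, net in enumerate(spec.network_names)}
        noise = rng.standard_normal((len(_SEED_NETWORK_MAP), t_len))
        for s_i, (seed_name, net) in enumerate(_SEED_NETWORK_MAP.items()):
            lat = f[net_index[net]]
            r = spec.seed_loading_r
            seed_rows[s_i] = math.sqrt(r) * lat + math.sqrt(1 - r) * noise[s_i]
    return x, seed_rows, regimes


def simulate_bold_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort with recorded ground truth.

    Cases attend every month in ``spec.visit_months``; controls attend
    baseline only (longitudinal follow-up of the patient group).  Identical
    spec and seed give bit-identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    meta = _build_metadata(spec)
    affected_i = spec.network_names.index(spec.affected_network)

    subjects: list[dict] = []
    for i in range(spec.n_cases):
        subjects.append(
            {
                "subject_id": f"case{i + 1:03d}",
                "group": "case",
                "age": float(rng.normal(65.9, 6.7)),
                "sex": "M" if rng.random() < 34 / 41 else "F",
                "education": float(np.clip(rng.normal(13.2, 3.0), 6, 22)),
                "intercept": float(rng.normal(0.0, spec.subject_coupling_sd)),
            }
        )
    for i in range(spec.n_controls):
        subjects.append(
            {
                "subject_id": f"ctrl{i + 1:03d}",
                "group": "control",
                "age": float(rng.normal(67.0, 7.6)),
                "sex": "M" if rng.random() < 17 / 38 else "F",
                "education": float(np.clip(rng.normal(14.2, 2.8), 6, 22)),
                "intercept": float(rng.normal(0.0, spec.subject_coupling_sd)),
            }
        )

    series: list[ParcellatedSeries] = []
    regime_truth: dict[str, np.ndarray] = {}
    planted_within: dict[str, dict[str, float]] = {}
    cohort_rows: list[dict] = []
    baseline_measure: dict[str, float] = {}
    n_nets = len(spec.network_names)
    for subj in subjects:
        months_list = spec.visit_months if subj["group"] == "case" else (0.0,)
        for v_i, months in enumerate(months_list):
            within = np.full(n_nets, spec.within_network_r + subj["intercept"])
            if subj["group"] == "case":
                within[affected_i] -= spec.group_effect
                within += spec.longitudinal_slope * months
            visit_id = f"V{v_i + 1}"
            x, seed_rows, regimes = _simulate_visit(rng, spec, within)
            labels = meta.region_labels
            values = np.vstack([x, seed_rows]) if seed_rows.size else x
            s = ParcellatedSeries(
                subject_id=subj["subject_id"],
                visit_id=visit_id,
                tr_seconds=spec.tr_seconds,
                values=values,
                region_labels=labels,
            )
            series.append(s)
            key = f"{subj['subject_id']}__{visit_id}"
            regime_truth[key] = regimes
            planted_within[key] = dict(zip(spec.network_names, within.tolist()))
            cohort_rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "visit_id": visit_id,
                    "group": subj["group"],
                    "months_from_baseline": months,
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "education": subj["education"],
                }
            )
            if months == 0.0:
                baseline_measure[subj["subject_id"]] = within[affected_i]

    # conversion outcomes for cases from the planted proportional-hazards model
    case_ids = [s["subject_id"] for s in subjects if s["group"] == "case"]
    case_measure = pd.Series({sid: baseline_measure[sid] for sid in case_ids})
    if len(case_ids) >= 2 and case_measure.std() > 0:
        outcomes = simulate_outcomes(
            case_measure,
            log_hazard_per_sd=spec.log_hazard_per_sd,
            censor_rate=spec.censor_rate,
            seed=int(rng.integers(2**31 - 1)),
            baseline_hazard_per_month=spec.baseline_hazard_per_month,
        )
    else:
        # hazard model needs a z-scorable measure; degenerate cohorts are
        # emitted fully censored at the median planted event horizon
        outcomes = pd.DataFrame(
            {
                "subject_id": case_ids,
                "conversion_event": "none",
                "months_to_event_or_censor": math.log(2)
                / spec.baseline_hazard_per_month,
            }
        )
    outcome_by_subject = outcomes.set_index("subject_id")
    for row in cohort_rows:
        if row["subject_id"] in outcome_by_subject.index:
            rec = outcome_by_subject.loc[row["subject_id"]]
            row["conversion_event"] = rec["conversion_event"]
            row["months_to_event_or_censor"] = rec["months_to_event_or_censor"]
        else:
            row["conversion_event"] = "none"
            row["months_to_event_or_censor"] = np.nan
    cohort = CohortTable(pd.DataFrame(cohort_rows))

    # receptor maps planted against the regional case-deficit effect map
    sizes = spec.resolved_network_sizes()
    effect = np.zeros(spec.n_regions)
    start = 0
    for n_i, sz in enumerate(sizes):
        if n_i == affected_i:
            effect[start : start + sz] = 1.0
        start += sz
    effect = effect + 0.01 * rng.standard_normal(spec.n_regions)  # break rank ties
    cortical = meta.cortical_labels
    effect_map = pd.Series(effect, index=cortical, name="planted_effect")
    map_names = list(spec.receptor_rho)
    receptors = simulate_receptor_maps(
        effect_map,
        planted_rho=[spec.receptor_rho[m] for m in map_names],
        n_maps=len(map_names),
        seed=int(rng.integers(2**31 - 1)),
        map_names=map_names,
    )

    ground_truth = {
        "regime_labels": regime_truth,
        "planted_within_coupling": planted_within,
        "regime_couplings": {
            "segregated": {
                "between": spec.regime_couplings()[0][0],
                "within": spec.regime_couplings()[0][1],
            },
            "integrated": {
                "between": spec.regime_couplings()[-1][0],
                "within": spec.regime_couplings()[-1][1],
            },
        },
        "mean_dwell": spec.state_schedule.mean_dwell if spec.state_schedule else None,
        "group_effect": spec.group_effect,
        "affected_network": spec.affected_network,
        "longitudinal_slope": spec.longitudinal_slope,
        "log_hazard_per_sd": spec.log_hazard_per_sd,
        "receptor_rho": dict(spec.receptor_rho),
        "effect_map": effect_map.to_dict(),
        "baseline_measure": baseline_measure,
    }
    return SyntheticCohort(
        series=series,
        metadata=meta,
        receptors=receptors,
        cohort=cohort,
        ground_truth=ground_truth,
    )


def simulate_receptor_maps(
    effect_map: pd.Series,
    planted_rho: float | list[float],
    n_maps: int,
    seed: int,
    map_names: list[str] | None = None,
) -> ReceptorTable:
    """Receptor maps with planted population Spearman correlation.

    Gaussian rank copula: the effect map's ranks are mapped to normal
    scores z_e, each receptor map is ``r z_e + sqrt(1 - r^2) eps`` with the
    Pearson copula parameter ``r = 2 sin(pi rho / 6)``, so the population
    Spearman correlation with the effect map equals the planted rho.  With
    ``|rho| = 1`` the ranks are exactly identical (or exactly reversed).
    """
    rhos = np.atleast_1d(np.asarray(planted_rho, dtype=float))
    if rhos.size == 1:
        rhos = np.repeat(rhos, n_maps)
    if rhos.size != n_maps:
        raise SpecError(f"{rhos.size} planted rho values for {n_maps} maps")
    if (np.abs(rhos) > 1).any():
        raise SpecError("planted Spearman rho must lie in [-1, 1]")
    if map_names is None:
        map_names = [
            CANONICAL_RECEPTOR_MAPS[i]
            if i < len(CANONICAL_RECEPTOR_MAPS)
            else f"map_{i + 1}"
            for i in range(n_maps)
        ]
    n = len(effect_map)
    from scipy.stats import norm, rankdata

    ranks = rankdata(effect_map.to_numpy(), method="average")
    z_e = norm.ppf((ranks - 0.5) / n)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, rho in zip(map_names, rhos):
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        noise = rng.standard_normal(n)
        cols[name] = r * z_e + math.sqrt(max(0.0, 1.0 - r * r)) * noise
    frame = pd.DataFrame(cols, index=pd.Index(effect_map.index, name="region_label"))
    return ReceptorTable(frame)


def simulate_outcomes(
    baseline_measure: pd.Series,
    log_hazard_per_sd: float,
    censor_rate: float,
    seed: int,
    baseline_hazard_per_month: float = math.log(2) / 60.0,
    pd_share: float = 10 / 17,
) -> pd.DataFrame:
    """Exponential proportional-hazards conversion times with censoring.

    The hazard of subject i is ``lambda0 * exp(beta * z_i)`` with z the
    z-scored baseline measure.  Censoring is an independent exponential
    competing time calibrated so the expected censored fraction roughly
    equals ``censor_rate``; events are typed PD or DLB with the cohort's
    observed split.  Returns subject_id / conversion_event /
    months_to_event_or_censor.
    """
    measure = np.asarray(baseline_measure, dtype=float)
    if measure.std() == 0:
        raise SpecError("zero variance in baseline measure: z-scoring undefined")
    if not 0 <= censor_rate <= 1:
        raise SpecError("censor_rate must lie in [0, 1]")
    z = (measure - measure.mean()) / measure.std()
    rng = np.random.default_rng(seed)
    lam = baseline_hazard_per_month * np.exp(log_hazard_per_sd * z)
    event_time = rng.exponential(1.0 / lam)
    if censor_rate >= 1.0:
        observed = rng.exponential(1.0 / baseline_hazard_per_month, size=z.size)
        events = np.full(z.size, False)
    else:
        lam_c = baseline_hazard_per_month * censor_rate / (1.0 - censor_rate)
        if lam_c > 0:
            censor_time = rng.exponential(1.0 / lam_c, size=z.size)
        else:
            censor_time = np.full(z.size, np.inf)
        events = event_time <= censor_time
        observed = np.minimum(event_time, censor_time)
    kinds = np.where(rng.random(z.size) < pd_share, "PD", "DLB")
    return pd.DataFrame(
        {
            "subject_id": list(baseline_measure.index),
            "conversion_event": np.where(events, kinds, "none"),
            "months_to_event_or_censor": np.maximum(observed, 1e-6),
        }
    )
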