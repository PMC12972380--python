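"""Synthetic two-batch, two-timepoint, four-group metabolomics cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: planted modules of correlated metabolites driven by one latent
factor each, group-specific module shifts, traits coupled to module
factors, shared and group-specific exercise responses, multiplicative
batch effects, abundance-dependent (MNAR) missingness, reference-serum
aliquots and sporadic outliers.  Every planted effect is recorded in a
:class:`GroundTruth` object so recovery can be scored exactly.

The latent model, on the log2 scale, for metabolite *i* in module *m*,
subject *s*, timepoint *t*:

    x_ist = baseline_i + loading_i * f_ms(t) + response_i(t, group)
            + batch_effect(batch(s), i) + tech_i + eps_ist

with f_ms(baseline) ~ N(shift(group, m), 1) and the post-exercise factor
correlated with baseline (stability rho_t).  Background metabolites have
zero loading.  The matrix is exponentiated to ion-count scale before
missingness and outliers are applied.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import IonCountMatrix, MetaboliteAnnotation, SampleMeta, TraitTable

GROUP_ORDER = ("endurance", "bodybuilding", "sprint", "control")

#: 22 health- and exercise-related traits of the emulated cohort
TRAIT_NAMES = (
    "vo2max", "max_load_rel", "vt1", "lactate_clearance", "endurance_training",
    "bmi", "biceps_circumference", "quadriceps_circumference", "resistance_training",
    "grip_strength", "reactive_strength_index", "speed_training", "isometric_leg_strength",
    "age", "weight", "bodyfat_pct", "heart_rate_rest", "heart_rate_variability",
    "systolic_bp", "diastolic_bp", "hemoglobin", "resting_lactate",
)


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults emulate the study design."""

    n_per_group: tuple[int, int, int, int] = (11, 9, 8, 7)  # endurance, bodybuilding, sprint, control
    n_metabolites: int = 1020
    module_sizes: tuple[int, ...] = (180, 120, 90, 60, 45)
    within_module_cor: float = 0.6
    #: per-(group, module-index) baseline shift of the latent factor, in SD units
    group_module_shift: Mapping[tuple[str, int], float] = dataclasses.field(
        default_factory=lambda: {
            ("endurance", 0): 1.5,
            ("bodybuilding", 1): -1.5,
            ("sprint", 2): -1.5,
        }
    )
    #: correlation of the post-exercise latent factor with baseline
    factor_stability: float = 0.9
    loading_range: tuple[float, float] = (0.5, 1.0)
    sign_flip_frac: float = 0.2
    baseline_log2_range: tuple[float, float] = (10.0, 20.0)

    # exercise response
    n_shared_response: int = 60
    shared_response_range: tuple[float, float] = (1.0, 2.5)  # |log2 FC|
    n_group_response: int = 20
    group_response_shift: float = 1.5  # extra log2 FC in the target group

    # technical structure
    n_batches: int = 2
    batch_factor_sd: float = 0.1
    ref_serum_per_batch: int = 4
    ref_plasma_per_batch: int = 1
    tech_noise_sd: float = 0.05          # log2 SD of well-to-well technical noise
    n_high_cv: int = 69                  # metabolites planted to fail the 25% CV filter
    high_cv_noise_sd: float = 1.5        # their technical log2 SD

    # missingness / outliers
    missing_rate: float = 0.04           # mean fraction of blanked experimental cells; 0 = none
    missing_slope: float = 4.0           # logistic steepness in (1 - abundance quantile)
    mcar: bool = False                   # ignore abundance, use the mean rate uniformly
    n_forced_high_missing: int = 94      # metabolites planted to fail the 30% filter
    forced_missing_cells: int = 32       # of 70 experimental wells (45.7% > 30%)
    outlier_rate: float = 0.01
    outlier_log2_factor: float = 8.0

    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_metabolites:
            raise ConfigError("module sizes exceed metabolite count")
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 2")
        if not (0 <= self.within_module_cor < 1):
            raise ConfigError("within_module_cor must be in [0, 1)")
        if self.batch_factor_sd < 0 or self.tech_noise_sd < 0:
            raise ConfigError("SDs must be >= 0")
        n_special = self.n_high_cv + self.n_forced_high_missing
        n_background = self.n_metabolites - sum(self.module_sizes)
        if n_special > n_background:
            raise ConfigError(
                "planted CV/missingness failures must fit in the background set"
            )
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError("outlier_rate must be in [0, 1)")


@dataclasses.dataclass
class GroundTruth:
    """Record of every planted effect, serializable next to the dataset."""

    module_of: dict[str, int]                      # -1 = background ("grey")
    group_module_shift: dict[str, float]           # "group|module_idx" -> SD shift
    response_shared: dict[str, float]              # metabolite -> log2 shift
    response_group: dict[str, float]               # "metabolite|group" -> extra log2 shift
    trait_driver: dict[str, dict]                  # trait -> {module, coef, noise_sd}
    high_cv: list[str]
    forced_high_missing: list[str]
    outliers: list[tuple[str, str]]                # (metabolite_id, sample_id)

    def module_labels(self, metabolite_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.module_of[m] for m in metabolite_ids])

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["outliers"] = [list(t) for t in self.outliers]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["outliers"] = [tuple(t) for t in payload["outliers"]]
        return cls(**payload)


# ---------------------------------------------------------------------------


def _noise_sd_for_cor(cfg: SimulationConfig) -> float:
    """Residual SD giving the requested mean within-module correlation."""
    lo, hi = cfg.loading_range
    mean_loading = 0.5 * (lo + hi)
    rho = cfg.within_module_cor
    if rho <= 0:
        return 1.0
    return float(np.sqrt(mean_loading**2 * (1 - rho) / rho))


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[IonCountMatrix, SampleMeta, TraitTable, MetaboliteAnnotation, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_subj = sum(cfg.n_per_group)
    groups = np.repeat(GROUP_ORDER, cfg.n_per_group)
    subject_ids = [f"subj{i + 1:02d}" for i in range(n_subj)]
    # alternate batches within each group so groups span both batches;
    # both timepoints of a subject share the batch (same 96-well plate)
    batch_of_subject = {}
    pos = 0
    for g, n in zip(GROUP_ORDER, cfg.n_per_group):
        for j in range(n):
            batch_of_subject[subject_ids[pos]] = f"batch{(j % cfg.n_batches) + 1}"
            pos += 1

    met_ids = [f"met{i + 1:04d}" for i in range(cfg.n_metabolites)]
    n_mod = len(cfg.module_sizes)
    module_of = np.full(cfg.n_metabolites, -1, dtype=int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of[start : start + size] = m
        start += size
    background = np.where(module_of == -1)[0]

    # planted QC failures live in the background so modules survive QC
    high_cv_idx = background[: cfg.n_high_cv]
    forced_missing_idx = background[cfg.n_high_cv : cfg.n_high_cv + cfg.n_forced_high_missing]

    # metabolite-level parameters
    baseline = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_metabolites)
    loadings = rng.uniform(*cfg.loading_range, size=cfg.n_metabolites)
    flips = rng.random(cfg.n_metabolites) < cfg.sign_flip_frac
    loadings[flips] *= -1
    loadings[module_of == -1] = 0.0
    if cfg.within_module_cor <= 0:
        loadings[:] = 0.0
    noise_sd = _noise_sd_for_cor(cfg)
    tech_sd = np.full(cfg.n_metabolites, cfg.tech_noise_sd)
    tech_sd[high_cv_idx] = cfg.high_cv_noise_sd

    # latent factors per (module, subject): baseline and correlated post
    shift = np.zeros((n_mod, n_subj))
    for (g, m), val in cfg.group_module_shift.items():
        if m < n_mod:
            shift[m, groups == g] += val
    f_base = rng.standard_normal((n_mod, n_subj)) + shift
    rho_t = cfg.factor_stability
    f_post = rho_t * f_base + np.sqrt(1 - rho_t**2) * rng.standard_normal((n_mod, n_subj)) + (1 - rho_t) * shift

    # exercise-response effects: shared set first, group-specific set next,
    # drawn from module + background metabolites that are not planted QC failures
    eligible = np.array(
        [i for i in range(cfg.n_metabolites) if i not in set(high_cv_idx) | set(forced_missing_idx)]
    )
    resp_pick = rng.choice(eligible, size=cfg.n_shared_response + cfg.n_group_response, replace=False)
    shared_idx = resp_pick[: cfg.n_shared_response]
    group_idx = resp_pick[cfg.n_shared_response :]
    shared_eff = np.zeros(cfg.n_metabolites)
    shared_eff[shared_idx] = rng.uniform(*cfg.shared_response_range, size=len(shared_idx)) * rng.choice(
        [-1.0, 1.0], size=len(shared_idx)
    )
    group_eff: dict[str, float] = {}
    group_target = {}
    for j, i in enumerate(group_idx):
        g = GROUP_ORDER[j % len(GROUP_ORDER)]
        group_target[i] = g
        group_eff[f"{met_ids[i]}|{g}"] = cfg.group_response_shift

    # batch log2 effects per (batch, metabolite)
    batches = [f"batch{b + 1}" for b in range(cfg.n_batches)]
    batch_eff = {b: rng.normal(0, cfg.batch_factor_sd, size=cfg.n_metabolites) for b in batches}

    # assemble experimental wells
    sample_rows = []
    columns = {}
    for s_idx, subj in enumerate(subject_ids):
        b = batch_of_subject[subj]
        g = groups[s_idx]
        for tp, f in (("baseline", f_base), ("post", f_post)):
            sid = f"{subj}_{'base' if tp == 'baseline' else 'post'}"
            x = (
                baseline
                + loadings * f[module_of.clip(min=0), s_idx] * (module_of >= 0)
                + batch_eff[b]
                + rng.normal(0, noise_sd, cfg.n_metabolites)
                + rng.normal(0, 1, cfg.n_metabolites) * tech_sd
            )
            if tp == "post":
                x = x + shared_eff
                for i, tgt in group_target.items():
                    if tgt == g:
                        x[i] += cfg.group_response_shift
            columns[sid] = x
            sample_rows.append((sid, subj, "experimental", g, tp, b))

    # reference aliquots: noise-free population mean + batch effect + technical noise
    ref_mean = baseline  # population mean of the latent model (factors are mean ~0)
    for b in batches:
        for r in range(cfg.ref_serum_per_batch):
            sid = f"{b}_refserum{r + 1}"
            columns[sid] = ref_mean + batch_eff[b] + rng.normal(0, 1, cfg.n_metabolites) * tech_sd
            sample_rows.append((sid, "", "reference_serum", "", "", b))
        for r in range(cfg.ref_plasma_per_batch):
            sid = f"{b}_refplasma{r + 1}"
            columns[sid] = ref_mean - 0.5 + batch_eff[b] + rng.normal(0, 1, cfg.n_metabolites) * tech_sd
            sample_rows.append((sid, "", "reference_plasma", "", "", b))

    log2_values = pd.DataFrame(columns, index=pd.Index(met_ids, name="metabolite_id"))
    counts = IonCountMatrix(np.power(2.0, log2_values), log_scale=False)

    meta = SampleMeta(pd.DataFrame(sample_rows, columns=list(SampleMeta.COLUMNS)))

    truth = GroundTruth(
        module_of={m: int(v) for m, v in zip(met_ids, module_of)},
        group_module_shift={f"{g}|{m}": float(v) for (g, m), v in cfg.group_module_shift.items()},
        response_shared={met_ids[i]: float(shared_eff[i]) for i in shared_idx},
        response_group=group_eff,
        trait_driver={},
        high_cv=[met_ids[i] for i in high_cv_idx],
        forced_high_missing=[met_ids[i] for i in forced_missing_idx],
        outliers=[],
    )

    counts, truth = apply_missingness_and_outliers(counts, cfg, truth, rng)

    traits = _simulate_traits(cfg, rng, subject_ids, f_base, truth)
    annotation = _simulate_annotation(met_ids, module_of, rng)
    return counts, meta, traits, annotation, truth


def apply_missingness_and_outliers(
    matrix: IonCountMatrix,
    cfg: SimulationConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IonCountMatrix, GroundTruth]:
    """Inject MNAR missingness, forced high-missingness metabolites and outliers.

    Missingness hits experimental wells only (reference aliquots must stay
    measurable for batch normalization); each cell goes missing with a
    probability logistic in one minus its global abundance quantile, so low
    abundances are censored preferentially.  A configured set of metabolites
    gets exactly ``forced_missing_cells`` of its experimental wells blanked.
    Outliers multiply random observed experimental cells by 2**outlier_log2_factor.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    if truth is None:
        forced = [
            m for m in matrix.metabolite_ids[: cfg.n_forced_high_missing]
        ] if cfg.n_forced_high_missing and cfg.n_forced_high_missing <= len(matrix.metabolite_ids) else []
        truth = GroundTruth({}, {}, {}, {}, {}, [], forced, [])
    values = matrix.values.copy()
    exp_cols = [c for c in values.columns if c.endswith("_base") or c.endswith("_post")]
    exp = values.loc[:, exp_cols].to_numpy()

    # outliers first (recorded on the clean grid)
    n_cells = exp.size
    n_out = int(round(cfg.outlier_rate * n_cells))
    out_records: list[tuple[str, str]] = []
    if n_out > 0:
        flat = rng.choice(n_cells, size=n_out, replace=False)
        rows, cols = np.unravel_index(flat, exp.shape)
        exp[rows, cols] *= 2.0**cfg.outlier_log2_factor
        out_records = [(values.index[r], exp_cols[c]) for r, c in zip(rows, cols)]

    # stochastic MNAR missingness: cell probability logistic in rank abundance,
    # with the intercept solved so the mean probability equals missing_rate
    if cfg.missing_rate > 0:
        order = exp.flatten().argsort().argsort()
        q = order / max(n_cells - 1, 1)
        if cfg.mcar:
            p = np.full(n_cells, cfg.missing_rate)
        else:
            from scipy.optimize import brentq

            s = cfg.missing_slope
            a = brentq(lambda a_: expit(a_ + s * (1 - q)).mean() - cfg.missing_rate, -40, 40)
            p = expit(a + s * (1 - q))
        drop = rng.random(n_cells) < p
        exp[drop.reshape(exp.shape)] = np.nan

    # forced high-missingness metabolites: exactly forced_missing_cells blank wells
    forced = truth.forced_high_missing
    met_pos = {m: i for i, m in enumerate(values.index)}
    for m in forced:
        i = met_pos[m]
        cells = rng.choice(len(exp_cols), size=min(cfg.forced_missing_cells, len(exp_cols)), replace=False)
        exp[i, cells] = np.nan

    values.loc[:, exp_cols] = exp
    truth.outliers = out_records
    return IonCountMatrix(values, log_scale=False), truth


def _simulate_traits(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject_ids: list[str],
    f_base: np.ndarray,
    truth: GroundTruth,
) -> TraitTable:
    """22 traits; the first two per module track that module's latent factor."""
    n_mod = f_base.shape[0]
    rows = {}
    for j, name in enumerate(TRAIT_NAMES):
        if n_mod > 0 and j < 2 * n_mod and cfg.within_module_cor > 0:
            m = j % n_mod
            coef, noise = 1.0, 1.0
            vals = coef * f_base[m] + rng.normal(0, noise, len(subject_ids))
            truth.trait_driver[name] = {"module": int(m), "coef": coef, "noise_sd": noise}
        else:
            vals = rng.normal(0, 1, len(subject_ids))
            truth.trait_driver[name] = {"module": -1, "coef": 0.0, "noise_sd": 1.0}
        rows[name] = vals
    df = pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"))
    return TraitTable(df)


def _simulate_annotation(
    met_ids: list[str], module_of: np.ndarray, rng: np.random.Generator
) -> MetaboliteAnnotation:
    """Plausible class labels: modules are lipid-dominated, as in serum data."""
    from .io import SUPERPATHWAYS

    supers = []
    for i, m in enumerate(module_of):
        if m >= 0:
            supers.append("lipid")
        else:
            supers.append(SUPERPATHWAYS[rng.integers(0, len(SUPERPATHWAYS))])
    df = pd.DataFrame(
        {
            "name": [f"metabolite {i + 1}" for i in range(len(met_ids))],
            "superpathway": supers,
            "subpathway": ["" for _ in met_ids],
            "hmdb": ["" for _ in met_ids],
            "pubchem": ["" for _ in met_ids],
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    return MetaboliteAnnotation(df)
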