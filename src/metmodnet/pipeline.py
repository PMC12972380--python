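"""End-to-end orchestration: simulate/load -> QC -> network -> consensus
-> association -> response -> power, with a provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, consensus, io, network, power, preprocess, response
from .simulate import SimulationConfig, simulate_cohort


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration; defaults are the study's analysis settings."""

    out_dir: str = "metmodnet_out"
    seed: int = 0
    simulate: bool = True
    matrix_path: str | None = None
    samples_path: str | None = None
    traits_path: str | None = None
    annotation_path: str | None = None

    # QC
    cv_max_pct: float = 25.0
    miss_max: float = 0.30
    knn_k: int = 10
    iqr_multiplier: float = 3.0
    sample_sd_mult: float = 5.0

    # network
    soft_power: float = 6.0
    min_module_size: int = 30
    merge_height: float = 0.25
    deep_split: int = 2

    # testing
    alpha_group: float = 0.05
    alpha_module: float = 0.05
    pairwise_method: str = "tukey"

    # power preset: the study's four group sizes, module-level Bonferroni alpha
    power_group_sizes: tuple[int, ...] = (11, 9, 8, 7)
    power_alpha: float = 0.05 / 6
    power_target: float = 0.80

    def qc_params(self) -> preprocess.QCParams:
        return preprocess.QCParams(
            cv_max_pct=self.cv_max_pct,
            miss_max=self.miss_max,
            knn_k=self.knn_k,
            iqr_multiplier=self.iqr_multiplier,
            sample_sd_mult=self.sample_sd_mult,
        )

    def network_params(self) -> network.NetworkParams:
        return network.NetworkParams(
            soft_power=self.soft_power,
            min_module_size=self.min_module_size,
            merge_height=self.merge_height,
            deep_split=self.deep_split,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage in fixed order; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        io.write_table(df, path)
        artifacts[name] = _sha256(path)

    # inputs ---------------------------------------------------------------
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed)
        matrix, meta, traits, annotation, truth = simulate_cohort(sim_cfg)
        io.write_matrix(matrix, out / "matrix.tsv")
        io.write_samples(meta, out / "samples.tsv")
        io.write_traits(traits, out / "traits.tsv")
        io.write_annotation(annotation, out / "annotation.tsv")
        truth.to_json(out / "truth.json")
        for name in ("matrix.tsv", "samples.tsv", "traits.tsv", "annotation.tsv", "truth.json"):
            artifacts[name] = _sha256(out / name)
    else:
        missing = [
            p for p in (config.matrix_path, config.samples_path, config.traits_path)
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(
                "real-data mode needs matrix, samples and traits files; "
                f"missing or not found: {missing}"
            )
        matrix = io.read_matrix(config.matrix_path)
        meta = io.read_samples(config.samples_path)
        traits = io.read_traits(config.traits_path)

    # QC -------------------------------------------------------------------
    clean, report = preprocess.run_qc(matrix, meta, config.qc_params())
    io.write_matrix(clean, out / "clean_matrix.tsv")
    artifacts["clean_matrix.tsv"] = _sha256(out / "clean_matrix.tsv")
    save(report.summary(), "qc_summary.tsv")
    excl = pd.DataFrame(
        [("cv", m) for m in report.cv_excluded]
        + [("missingness", m) for m in report.missingness_excluded],
        columns=["rule", "metabolite_id"],
    )
    save(excl, "qc_excluded_metabolites.tsv")
    save(
        pd.DataFrame(report.iqr_flagged_points, columns=["metabolite_id", "sample_id"]),
        "qc_iqr_flagged.tsv",
    )

    # network per timepoint -------------------------------------------------
    net_params = config.network_params()
    values = clean.values
    assignments = {}
    for tp in ("baseline", "post"):
        cols = [s for s in values.columns if s in set(meta.sample_ids(role="experimental", timepoint=tp))]
        assignment = network.detect_modules(values.loc[:, cols], net_params, timepoint=tp)
        assignments[tp] = assignment
        table = assignment.to_frame()
        table["kME"] = network.kme(values.loc[:, cols], assignment).to_numpy()
        save(table, f"modules_{tp}.tsv")

    # consensus --------------------------------------------------------------
    match = consensus.match_modules(assignments["baseline"], assignments["post"])
    cons = consensus.consensus_refine(assignments["baseline"], assignments["post"], match)
    save(match.to_frame(), "module_match.tsv")
    save(consensus.consensus_frame(assignments["baseline"], assignments["post"], cons), "consensus.tsv")

    # association ------------------------------------------------------------
    reps = association.module_representatives(values, cons, meta, timepoint="baseline")
    save(reps.to_frame(), "module_representatives.tsv")
    mt = association.module_trait_lm(reps, traits, meta, adjust_for_group=False)
    mt_adj = association.module_trait_lm(reps, traits, meta, adjust_for_group=True)
    save(pd.concat([mt, mt_adj], ignore_index=True), "module_trait.tsv")
    mg, mg_pairs = association.module_group_anova(reps, meta, posthoc=True)
    save(mg, "module_group.tsv")
    save(mg_pairs, "module_group_pairs.tsv")
    met_g, met_g_pairs = association.per_metabolite_group_test(values, meta)
    save(met_g, "metabolite_group.tsv")
    save(met_g_pairs, "metabolite_group_pairs.tsv")

    # response ----------------------------------------------------------------
    resp, resp_pairs = response.run_response(
        values,
        meta,
        exclude=report.iqr_removed_cells,
        pairwise_method=config.pairwise_method,
    )
    save(resp, "response.tsv")
    save(resp_pairs, "response_pairs.tsv")

    # power -------------------------------------------------------------------
    f_min = power.min_detectable_f_unequal(
        list(config.power_group_sizes), config.power_alpha, config.power_target
    )
    save(
        pd.DataFrame(
            [
                (
                    len(config.power_group_sizes),
                    "/".join(str(s) for s in config.power_group_sizes),
                    config.power_alpha,
                    config.power_target,
                    f_min,
                )
            ],
            columns=["k", "group_sizes", "alpha", "target_power", "min_detectable_f"],
        ),
        "power.tsv",
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
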