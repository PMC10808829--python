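"""End-to-end study replica pipeline.

Stages: simulate (or load) a two-group cohort -> per-participant SRET
features -> endorsement matrices for the clinical, non-clinical and combined
partitions -> representative clustering solution per partition (default
initialization seed 3) -> seed-perturbation stability study -> top-word
profiles and cross-solution correspondence -> cluster statistics suite.
Every artifact is written to the output directory and hashed into a run
manifest; re-running with the same configuration reproduces identical file
hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PipelineError
from .instruments import cronbach_alpha
from .metrics import build_endorsement_matrix, compute_features
from .mixture import kmax_bezdek, select_model
from .profiles import top_words, correspondence_table
from .simulate import default_paperlike_spec, generate_cohort, write_cohort
from .stats import chi2_2x2, multinomial_gof, one_way_anova, t_test_raw, tukey_hsd
from .validation import perturbation_study
from .wordbank import default_word_bank

FEATURE_COLUMNS = [
    "n_neg_endorsed", "n_pos_endorsed", "neg_rt_bias", "pos_rt_bias",
    "neg_recall_bias", "recall_bias_diff", "ids_total",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (pre-existing delimited tables) or
    ``simulation_seed`` (synthetic cohort) must be set.
    """

    out_dir: str
    simulation_seed: int = None
    input_dir: str = None
    criterion: str = "bic"
    stability_seeds: tuple = tuple(range(1, 31))
    representative_seed: int = 3
    kmin: int = 2
    kmax: object = "bezdek"     # "bezdek" or an explicit integer
    n_restarts: int = 10
    n_clinical: int = None      # simulation-only group-size overrides
    n_nonclinical: int = None

    def validate(self) -> None:
        if (self.simulation_seed is None) == (self.input_dir is None):
            raise ConfigError("RunConfig: exactly one of simulation_seed / input_dir must be set")
        if not self.stability_seeds:
            raise ConfigError("RunConfig: stability_seeds must be non-empty")
        if self.kmax != "bezdek" and (not isinstance(self.kmax, int) or self.kmax < self.kmin):
            raise ConfigError("RunConfig: kmax must be 'bezdek' or an integer >= kmin")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        if isinstance(cfg.stability_seeds, list):
            cfg.stability_seeds = tuple(cfg.stability_seeds)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _resolve_kmax(config: RunConfig, n: int) -> int:
    return kmax_bezdek(n) if config.kmax == "bezdek" else int(config.kmax)


def _write_solution(solution, ids, out: Path, stem: str) -> None:
    payload = solution.model.to_dict()
    payload["criteria"] = solution.criteria
    payload["entropy"] = solution.entropy
    with open(out / f"{stem}_solution.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        {
            "participant_id": ids,
            "cluster": solution.labels,
            "max_responsibility": solution.responsibilities.max(axis=1),
        }
    ).to_csv(out / f"{stem}_labels.csv", index=False)


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return run
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bank = default_word_bank()

    if config.simulation_seed is not None:
        spec_c = default_paperlike_spec(config.simulation_seed, "clinical",
                                        n_participants=config.n_clinical)
        spec_n = default_paperlike_spec(config.simulation_seed + 1, "nonclinical",
                                        n_participants=config.n_nonclinical)
        cohort_c = _stage("simulate")(generate_cohort)(spec_c)
        cohort_n = _stage("simulate")(generate_cohort)(spec_n)
        trials = pd.concat([cohort_c.trials, cohort_n.trials], ignore_index=True)
        recalls = pd.concat([cohort_c.recalls, cohort_n.recalls], ignore_index=True)
        participants = pd.concat([cohort_c.participants, cohort_n.participants],
                                 ignore_index=True)
        write_cohort(cohort_c, out / "data_clinical", bank)
        write_cohort(cohort_n, out / "data_nonclinical", bank)
    else:
        src = Path(config.input_dir)
        trials = pd.read_csv(src / "trials.csv")
        recalls = pd.read_csv(src / "recalls.csv")
        participants = pd.read_csv(src / "participants.csv")

    features = _stage("metrics")(compute_features)(trials, recalls, bank)
    features = features.merge(
        participants[["participant_id", "group", "sex", "diagnosis", "ids_total"]],
        on="participant_id",
    )
    features.to_csv(out / "features.csv", index=False)

    partitions = {
        "clinical": trials[trials["participant_id"].isin(
            participants.loc[participants["group"] == "clinical", "participant_id"])],
        "nonclinical": trials[trials["participant_id"].isin(
            participants.loc[participants["group"] == "nonclinical", "participant_id"])],
        "combined": trials,
    }

    solutions = {}
    for name, part_trials in partitions.items():
        matrix = _stage("matrix")(build_endorsement_matrix)(part_trials, bank)
        matrix.write_csv(out / f"{name}_endorsement_matrix.csv", bank)
        kmax = _resolve_kmax(config, matrix.n)
        solution = _stage("cluster")(select_model)(
            matrix, criterion=config.criterion, seed=config.representative_seed,
            kmin=config.kmin, kmax=kmax, n_restarts=config.n_restarts,
        )
        solutions[name] = (matrix, solution)
        _write_solution(solution, matrix.participant_ids, out, name)

        report = _stage("stability")(perturbation_study)(
            matrix, seeds=config.stability_seeds, kmin=config.kmin, kmax=kmax,
            n_restarts=config.n_restarts,
            representative_seed=config.representative_seed,
        )
        report.per_seed.to_csv(out / f"{name}_stability_report.csv", index=False)
        report.summary.to_csv(out / f"{name}_stability_summary.csv", index=False)
        report.centroid_match.to_csv(out / f"{name}_centroid_match.csv", index=False)

        profs = _stage("profiles")(top_words)(matrix, solution.labels, bank)
        prof_rows = []
        for prof in profs:
            for _, row in prof.top_words.iterrows():
                prof_rows.append({"cluster": prof.cluster, **row.to_dict(), "is_top": True})
        pd.DataFrame(prof_rows).to_csv(out / f"{name}_profiles.csv", index=False)

    # Correspondence of the sub-sample solutions with the combined solution.
    combined_matrix, combined_solution = solutions["combined"]
    combined_labels = pd.Series(combined_solution.labels,
                                index=combined_matrix.participant_ids)
    for name in ("clinical", "nonclinical"):
        matrix, solution = solutions[name]
        sub_labels = pd.Series(solution.labels, index=matrix.participant_ids)
        table = _stage("correspondence")(correspondence_table)(
            sub_labels, combined_labels.loc[sub_labels.index],
            name_a=name, name_b="combined",
        )
        table.counts.to_csv(out / f"correspondence_{name}.csv")
        table.column_composition.to_csv(out / f"correspondence_{name}_column_pct.csv")

    stats_rows = _stage("stats")(_cluster_statistics)(features, participants, solutions, out)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "version": _version(),
        "solutions": {
            name: {"K": sol.model.K, "criterion": config.criterion,
                   "criterion_value": sol.criteria[config.criterion],
                   "n": int(matrix.n)}
            for name, (matrix, sol) in solutions.items()
        },
        "statistics": stats_rows,
        "files": _hash_files(out),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _cluster_statistics(features: pd.DataFrame, participants: pd.DataFrame,
                        solutions: dict, out: Path) -> dict:
    """ANOVA/Tukey per feature per partition plus the group-level tests."""
    anova_rows = []
    tukey_rows = []
    for name, (matrix, solution) in solutions.items():
        labels = pd.Series(solution.labels, index=matrix.participant_ids)
        sub = features.set_index("participant_id").loc[labels.index]
        for col in FEATURE_COLUMNS:
            groups = [sub.loc[labels == k, col].to_numpy()
                      for k in range(solution.model.K)]
            groups = [g[~np.isnan(g)] for g in groups]
            if sum(g.size >= 1 for g in groups) < 2:
                continue
            res = one_way_anova(groups)
            anova_rows.append({
                "partition": name, "feature": col, "ss_between": res.ss_between,
                "df_between": res.df_between, "ss_residual": res.ss_residual,
                "df_residual": res.df_residual, "F": res.F,
                "eta_sq": res.eta_sq, "p": res.p,
            })
            for pair in tukey_hsd([g for g in groups if g.size], alpha=0.05):
                tukey_rows.append({"partition": name, "feature": col,
                                   **pair.__dict__})
    pd.DataFrame(anova_rows).to_csv(out / "anova_tables.csv", index=False)
    pd.DataFrame(tukey_rows).to_csv(out / "tukey_tables.csv", index=False)

    # Between-group demographics: sex distribution and depressive symptoms.
    sex_counts = pd.crosstab(participants["group"], participants["sex"])
    chi = chi2_2x2(sex_counts.to_numpy()) if sex_counts.shape == (2, 2) else None
    ids_c = participants.loc[participants["group"] == "clinical", "ids_total"]
    ids_n = participants.loc[participants["group"] == "nonclinical", "ids_total"]
    ttest = t_test_raw(ids_n, ids_c) if len(ids_c) >= 2 and len(ids_n) >= 2 else None

    # Diagnosis frequency across the clinical clusters (uniform multinomial).
    matrix_c, solution_c = solutions["clinical"]
    labels_c = pd.Series(solution_c.labels, index=matrix_c.participant_ids)
    diag = participants.set_index("participant_id").loc[labels_c.index, "diagnosis"]
    mult_rows = []
    for label in sorted(diag.unique()):
        counts = [int(((diag == label) & (labels_c == k)).sum())
                  for k in range(solution_c.model.K)]
        if sum(counts) == 0:
            continue
        res = multinomial_gof(counts)
        mult_rows.append({"diagnosis": label, "counts": counts,
                          "chi2": res.chi2, "df": res.df, "p": res.p})
    pd.DataFrame(mult_rows).to_csv(out / "multinomial_tests.csv", index=False)

    return {
        "sex_chi2": None if chi is None else {"chi2": chi.chi2, "df": chi.df, "p": chi.p},
        "ids_t_test": None if ttest is None else
            {"t": ttest.t, "df": ttest.df, "ci95": list(ttest.ci95),
             "d": ttest.cohens_d, "p": ttest.p},
        "n_anova_rows": len(anova_rows),
        "n_multinomial_tests": len(mult_rows),
    }


def _hash_files(out: Path) -> dict:
    hashes = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(out))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return hashes


def _version() -> str:
    from . import __version__

    return __version__


def reliability_summary(items: pd.DataFrame, group_col: pd.Series = None) -> dict:
    """Cronbach's alpha overall and per group for an item matrix."""
    X = items.drop(columns=["participant_id"]).to_numpy(dtype=float)
    out = {"overall": cronbach_alpha(X)}
    if group_col is not None:
        for g in pd.unique(group_col):
            out[str(g)] = cronbach_alpha(X[np.asarray(group_col == g)])
    return out
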