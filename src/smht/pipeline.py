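"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate -> efa -> validate -> affect -> fuse in
order, skipping disabled stages, writing every artifact under the configured
output directory, and returning a report bundle with a provenance block
(config hash, seed, package version).  All randomness flows from the single
config seed; two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from . import fusion as fusion_mod
from . import io as io_mod
from . import psychometrics as psy
from .affect import train_adaboost, train_naive_bayes, word_error_rate, _doc_term_matrix, _nb_predict_matrix
from .containers import ValidationError
from .experiments import planted_config, score_cohort, train_affect_models, _child_seed
from .fuzzy_efa import bartlett_sphericity, fit_fuzzy_fa, kmo_statistic
from .simulate import (
    CohortConfig,
    default_class_unigrams,
    simulate_cohort,
    simulate_corpus,
    simulate_criterion,
    simulate_responses,
    simulate_retest,
)

log = logging.getLogger("smht")

STAGES = ("simulate", "efa", "validate", "affect", "fuse")


class ConfigError(ValidationError):
    """Invalid pipeline configuration."""


class StageDependencyError(ValidationError):
    """An enabled stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, JSON-round-trippable.

    Stage toggles, generator sizes and effect sizes, fuzzy-FA options,
    psychometric thresholds, fusion weights, and the root seed.
    """

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str = "results/pipeline"
    # questionnaire generator
    n_respondents: int = 300
    n_items: int = 18
    n_factors: int = 3
    loading: float = 0.7
    outlier_fraction: float = 0.05
    outlier_magnitude: float = 4.0
    retest_reliability: float = 0.87
    criterion_validity: float = 0.65
    # fuzzy-FA options
    efa_max_iter: int = 50
    efa_tol: float = 1e-4
    kaiser_threshold: float = 1.0
    # psychometric thresholds
    high_low_fraction: float = 0.27
    alpha_level: float = 0.05
    # scale text size (for the readability formula; language-neutral counts)
    word_count: int = 1452
    sentence_count: int = 121
    syllable_count: int = 1890
    # text channel
    docs_per_class: int = 200
    doc_length: int = 40
    boost_rounds: int = 10
    token_error_rate: float = 0.08
    # cohort / fusion
    cohort_subjects: int = 300
    scale_effect: float = 0.8
    text_effect: float = 0.6
    prosody_effect: float = 1.0
    interview_noise: float = 0.05
    fusion_weights: tuple[float, float, float] = fusion_mod.DEFAULT_WEIGHTS
    threshold: float = fusion_mod.DEFAULT_THRESHOLD
    # optional external inputs (used when the simulate stage is disabled)
    responses_csv: str | None = None
    retest_csv: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if len(self.fusion_weights) != 3:
            raise ConfigError("fusion_weights must have 3 entries")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(data)
        for key in ("stages", "fusion_weights"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["fusion_weights"] = list(self.fusion_weights)
        return out

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        for key in ("out_dir", "responses_csv", "retest_csv"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the report bundle."""
    out_dir = Path(config.out_dir)
    data_dir = out_dir / "data"
    bundle: dict = {
        "provenance": {
            "config_hash": config.digest(),
            "seed": int(config.seed),
            "version": __version__,
        }
    }
    artifacts: dict = {}
    seed = int(config.seed)

    if "simulate" in config.stages:
        log.info("stage simulate: start")
        cfg = planted_config(
            n=config.n_respondents,
            p=config.n_items,
            k=config.n_factors,
            loading=config.loading,
            outlier_fraction=config.outlier_fraction,
            outlier_magnitude=config.outlier_magnitude,
            seed=_child_seed(seed, 1),
        )
        sim = simulate_responses(cfg)
        artifacts["responses"] = sim.responses
        artifacts["outlier_indices"] = sim.outlier_indices
        artifacts["retest"] = simulate_retest(
            sim.responses, config.retest_reliability, _child_seed(seed, 2)
        )
        artifacts["criterion"] = simulate_criterion(
            sim.responses, config.criterion_validity, _child_seed(seed, 3)
        )
        cohort_cfg = CohortConfig(
            n_subjects=config.cohort_subjects,
            scale_effect=config.scale_effect,
            text_effect=config.text_effect,
            prosody_effect=config.prosody_effect,
            interview_noise=config.interview_noise,
            doc_length=config.doc_length,
        )
        artifacts["cohort_config"] = cohort_cfg
        artifacts["cohort"] = simulate_cohort(cohort_cfg, _child_seed(seed, 4))
        io_mod.write_response_csv(artifacts["responses"], data_dir / "responses.csv")
        io_mod.write_response_csv(artifacts["retest"], data_dir / "retest.csv")
        np.savetxt(
            data_dir / "criterion.csv",
            artifacts["criterion"],
            header="criterion",
            comments="",
            fmt="%.6f",
        )
        bundle["simulate"] = {
            "n_respondents": config.n_respondents,
            "n_items": config.n_items,
            "n_outliers": int(len(sim.outlier_indices)),
            "cohort_subjects": config.cohort_subjects,
            "manifest": {
                "responses": "data/responses.csv",
                "retest": "data/retest.csv",
                "criterion": "data/criterion.csv",
                "seed": seed,
            },
        }
        log.info("stage simulate: done (n=%d, p=%d)", config.n_respondents, config.n_items)
    elif config.responses_csv:
        artifacts["responses"] = io_mod.read_response_csv(config.responses_csv)
        if config.retest_csv:
            artifacts["retest"] = io_mod.read_response_csv(config.retest_csv)

    if "efa" in config.stages:
        if "responses" not in artifacts:
            raise StageDependencyError(
                "stage 'efa' needs responses (enable 'simulate' or set responses_csv)"
            )
        log.info("stage efa: start")
        model = fit_fuzzy_fa(
            artifacts["responses"],
            max_iter=config.efa_max_iter,
            tol=config.efa_tol,
            kaiser_threshold=config.kaiser_threshold,
        )
        artifacts["efa_model"] = model
        kmo = kmo_statistic(model.correlation)
        chi2, df, pval = bartlett_sphericity(
            model.correlation, artifacts["responses"].n_respondents
        )
        io_mod.write_json(model.to_dict(), out_dir / "efa_model.json")
        loadings_path = out_dir / "loadings.csv"
        loadings_path.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            loadings_path,
            model.loadings,
            delimiter=",",
            header=",".join(f"factor_{j + 1}" for j in range(model.retained_k)),
            comments="",
            fmt="%.8f",
        )
        bundle["efa"] = {
            "retained_k": model.retained_k,
            "eigenvalues": model.eigenvalues.tolist(),
            "cumulative_contribution": model.cumulative_contribution.tolist(),
            "converged": model.converged,
            "iterations_run": model.iterations_run,
            "kmo": kmo,
            "bartlett": {"chi2": chi2, "df": df, "p_value": pval},
        }
        log.info("stage efa: done (retained_k=%d, KMO=%.3f)", model.retained_k, kmo)

    if "validate" in config.stages:
        if "responses" not in artifacts:
            raise StageDependencyError("stage 'validate' needs responses")
        log.info("stage validate: start")
        X = artifacts["responses"]
        alpha = psy.cronbach_alpha(X)
        report = {
            "alpha": alpha,
            "readability": psy.readability(
                config.word_count, config.sentence_count, config.syllable_count
            ),
        }
        if "retest" in artifacts:
            report["retest_r"] = psy.retest_reliability(X, artifacts["retest"])
        if "criterion" in artifacts:
            report["criterion_r"] = psy.criterion_validity(
                X.total_scores(), artifacts["criterion"]
            )
        verdicts = psy.item_discrimination(
            X, config.high_low_fraction, config.alpha_level
        )
        flags = psy.normality_screen(X)
        report["items_deleted"] = verdicts.index[verdicts["verdict"] == "delete"].tolist()
        report["items_flagged_nonnormal"] = flags.index[flags["flagged"]].tolist()
        verdicts.to_csv(out_dir / "item_discrimination.csv")
        flags.to_csv(out_dir / "normality_screen.csv")
        bundle["psychometrics"] = report
        log.info("stage validate: done (alpha=%.3f)", alpha)

    if "affect" in config.stages:
        log.info("stage affect: start")
        unigrams = default_class_unigrams()
        train = simulate_corpus(
            unigrams, config.docs_per_class, config.doc_length, _child_seed(seed, 5)
        )
        test = simulate_corpus(
            unigrams, config.docs_per_class, config.doc_length, _child_seed(seed, 6)
        )
        nb = train_naive_bayes(train)
        counts = _doc_term_matrix(test.documents, nb.vocabulary)
        nb_pred = [nb.classes[i] for i in _nb_predict_matrix(nb, counts)]
        nb_acc = float(np.mean([p == t for p, t in zip(nb_pred, test.labels)]))
        ensemble = train_adaboost(
            train, T=config.boost_rounds, seed=_child_seed(seed, 8)
        )
        ens_pred = ensemble.predict(test.documents)
        ens_acc = float(np.mean([p == t for p, t in zip(ens_pred, test.labels)]))
        # speech-to-text emulation: corrupt test tokens at a fixed rate and
        # measure the resulting word error rate
        rng = np.random.default_rng(_child_seed(seed, 11))
        vocab = np.array(train.vocabulary)
        wers = []
        for doc in test.documents[:100]:
            hyp = [
                str(rng.choice(vocab)) if rng.random() < config.token_error_rate else tok
                for tok in doc
            ]
            wers.append(word_error_rate(doc, hyp))
        io_mod.write_corpus(train, data_dir / "corpus.txt", data_dir / "labels.txt")
        bundle["affect"] = {
            "nb_accuracy": nb_acc,
            "ensemble_accuracy": ens_acc,
            "ensemble_rounds": [
                {"error": r.error, "alpha": r.alpha} for r in ensemble.rounds
            ],
            "wer": float(np.mean(wers)),
        }
        artifacts["ensemble"] = ensemble
        log.info("stage affect: done (NB acc=%.3f, ensemble acc=%.3f)", nb_acc, ens_acc)

    if "fuse" in config.stages:
        if "cohort" not in artifacts:
            raise StageDependencyError("stage 'fuse' needs a simulated cohort")
        if "ensemble" not in artifacts:
            raise StageDependencyError("stage 'fuse' needs the affect stage outputs")
        log.info("stage fuse: start")
        cohort = artifacts["cohort"]
        ensemble, scorer = train_affect_models(
            artifacts["cohort_config"], _child_seed(seed, 12),
            docs_per_class=config.docs_per_class,
            boost_rounds=config.boost_rounds,
        )
        scored = score_cohort(
            cohort, ensemble, scorer, config.fusion_weights, config.threshold
        )
        # self-reported score emulated as the scale-only (objective) component
        cal = fusion_mod.calibration_rate(
            scored["fused_decision"],
            scored["scale_decision"],
            scored["interview_label"],
            fused_scores=scored["fused"],
            self_reports=scored["objective"],
        )
        scored.to_csv(out_dir / "fused_scores.csv", index=False)
        bundle["fusion"] = {
            "acc_fused": cal.acc_fused,
            "acc_scale_only": cal.acc_scale_only,
            "calibration_rate": cal.calibration_rate,
            "self_test_error": cal.self_test_error,
            "weights": list(config.fusion_weights),
            "threshold": config.threshold,
        }
        log.info(
            "stage fuse: done (acc_fused=%.3f, acc_scale=%.3f)",
            cal.acc_fused,
            cal.acc_scale_only,
        )

    io_mod.write_report(bundle, out_dir)
    return bundle
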