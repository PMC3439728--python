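"""End-to-end orchestration: simulate -> matrix -> choose-k -> LDA -> distances -> evaluation.

A run is fully determined by its :class:`PipelineConfig`.  Each stochastic
stage receives a seed derived from the global seed by hashing a stage label,
so adding or reordering stages never perturbs another stage's randomness.
Every intermediate is written as plain TSV/JSON into the run directory, plus
a ``manifest.json`` recording the configuration, stage seeds and wall times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, corpus, distance, evaluate, lda, simulate, topic_number

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from a labeled hash."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either ``labels_path`` (+ ``lexicon_path``) or ``generator`` must be
    given.  ``k`` fixes the topic count and skips the selection stage.
    """

    out_dir: str | Path
    labels_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    generator: simulate.GeneratorConfig | None = None
    lambda_: float = 2.0
    binarize_for_k: bool = False
    k: int | None = None
    lda_alpha: float | None = None
    lda_beta: float = 0.1
    n_iterations: int = 1000
    burn_in: int = 500
    sample_lag: int = 10
    n_trials: int = 10_000
    max_m: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        synthetic = self.generator is not None
        from_files = self.labels_path is not None and self.lexicon_path is not None
        if synthetic == from_files:
            raise ValueError(
                "provide exactly one of: a generator config, or labels+lexicon paths"
            )


def _write_theta_phi(fit: lda.TopicModelFit, out: Path) -> None:
    K = fit.theta.shape[1]
    topics = [f"topic{k}" for k in range(K)]
    pd.DataFrame(fit.theta, index=fit.drug_ids, columns=topics).to_csv(
        out / "theta.tsv", sep="\t", index_label="drug_id"
    )
    pd.DataFrame(fit.phi, index=topics, columns=fit.term_ids).to_csv(
        out / "phi.tsv", sep="\t", index_label="topic"
    )
    pd.DataFrame(
        {"iteration": np.arange(1, fit.log_likelihood_trace.size + 1),
         "log_likelihood": fit.log_likelihood_trace}
    ).to_csv(out / "trace.tsv", sep="\t", index=False)


def _write_evaluation(
    assessments, curve, null, bw, atc, out: Path
) -> dict:
    pd.DataFrame(
        [
            {
                "drug_id": a.drug_id,
                "neighbor_id": a.neighbor_id,
                "n_indications": a.n_indications,
                "success": int(a.success),
                "shared_indications": ";".join(sorted(a.shared_indications)),
            }
            for a in assessments
        ]
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "m": m,
                "n_eligible": p.n_eligible,
                "n_success": p.n_success,
                "recall": "" if p.recall is None else p.recall,
            }
            for m, p in curve.points.items()
        ]
    ).to_csv(out / "recall_curve.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "m": m,
                "null_recall": "" if v is None else v,
                "null_std": "" if null.std[m] is None else null.std[m],
            }
            for m, v in null.mean.items()
        ]
    ).to_csv(out / "null_curve.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "bw_drug_id": d,
                "neighbor_id": n,
                "shared_indications": ";".join(sorted(s)),
            }
            for d, n, s in bw.replacements
        ]
    ).to_csv(out / "bw_report.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "category": r.category,
                "n_success_in": r.n_success_in,
                "n_fail_in": r.n_fail_in,
                "n_success_out": r.n_success_out,
                "n_fail_out": r.n_fail_out,
                "proportion": r.proportion,
                "p_value": r.p_value,
            }
            for r in atc
        ]
    ).to_csv(out / "atc_enrichment.tsv", sep="\t", index=False)

    m1 = curve.points[1]
    return {
        "n_drugs_assessed": len(assessments),
        "n_success": sum(a.success for a in assessments),
        "overall_recall": evaluate.overall_recall(assessments),
        "null_recall_m1": null.mean[1],
        "n_bw_drugs": bw.n_bw_drugs,
        "n_bw_replaceable": bw.n_replaceable,
        "recall_m1": m1.recall,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order and return the run directory.

    Re-running with an identical config reproduces byte-identical numeric
    tables.  A stage failure aborts with the stage name; artifacts written
    before the failure are left in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("setopics")
    root.addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "config": _config_to_obj(config),
        "stages": [],
    }
    stage_name = "?"

    def stage(name: str):
        nonlocal stage_name
        stage_name = name
        logger.info("stage %s", name)
        return time.perf_counter()

    def done(t0: float, **extra) -> None:
        manifest["stages"].append(
            {"name": stage_name, "wall_seconds": round(time.perf_counter() - t0, 3), **extra}
        )

    try:
        if config.generator is not None:
            t0 = stage("simulate")
            gen_seed = derive_seed(config.seed, "simulate")
            gen = dataclasses.replace(config.generator, seed=gen_seed)
            records, gen_matrix, truth = simulate.generate_corpus(gen)
            lexicon = simulate.corpus_lexicon(gen)
            corpus.write_labels(records, out / "labels.jsonl")
            lexicon.write_tsv(out / "lexicon.tsv")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth.to_json_obj(), fh)
            done(t0, seed=gen_seed)
        else:
            t0 = stage("load")
            records = corpus.deduplicate_labels(corpus.load_labels(config.labels_path))
            lexicon = corpus.SideEffectLexicon.read_tsv(config.lexicon_path)
            done(t0, n_records=len(records))

        t0 = stage("build-matrix")
        matrix = corpus.build_matrix(records, lexicon)
        corpus.write_matrix(matrix, out / "matrix.tsv")
        done(t0, n_drugs=matrix.n_drugs, n_terms=matrix.n_terms)

        if config.k is None:
            t0 = stage("choose-k")
            spectrum = topic_number.compute_spectrum(
                matrix, binarize=config.binarize_for_k
            )
            pd.DataFrame({"eigenvalue": spectrum.eigenvalues}).to_csv(
                out / "spectrum.tsv", sep="\t", index=False
            )
            sel = topic_number.choose_k(spectrum, config.lambda_)
            with open(out / "k_selection.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "k_star": sel.k_star,
                        "lambda": sel.lambda_,
                        "loss_curve": {str(k): v for k, v in sel.loss_curve.items()},
                    },
                    fh,
                )
            pd.DataFrame(
                {"k": list(sel.loss_curve), "loss": list(sel.loss_curve.values())}
            ).to_csv(out / "loss_curve.tsv", sep="\t", index=False)
            k = sel.k_star
            done(t0, k_star=k)
        else:
            k = config.k
            manifest["k_override"] = k

        t0 = stage("fit-lda")
        lda_seed = derive_seed(config.seed, "fit-lda")
        lda_config = lda.LdaConfig(
            n_topics=k,
            alpha=config.lda_alpha,
            beta=config.lda_beta,
            n_iterations=config.n_iterations,
            burn_in=config.burn_in,
            sample_lag=config.sample_lag,
            seed=lda_seed,
        )
        fit, _assignments = lda.fit(matrix, lda_config)
        _write_theta_phi(fit, out)
        done(t0, seed=lda_seed, k=k)

        t0 = stage("distances")
        dist = distance.pairwise_distances(fit)
        pd.DataFrame(dist.values, index=dist.drug_ids, columns=dist.drug_ids).to_csv(
            out / "dist.tsv", sep="\t", index_label="drug_id"
        )
        nn = distance.nearest_neighbors(dist)
        pd.DataFrame(nn.rows, columns=["drug_id", "neighbor_id", "distance"]).to_csv(
            out / "neighbors.tsv", sep="\t", index=False
        )
        done(t0)

        t0 = stage("evaluate")
        eval_seed = derive_seed(config.seed, "evaluate")
        assessed_records = [r for r in records if r.drug_id in {d for d, _, _ in nn.rows}]
        assessments = evaluate.evaluate_pairs(nn, assessed_records)
        curve = evaluate.recall_curve(assessments, config.max_m)
        null = evaluate.random_null(
            assessed_records, config.max_m, n_trials=config.n_trials, seed=eval_seed
        )
        bw = evaluate.bw_replacements(assessments, assessed_records)
        atc = evaluate.atc_enrichment(assessments, assessed_records)
        summary = _write_evaluation(assessments, curve, null, bw, atc, out)
        summary["analytic_null_m1"] = evaluate.analytic_null(assessed_records, 1)[1]
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
        done(t0, seed=eval_seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _config_to_obj(config: PipelineConfig) -> dict:
    obj = dataclasses.asdict(config)
    obj["out_dir"] = str(obj["out_dir"])
    for key in ("labels_path", "lexicon_path"):
        if obj[key] is not None:
            obj[key] = str(obj[key])
    return obj
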