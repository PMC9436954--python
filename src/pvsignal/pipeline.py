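"""End-to-end orchestration: simulate/load -> dedup -> screen -> evaluate.

:func:`run_pipeline` executes a whole experiment from one configuration
and writes CSV/JSON outputs plus a run manifest into an output directory.
The manifest records the configuration snapshot, the seeds used at every
stochastic stage, the package version and SHA-256 digests of every output
file: two runs from the same configuration and seeds produce byte-
identical CSVs (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import load_config, validate_config
from .core import deduplicate_followups, read_reports, write_reports
from .evaluation import PerformanceSummary, roc_points
from .reference import LabelHistory
from .screening import ScreeningConfig, TermGroup, run_retrospective_screen
from .simulate import (
    default_scenario,
    generate_label_history,
    generate_reports,
    null_scenario,
    truth_table,
)

logger = logging.getLogger("pvsignal")

__all__ = ["run_pipeline", "evaluate_final_year"]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _default_targets(generator_cfg) -> list[TermGroup]:
    """Emerging planted signals of the synthetic scenario, as singletons."""
    return [
        TermGroup(name=sig.ae_term, members=(sig.ae_term,))
        for sig in generator_cfg.planted
        if sig.label_update_year is not None
        and sig.label_update_year > sig.first_report_year
    ]


def evaluate_final_year(screen, universe: str = "test_split") -> list[PerformanceSummary]:
    """Performance of every method on one screened year's gold standard.

    Classifier flags are taken on the held-out test split (or the whole
    gold standard with ``universe='all_gold'``); the conventional methods
    are always judged on the whole Y/N pool with their native rules.
    Classifiers also report a full score-based ROC curve.
    """
    if screen.status != "ok":
        raise ValueError(f"year {screen.year} was skipped: {screen.reason}")
    reference = {t: c for t, c in screen.classes.items() if c in ("Y", "N")}
    summaries = []
    for method, scores in screen.gold_scores.items():
        native_to = screen.thresholds.get(method)
        if method in ("gbm", "rf"):
            eval_terms = (
                [t for t in screen.test_pairs]
                if universe == "test_split" else list(scores)
            )
            flags = {t: scores[t] >= native_to for t in eval_terms}
            roc = tuple(roc_points({t: scores[t] for t in eval_terms}, reference))
            label = universe
        else:
            cut = 1.0 if method == "ror025" else 0.0
            flags = {t: s > cut for t, s in scores.items()}
            roc = ()
            label = "all_gold"
        summaries.append(
            PerformanceSummary.from_flags(
                method, flags, reference, roc=roc, universe=label
            )
        )
    return summaries


def run_pipeline(
    config: str | Path | Mapping, out_dir: str | Path
) -> dict:
    """Run the full experiment; returns the manifest dictionary.

    Raises on invalid configuration or on any stage error (callers
    wrapping this in a CLI turn exceptions into a nonzero exit status).
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(findings))
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    master_seed = int(cfg["seed"])
    seeds = {"generator": master_seed, "screening": master_seed + 1}

    data_cfg = cfg["data"]
    scr_cfg = cfg["screening"]
    window = tuple(scr_cfg["window"])
    outputs: dict[str, Path] = {}

    generator_cfg = None
    if data_cfg["reports"] is None:
        scenario = cfg["generator"]["scenario"]
        factory = default_scenario if scenario == "default" else null_scenario
        generator_cfg = factory(
            seed=seeds["generator"], n_reports=cfg["generator"]["n_reports"]
        )
        rs = generate_reports(generator_cfg)
        lh = generate_label_history(generator_cfg, data_cfg["class_drugs"])
        write_reports(rs, out / "reports.csv")
        lh.to_csv(out / "label_history.csv")
        truth = truth_table(generator_cfg)
        pd.DataFrame(
            sorted(truth.items()), columns=["ae_term", "is_true_signal"]
        ).to_csv(out / "truth.csv", index=False)
        outputs["reports"] = out / "reports.csv"
        outputs["label_history"] = out / "label_history.csv"
        outputs["truth"] = out / "truth.csv"
    else:
        rs = read_reports(
            data_cfg["reports"],
            dialect=data_cfg["dialect"],
            study_drug=data_cfg["study_drug"],
            comparator_drugs=data_cfg["comparator_drugs"],
            year_range=window,
        )
        lh = LabelHistory.from_csv(data_cfg["label_history"])

    rs = deduplicate_followups(rs)
    logger.info("pipeline: %d deduplicated reports; window %s", len(rs), window)

    if cfg["targets"] is not None:
        targets = [
            TermGroup(name=t["name"], members=tuple(t["members"]))
            for t in cfg["targets"]
        ]
    elif generator_cfg is not None:
        targets = _default_targets(generator_cfg)
    else:
        raise ValueError("targets must be given when running on external data")

    screening_config = ScreeningConfig(
        methods=tuple(scr_cfg["methods"]),
        train_fraction=float(scr_cfg["train_fraction"]),
        folds=int(scr_cfg["folds"]),
        smote_k=int(scr_cfg["smote_k"]),
        ror_covariates=tuple(scr_cfg["ror_covariates"]),
        ic_level=float(scr_cfg["ic_level"]),
        ic_samples=int(scr_cfg["ic_samples"]),
        seed=seeds["screening"],
    )
    timeline, screens = run_retrospective_screen(
        rs, lh, targets, window,
        config=screening_config,
        class_drugs=data_cfg["class_drugs"],
        return_years=True,
    )
    logger.info(
        "pipeline: screened %d cumulative datasets (%d ok)",
        len(screens), sum(s.status == "ok" for s in screens),
    )

    timeline.to_frame().to_csv(out / "timeline.csv", index=False)
    timeline.summary_frame().to_csv(out / "summary.csv", index=False)
    outputs["timeline"] = out / "timeline.csv"
    outputs["summary"] = out / "summary.csv"

    score_rows = [
        {
            "year": screen.year,
            "method": s.method,
            "ae_term": s.ae_term,
            "raw_score": s.raw_score,
            "threshold": s.threshold,
            "std_diff": s.std_diff,
            "flagged": s.flagged,
        }
        for screen in screens
        for s in screen.scores
    ]
    pd.DataFrame(score_rows).to_csv(
        out / "unknown_scores.csv", index=False, float_format="%.6g"
    )
    outputs["unknown_scores"] = out / "unknown_scores.csv"

    metrics: dict = {"years_skipped": [s.year for s in screens if s.status != "ok"]}
    final_ok = [s for s in screens if s.status == "ok"]
    if final_ok:
        summaries = evaluate_final_year(
            final_ok[-1], universe=cfg["evaluation"]["universe"]
        )
        metrics["final_year"] = final_ok[-1].year
        metrics["performance"] = [
            {
                "method": p.method,
                "tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn,
                "sensitivity": round(p.sensitivity, 6),
                "specificity": round(p.specificity, 6),
                "auroc_balanced": round(p.auroc_balanced, 6),
                "universe": p.universe,
            }
            for p in summaries
        ]
        roc_rows = [
            {"method": p.method, "fpr": fpr, "tpr": tpr}
            for p in summaries
            for fpr, tpr in p.roc_points
        ]
        pd.DataFrame(roc_rows).to_csv(
            out / "roc_points.csv", index=False, float_format="%.6g"
        )
        outputs["roc_points"] = out / "roc_points.csv"
    with open(out / "metrics.json", "w") as handle:
        json.dump(metrics, handle, indent=2, sort_keys=True)
    outputs["metrics"] = out / "metrics.json"

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "seeds": seeds,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
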