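"""End-to-end pipeline runs: simulate/ingest -> standardize -> featurize
-> clean labels -> train -> predict -> evaluate, with a manifest for
reproducibility.

A run directory receives the event file, billing files, the fitted
vocabulary, predictions, the evaluation report (JSON, deterministically
serialized) and a manifest with the config hash, seed and input
digests: re-running with identical config and inputs reproduces every
metric byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from datetime import timedelta
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import (
    evaluate_predictions,
    paired_comparison,
    reimbursement_delta,
)
from .features import feature_matrix, fit_vocabulary
from .labels import (
    Labelset,
    clean_labelsets,
    default_code_definitions,
    read_code_definitions,
    restrict_labelset,
)
from .logmodel import (
    assemble_exams,
    merge_billing,
    read_billing,
    read_events,
    write_billing,
    write_events,
)
from .multioutput import (
    BaseClassifierSpec,
    BinaryRelevance,
    ClassifierChain,
    EnsembleOfChains,
    labelsets_to_frame,
)
from .standardize import RuleTable
from .synthetic import (
    GeneratorConfig,
    generate_dataset,
    simulate_technologist,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "temporal_split"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_exams": 500},
    "ingest": None,  # {"events": path, "billing": path} to skip simulation
    "standardize": {},  # RuleTable overrides
    "labels": {"min_instances": 20, "code_defs": None, "correct_test": True},
    "split": {"test_fraction": 0.3, "scheme": "temporal"},
    "model": {
        "method": "ecc",
        "family": "mlp",
        "hyperparameters": {},
        "n_chains": 10,
        "include_aborted": False,
    },
    "eval": {"technologist": None},  # {"forget_rate": .., "add_rate": ..}
    "merge_tolerance_min": 30,
}

_KNOWN_SECTIONS = set(DEFAULT_CONFIG)


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge onto defaults; unknown keys are rejected, not ignored."""
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if isinstance(merged.get(key), dict) and isinstance(value, dict):
            bad = set(value) - set(merged[key])
            if bad and key != "simulate" and key != "standardize":
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def temporal_split(exams, test_fraction: float = 0.3, scheme: str = "temporal",
                   seed: int = 0):
    """Held-out split; temporal by default (test = final contiguous
    fraction by registration time, the way a held-out month works)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if scheme == "temporal":
        ordered = sorted(exams, key=lambda e: e.registration_time)
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        ordered = list(exams)
        rng.shuffle(ordered)
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    n_test = max(1, int(round(len(ordered) * test_fraction)))
    return ordered[:-n_test], ordered[-n_test:]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def _build_model(model_cfg: dict, code_defs, seed: int):
    spec = BaseClassifierSpec(
        family=model_cfg["family"],
        hyperparameters=model_cfg.get("hyperparameters", {}),
        random_seed=seed,
    )
    method = model_cfg["method"]
    if method == "binary_relevance":
        return BinaryRelevance(code_defs, spec)
    if method == "chain":
        return ClassifierChain(code_defs, spec)
    if method == "ecc":
        return EnsembleOfChains(
            code_defs, spec, n_chains=model_cfg.get("n_chains", 10), seed=seed
        )
    raise ConfigError(f"unknown model method {method!r}")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute a full run; returns a results dict (also written to disk)."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- stage: simulate or ingest -------------------------------------
    events_path = out / "events.jsonl"
    billing_path = out / "billing_truth.csv"
    if cfg["ingest"]:
        events_path = Path(cfg["ingest"]["events"])
        billing_path = Path(cfg["ingest"]["billing"])
    else:
        gen_cfg = GeneratorConfig(**cfg["simulate"])
        bundle = generate_dataset(gen_cfg, seed=seed)
        with events_path.open("w") as fh:
            write_events(bundle.events, fh)
        with billing_path.open("w") as fh:
            write_billing(bundle.truth, fh)
        with (out / "provenance.csv").open("w") as fh:
            fh.write("exam_id,template\n")
            for exam_id, name in bundle.provenance:
                fh.write(f"{exam_id},{name}\n")

    # --- stage: ingest + assemble --------------------------------------
    with open(events_path) as fh:
        log = read_events(fh)
    if log.rejects:
        raise RuntimeError(
            f"stage ingest: {len(log.rejects)} rejected events, "
            f"first: line {log.rejects[0].line_no}: {log.rejects[0].reason}"
        )
    assembly = assemble_exams(log.events)
    with open(billing_path) as fh:
        billing = read_billing(fh)
    merged = merge_billing(
        assembly.exams, billing,
        tolerance=timedelta(minutes=cfg["merge_tolerance_min"]),
    )
    exams = merged.exams
    if not cfg["model"].get("include_aborted", False):
        exams = [e for e in exams if not e.aborted]

    # --- stage: label cleaning (pruning fitted on training split) ------
    if cfg["labels"]["code_defs"]:
        with open(cfg["labels"]["code_defs"]) as fh:
            code_defs = read_code_definitions(fh)
    else:
        code_defs = default_code_definitions()

    train_exams, test_exams = temporal_split(
        exams,
        test_fraction=cfg["split"]["test_fraction"],
        scheme=cfg["split"]["scheme"],
        seed=seed,
    )
    cleaned = clean_labelsets(
        [e.labelset for e in train_exams],
        code_defs,
        min_instances=cfg["labels"]["min_instances"],
        exam_ids=[e.exam_id for e in train_exams],
    )
    kept = cleaned["kept"]
    train_Y = cleaned["labelsets"]
    test_clean = clean_labelsets(
        [e.labelset for e in test_exams],
        code_defs,
        min_instances=1,  # no pruning refit on test
        exam_ids=[e.exam_id for e in test_exams],
        apply_corrections=cfg["labels"]["correct_test"],
    )
    test_Y = [restrict_labelset(ls, kept) for ls in test_clean["labelsets"]]
    kept_defs = {c: code_defs[c] for c in kept}

    # --- stage: standardize + featurize --------------------------------
    rules = RuleTable.from_mapping(cfg["standardize"]) if cfg["standardize"] else RuleTable()
    vocabulary = fit_vocabulary(train_exams, rules)
    with (out / "vocabulary.json").open("w") as fh:
        vocabulary.to_json(fh)
    X_train = feature_matrix(train_exams, vocabulary)
    X_test = feature_matrix(test_exams, vocabulary)

    # --- stage: train + predict ----------------------------------------
    model = _build_model(cfg["model"], kept_defs, seed)
    Y_frame = labelsets_to_frame(train_Y, kept)
    model.fit(X_train, Y_frame)
    preds = model.predict_labelsets(X_test)
    with (out / "predictions.csv").open("w") as fh:
        fh.write("exam_id,code_id,count\n")
        for exam, ls in zip(test_exams, preds):
            for code, n in ls.items():
                fh.write(f"{exam.exam_id},{code},{n}\n")

    # --- stage: evaluate ------------------------------------------------
    report = evaluate_predictions(test_Y, preds, kept_defs, n_codes=len(kept))
    results = {
        "report": report.to_json_obj(),
        "n_train": len(train_exams),
        "n_test": len(test_exams),
        "kept_codes": kept,
        "removed_codes": cleaned["removed"],
        "removed_points_share": round(cleaned["removed_points_share"], 10),
        "truth_cardinality": round(
            sum(ls.total_units for ls in test_Y) / len(test_Y), 10
        ),
    }

    tech_cfg = cfg["eval"].get("technologist")
    if tech_cfg:
        rng = np.random.default_rng(seed + 7)
        manual = simulate_technologist(
            test_Y,
            forget_rate=tech_cfg["forget_rate"],
            add_rate=tech_cfg["add_rate"],
            rng=rng,
            code_defs=kept_defs,
            aux_forget_multiplier=tech_cfg.get("aux_forget_multiplier", 2.5),
        )
        manual_report = evaluate_predictions(test_Y, manual, kept_defs,
                                             n_codes=len(kept))
        under, over = reimbursement_delta(test_Y, manual, kept_defs)
        results["manual"] = manual_report.to_json_obj()
        results["manual_undercoding_loss_frac"] = round(under, 10)
        results["manual_overcoding_excess_frac"] = round(over, 10)
        results["auto_vs_manual"] = {
            k: round(v, 10)
            for k, v in paired_comparison(test_Y, preds, manual).items()
        }

    report.per_code.to_csv(out / "per_code.csv")
    _dump_json(results, out / "eval_report.json")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "input_digests": {
            "events": _digest(Path(events_path)),
            "billing": _digest(Path(billing_path)),
        },
        "n_events": len(log.events),
        "n_exams": len(exams),
    }
    _dump_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
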