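"""Three-stage workflow orchestration.

Runs (optionally) synthetic-data generation, then curve processing,
structure curation, biological response profiling, consensus QSAR with
gap-filling of missing in vitro calls, and fragment-level IVIVC, writing
each stage's outputs before the next stage starts and emitting a
machine-readable run report.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bioprofile, curation, curves, qsar, synthetic, toxicophore

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "toxprofiler_out",
    "simulate": {
        "enabled": True,
        "n_compounds": 300,
        "n_assays": 20,
        "n_relevant_assays": 3,
        "association_odds": 8.0,
        "are_association_odds": 8.0,
        "missing_rate": 0.1,
        "curve_noise_sd": 5.0,
        "target_active_rate": 0.3,
        "target_toxic_rate": 0.35,
    },
    "inputs": {  # used when simulate.enabled is false
        "smiles": None,
        "curves": None,
        "matrix": None,
        "labels": None,
    },
    "curves": {"noise_threshold": 10.0},
    "profile": {"ra_threshold": 0.25, "min_matching_actives": 10},
    "qsar": {
        "enabled": True,
        "folds": 5,
        "rf_trees": 100,
        "knn_k": 5,
        "ad_k": 5,
        "ad_z": 0.5,
        "ratio": [750, 800],
        "run_cv": True,
    },
    "toxicophore": {
        "enabled": True,
        "fragments": [],
        "radius": 2,
        "min_support": 5,
        "rank": True,
    },
}


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def config_fingerprint(cfg: dict[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: dict[str, Any], outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full workflow; returns the run report (also written as
    JSON to the output directory)."""
    cfg = merge_config(cfg)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {
        "config_fingerprint": config_fingerprint(cfg),
        "seed": seed,
        "stages": {},
    }
    t0 = time.time()

    # -- stage: data (synthetic or file inputs) ----------------------------
    stage = "data"
    try:
        if cfg["simulate"]["enabled"]:
            sim_cfg = synthetic.SimulationConfig.from_dict(
                {k: v for k, v in cfg["simulate"].items() if k != "enabled"} | {"seed": seed}
            )
            library = synthetic.generate_library(sim_cfg)
            curve_list = synthetic.generate_curves(library, sim_cfg)
            matrix = synthetic.generate_assay_matrix(library, sim_cfg)
            labels = synthetic.liver_labels(library)
            smiles_by_id = {rec.compound_id: rec.smiles for rec in library}
            synthetic.write_smiles(library, out / "library.smi")
            synthetic.write_curves_csv(curve_list, out / "curves.csv")
            matrix.to_csv(out / "assay_matrix.csv")
            matrix.metadata.to_csv(out / "assay_metadata.csv", index_label="assay_id")
            synthetic.write_labels_csv(labels, out / "labels.csv")
        else:
            inputs = cfg["inputs"]
            for key in ("smiles", "curves", "matrix", "labels"):
                if not inputs.get(key):
                    raise FileNotFoundError(f"missing required input path: inputs.{key}")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"input file not found: {inputs[key]}")
            pairs = curation.read_smi(inputs["smiles"])
            smiles_by_id = {cid: smi for cid, smi in pairs}
            curve_list = curves.read_curves_csv(inputs["curves"])
            metadata = None
            meta_path = inputs.get("matrix_metadata")
            if meta_path:
                metadata = pd.read_csv(meta_path, index_col="assay_id")
            matrix = bioprofile.AssayResponseMatrix.read_csv(inputs["matrix"], metadata)
            labels = bioprofile.read_labels_csv(inputs["labels"])
        report["stages"][stage] = {
            "status": "completed",
            "n_compounds": len(smiles_by_id),
            "n_curves": len(curve_list),
            "n_assays": len(matrix.assays),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        raise StageError(stage, exc) from exc

    # -- stage: curve processing ------------------------------------------
    stage = "curves"
    try:
        calls = curves.process_curves(curve_list, cfg["curves"]["noise_threshold"])
        curves.write_calls_csv(calls, out / "compound_calls.csv")
        report["stages"][stage] = {
            "status": "completed",
            "n_compounds": int(len(calls)),
            "category_counts": calls["category"].value_counts().to_dict(),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        raise StageError(stage, exc) from exc

    # -- stage: curation ---------------------------------------------------
    stage = "curate"
    try:
        curated, rejected = curation.curate_many(smiles_by_id.items())
        curation.write_smi(curated, out / "curated.smi")
        curation.write_rejections_csv(rejected, out / "rejections.csv")
        curated_ids = {rec.provenance[0] for rec in curated if rec.provenance}
        report["stages"][stage] = {
            "status": "completed",
            "n_curated": len(curated),
            "n_rejected": len(rejected),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        raise StageError(stage, exc) from exc

    # -- stage: profiling --------------------------------------------------
    stage = "profile"
    try:
        are_binary = calls["score"].map(lambda s: 1 if s == 1.0 else (0 if s == 0.0 else None))
        are_binary = are_binary.dropna().astype(int)
        profile = bioprofile.build_profile(
            matrix,
            endpoint_a=are_binary,
            endpoint_b=labels,
            ra_threshold=cfg["profile"]["ra_threshold"],
            min_matching_actives=cfg["profile"]["min_matching_actives"],
        )
        profile.stats_frame().to_csv(out / "assay_stats.csv", index=False)
        profile.ra.to_csv(out / "ra.csv", index_label="compound_id")
        profile.profile_table.to_csv(out / "profile_matrix.csv", index_label="compound_id")
        report["stages"][stage] = {
            "status": "completed",
            "selected_assays": profile.selected_assays,
            "combined_chi2_p": profile.combined_chi2[1] if profile.combined_chi2 else None,
            "n_profiled": int(len(profile.profile_table)),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        raise StageError(stage, exc) from exc

    # -- stage: QSAR gap filling ------------------------------------------
    stage = "qsar"
    combined_calls = calls["category"].copy()
    call_source = pd.Series("experimental", index=combined_calls.index)
    if cfg["qsar"]["enabled"]:
        try:
            qcfg = cfg["qsar"]
            train_ids = [c for c in are_binary.index if c in curated_ids]
            specs = qsar.default_specs(
                seed=seed, rf_trees=int(qcfg["rf_trees"]), knn_k=int(qcfg["knn_k"])
            )
            all_ids = sorted(smiles_by_id)
            desc = qsar.descriptor_sets_from_smiles(
                [smiles_by_id[c] for c in all_ids], all_ids
            )
            train_desc = {ds: desc[ds].subset(train_ids) for ds in desc}
            y = are_binary.loc[train_ids]
            act = [c for c in train_ids if y[c] == 1]
            inact = [c for c in train_ids if y[c] == 0]
            fps = qsar.fingerprint_features(
                [smiles_by_id[c] for c in train_ids], train_ids
            )
            modeling_ids, leftout = qsar.downsample(
                act, inact, fps, ratio=tuple(qcfg["ratio"]), seed=seed
            )
            bundle = qsar.train_consensus(
                {ds: desc[ds].subset(modeling_ids) for ds in desc},
                y.loc[modeling_ids],
                specs=specs,
                ad_k=int(qcfg["ad_k"]),
                ad_z=float(qcfg["ad_z"]),
            )
            cv_summary = None
            if qcfg.get("run_cv", True):
                cv = qsar.external_cv(
                    train_desc, y, folds=int(qcfg["folds"]), seed=seed, specs=specs,
                    ad_k=int(qcfg["ad_k"]), ad_z=float(qcfg["ad_z"]),
                    ratio=tuple(qcfg["ratio"]),
                )
                cv.to_csv(out / "cv_report.csv")
                cv_summary = cv.summary().to_dict(orient="records")
            predictions = bundle.predict(desc)
            pred_df = pd.DataFrame(
                [
                    {
                        "compound_id": p.compound_id,
                        "score": p.score,
                        "class_cpt1": p.class_cpt1,
                        "class_cpt2": p.class_cpt2,
                        "in_ad": p.in_ad,
                    }
                    for p in predictions
                ]
            ).set_index("compound_id")
            pred_df.to_csv(out / "qsar_predictions.csv", index_label="compound_id")
            # gap filling: experimental call wins; out-of-AD predictions are
            # used but flagged low-confidence
            n_filled = 0
            for p in predictions:
                cid = p.compound_id
                experimental = combined_calls.get(cid)
                if experimental in (bioprofile.ACTIVE, bioprofile.INACTIVE):
                    continue
                combined_calls.loc[cid] = p.class_cpt1
                call_source.loc[cid] = "predicted" if p.in_ad else "predicted_low_confidence"
                n_filled += 1
            report["stages"][stage] = {
                "status": "completed",
                "n_modeling": len(modeling_ids),
                "n_leftout": len(leftout),
                "n_gap_filled": n_filled,
                "cv_summary": cv_summary,
            }
        except Exception as exc:  # noqa: BLE001
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise StageError(stage, exc) from exc
    else:
        report["stages"][stage] = {"status": "skipped"}

    # -- stage: toxicophore IVIVC -----------------------------------------
    stage = "toxicophore"
    if cfg["toxicophore"]["enabled"]:
        try:
            tcfg = cfg["toxicophore"]
            compounds = [(cid, smi) for cid, smi in sorted(smiles_by_id.items())]
            source = "experimental" if not cfg["qsar"]["enabled"] else (
                "mixed" if (call_source != "experimental").any() else "experimental"
            )
            results = []
            for frag_cfg in tcfg["fragments"]:
                spec = toxicophore.FragmentSpec(
                    str(frag_cfg["id"]), str(frag_cfg["pattern"]), "user_supplied"
                )
                matched = toxicophore.match(spec, compounds)
                if not matched:
                    continue
                results.append(
                    toxicophore.fragment_ivivc(
                        matched, combined_calls, labels, spec.fragment_id, source
                    )
                )
            toxicophore.write_ivivc_csv(results, out / "fragment_ivivc.csv")
            ranked_summary = []
            if tcfg.get("rank", True):
                dual = pd.Series(
                    {
                        cid: (combined_calls.get(cid) == bioprofile.ACTIVE)
                        and bool(labels.get(cid, 0))
                        for cid, _ in compounds
                    }
                )
                ranked = toxicophore.rank_fragments(
                    compounds, dual,
                    radius=int(tcfg["radius"]), min_support=int(tcfg["min_support"]),
                )
                ranked_summary = [
                    {"pattern": rf.spec.pattern, "odds_ratio": rf.odds_ratio}
                    for rf in ranked[:10]
                ]
            report["stages"][stage] = {
                "status": "completed",
                "n_fragments_evaluated": len(results),
                "top_ranked": ranked_summary,
                "call_source": source,
            }
        except Exception as exc:  # noqa: BLE001
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise StageError(stage, exc) from exc
    else:
        report["stages"][stage] = {"status": "skipped"}

    report["elapsed_s"] = round(time.time() - t0, 3)
    _write_report(report, out)
    return report


def _write_report(report: dict[str, Any], out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
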