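"""End-to-end orchestration: cohort -> optimizations -> transfer -> reports.

Artifacts are plain files under an output directory:

    cohort/sub-XX.h5          subject containers (+ index.json with seeds)
    montages/<protocol>.json  montage + objective + GA history
    transfer.tsv              protocol x subject evaluation table
    comparison.json           paired t / Kruskal-Wallis / Dunn report
    quadratic_fit.json        NERNI vs <En> dose-response fit
    features.tsv              anatomical features per subject
    regression.json           feature regressions + LOSO predictions

Every stage records the global seed; a re-run with the same config and seed
reproduces the artifacts. With ``resume=True`` stages whose outputs exist
are loaded instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import feature_diffs, features_table, fit_feature_regression, loso_predict
from .cohort import CohortSpec, _make_subject, generate_cohort
from .io import load_subject, save_subject
from .model import Montage, SubjectModel
from .objective import mean_en, nerni
from .optimize import OptimizationConfig, check_constraints, ga_optimize, optimize_group_loo
from .transfer import Protocol, compare_protocols, evaluate_transfer, nerni_vs_mean_en_fit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    optimization: OptimizationConfig = field(default_factory=OptimizationConfig)
    out_dir: Path = Path("tesgroup-run")
    seed: int = 0
    resume: bool = False
    regression_order: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        # the global seed feeds both the generator and the optimizer
        self.cohort = replace(self.cohort, seed=self.seed)
        self.optimization = replace(self.optimization, seed=self.seed)


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a flat-sectioned TOML file.

    Sections: [cohort], [cohort.target], [optimization], [run]; keyword
    overrides win over file values.
    """
    import tomllib

    from .cohort import TargetPatch

    with open(path, "rb") as f:
        raw = tomllib.load(f)
    cohort_kw = dict(raw.get("cohort", {}))
    target_kw = cohort_kw.pop("target", None)
    if target_kw:
        cohort_kw["target"] = TargetPatch(**target_kw)
    run_kw = dict(raw.get("run", {}))
    run_kw.update(overrides)
    return RunConfig(
        cohort=CohortSpec(**cohort_kw),
        optimization=OptimizationConfig(**raw.get("optimization", {})),
        **run_kw,
    )


def _montage_path(out: Path, protocol_id: str) -> Path:
    return out / "montages" / f"{protocol_id}.json"


def _save_result(out: Path, protocol_id: str, montage: Montage, payload: dict) -> None:
    path = _montage_path(out, protocol_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    montage.to_csv(path.with_suffix(".csv"))
    payload = {
        "reference": montage.reference_label,
        "currents_mA": montage.currents,
        **payload,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _load_montage(out: Path, protocol_id: str, config: OptimizationConfig) -> Montage | None:
    path = _montage_path(out, protocol_id)
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    montage = Montage(payload["currents_mA"], reference_label=payload.get("reference", "Cz"))
    check_constraints(montage, config)  # validate on read
    return montage


def _template_subject(spec: CohortSpec) -> SubjectModel:
    """Unjittered base head, the synthetic stand-in for a standard template."""
    return _make_subject(spec, spec.base, "template", {"template": True})


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study and return the artifact directory."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    (out / "cohort").mkdir(parents=True, exist_ok=True)
    opt = config.optimization

    # --- stage 1: cohort -------------------------------------------------
    index_path = out / "cohort" / "index.json"
    if config.resume and index_path.exists():
        index = json.loads(index_path.read_text())
        cohort = [load_subject(out / "cohort" / p) for p in index["subjects"].values()]
        logger.info("stage=cohort resumed n=%d", len(cohort))
    else:
        cohort = generate_cohort(config.cohort)
        index = {"seed": config.seed, "subjects": {}}
        for s in cohort:
            fname = f"{s.subject_id}.h5"
            save_subject(out / "cohort" / fname, s)
            index["subjects"][s.subject_id] = fname
        index_path.write_text(json.dumps(index, indent=2))
        logger.info("stage=cohort generated n=%d", len(cohort))

    cfg_dump = {
        "seed": config.seed,
        "cohort": {
            k: v for k, v in dataclasses.asdict(config.cohort).items() if k != "base"
        },
        "optimization": dataclasses.asdict(opt),
    }
    (out / "config.json").write_text(json.dumps(cfg_dump, indent=2, default=str))

    # --- stage 2: personalized optimizations ------------------------------
    personalized: dict[str, Montage] = {}
    for s in cohort:
        pid = f"personalized_{s.subject_id}"
        montage = _load_montage(out, pid, opt) if config.resume else None
        if montage is None:
            res = ga_optimize(s, config=opt)
            _save_result(out, pid, res.montage, {
                "objective": res.objective,
                "history": res.history,
                "seed": res.seed,
                "subject_id": s.subject_id,
            })
            montage = res.montage
        logger.info("stage=personalized subject_id=%s", s.subject_id)
        personalized[s.subject_id] = montage

    # --- stage 3: leave-one-out group optimizations -----------------------
    group_montages: dict[str, Montage] = {}
    if all(
        config.resume and _load_montage(out, f"group_loo_{s.subject_id}", opt)
        for s in cohort
    ):
        for s in cohort:
            group_montages[s.subject_id] = _load_montage(out, f"group_loo_{s.subject_id}", opt)
    else:
        loo = optimize_group_loo(cohort, config=opt)
        for sid, r in loo.items():
            _save_result(out, f"group_loo_{sid}", r.result.montage, {
                "objective": r.result.objective,
                "held_out_nerni": r.held_out_nerni,
                "held_out_mean_en": r.held_out_mean_en,
                "history": r.result.history,
                "seed": r.result.seed,
            })
            group_montages[sid] = r.result.montage

    # --- stage 4: template ------------------------------------------------
    template = _template_subject(config.cohort)
    tmpl_montage = _load_montage(out, "template", opt) if config.resume else None
    if tmpl_montage is None:
        res = ga_optimize(template, config=opt)
        _save_result(out, "template", res.montage, {
            "objective": res.objective, "history": res.history, "seed": res.seed,
        })
        tmpl_montage = res.montage
    logger.info("stage=template done")

    # --- stage 5: transfer evaluation -------------------------------------
    protocols = [
        *(
            Protocol(f"personalized_{sid}", "personalized", m, own_subject=sid)
            for sid, m in personalized.items()
        ),
        *(
            Protocol(f"group_loo_{sid}", "group_loo", m, own_subject=sid)
            for sid, m in group_montages.items()
        ),
        Protocol("template", "template", tmpl_montage),
        *(
            Protocol(f"nonpers_{sid}", "non_personalized_individual", m)
            for sid, m in personalized.items()
        ),
    ]
    table = evaluate_transfer(protocols, cohort)
    table.to_csv(out / "transfer.tsv", sep="\t", index=False)

    report = compare_protocols(table)
    (out / "comparison.json").write_text(json.dumps(report.to_dict(), indent=2))
    quad = nerni_vs_mean_en_fit(table)
    (out / "quadratic_fit.json").write_text(json.dumps(quad.to_dict(), indent=2))
    logger.info("stage=transfer rows=%d", len(table))

    # --- stage 6: anatomical features and regressions ---------------------
    if all(s.features is not None for s in cohort):
        feats = features_table(cohort)
        feats.to_csv(out / "features.tsv", sep="\t")
        reg_out: dict = {}

        # pooled donor-subject pairs: feature diffs vs transferred outcome
        donor_rows = []
        for donor in cohort:
            diffs = feature_diffs(cohort, donor.subject_id)
            sub_table = table[table["protocol_id"] == f"nonpers_{donor.subject_id}"]
            sub_table = sub_table.set_index("subject_id").drop(index=donor.subject_id)
            donor_rows.append(
                diffs.join(sub_table[["nerni", "mean_en"]], how="inner")
            )
        pooled = pd.concat(donor_rows, axis=0)
        X = pooled.drop(columns=["nerni", "mean_en"])
        for response in ("nerni", "mean_en"):
            try:
                fit = fit_feature_regression(
                    X, pooled[response], order=config.regression_order
                )
            except ValueError:
                # collinear feature set (expected for spherical heads, where
                # every feature is a function of the shell radii): fall back
                # to PCA-before-regression
                fit = fit_feature_regression(
                    X,
                    pooled[response],
                    order=config.regression_order,
                    use_pca=True,
                    pca_components=min(4, len(pooled) - 2),
                )
            reg_out[f"pairwise_{response}"] = fit.to_dict()

        # LOSO: predict each donor's average transferred outcome from its features
        responses = {}
        for response in ("nerni", "mean_en"):
            per_donor = (
                table[table["protocol_kind"] == "non_personalized_individual"]
                .assign(donor=lambda d: d["protocol_id"].str.replace("nonpers_", "", regex=False))
                .query("donor != subject_id")
                .groupby("donor")[response]
                .mean()
                .reindex(feats.index)
            )
            responses[response] = per_donor
            try:
                preds, obs, r2 = loso_predict(
                    feats,
                    per_donor.to_numpy(),
                    order=1,
                    use_pca=True,
                    pca_components=max(1, min(4, len(feats) - 3)),
                )
                reg_out[f"loso_{response}"] = {
                    "r_squared": r2,
                    "predicted": dict(zip(feats.index, preds)),
                    "observed": dict(zip(feats.index, obs)),
                }
            except ValueError as exc:
                reg_out[f"loso_{response}"] = {"error": str(exc)}
        (out / "regression.json").write_text(json.dumps(reg_out, indent=2))
        logger.info("stage=features done")

    return out
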