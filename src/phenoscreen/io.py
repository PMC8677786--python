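"""Readers/writers, run configuration and the end-to-end pipeline.

The pipeline chains: read training screen → fingerprint → fit bagging
ensemble → cross-validate → screen candidate library → activity /
reliability / novelty filters → group by reference drugs → report.
All randomness flows from one root seed recorded in the report; identical
config + seed regenerate every output byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .chem import (
    Molecule,
    ReferenceSet,
    SmilesParseError,
    ecfp,
    parse_smiles,
)
from .evaluate import CVReport, kfold_mae
from .pct import (
    Ensemble,
    ScreenRecord,
    TrainingSet,
    TreeParams,
    ensemble_from_json,
    ensemble_to_json,
    fit_ensemble,
)
from .screen import (
    GroupAssignment,
    Hit,
    ScreenConfig,
    filter_hits,
    group_by_reference,
    remove_training_overlap,
    screen_library,
    summarize,
)

logger = logging.getLogger(__name__)

HITS_COLUMNS = [
    "id",
    "rfp_mean",
    "egfp_mean",
    "rfp_sd",
    "egfp_sd",
    "passed_activity",
    "passed_reliability",
    "passed_novelty",
    "group",
    "best_tanimoto",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or unreadable input data (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""


# ---------------------------------------------------------------------------
# configuration


class FingerprintSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radius: int = 2
    nbits: int = 2048


class TreeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 100
    min_leaf: int = 5
    max_depth: Optional[int] = None
    bootstrap: bool = True

    def to_params(self) -> TreeParams:
        return TreeParams(
            min_leaf=self.min_leaf,
            max_depth=self.max_depth,
            n_trees=self.n_trees,
            bootstrap=self.bootstrap,
        )


class ScreenSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reduction_threshold: float = 0.25
    control_level: float = 1.0
    reliability_quantile: float = 0.5
    similarity_cutoff: float = 0.4
    reliability_target: str = "rfp"
    exclude_labels: list[str] = Field(default_factory=list)

    def to_config(self) -> ScreenConfig:
        return ScreenConfig(
            reduction_threshold=self.reduction_threshold,
            control_level=self.control_level,
            reliability_quantile=self.reliability_quantile,
            similarity_cutoff=self.similarity_cutoff,
            reliability_target=self.reliability_target,
            exclude_labels=tuple(self.exclude_labels),
        )


class PathsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    training: str
    library: str
    refs: str
    outdir: str
    model: Optional[str] = None  # reuse a trained model instead of fitting


class RunConfig(BaseModel):
    """Strictly validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    fingerprint: FingerprintSection = Field(default_factory=FingerprintSection)
    tree: TreeSection = Field(default_factory=TreeSection)
    screen: ScreenSection = Field(default_factory=ScreenSection)
    cv_folds: int = 10
    seed: int = 0
    paths: PathsSection


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_compound_table(
    path: str | Path, sidecar: Optional[str | Path] = None
) -> list[tuple[str, Molecule]]:
    """Read a CSV compound table with mandatory ``id`` and ``smiles`` columns.

    Rows with unparseable SMILES are collected into a sidecar CSV
    (default: ``<path>.errors.csv``); the run aborts only when more than
    half the rows fail.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in ("id", "smiles") if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    out: list[tuple[str, Molecule]] = []
    bad_rows: list[dict] = []
    for _, row in frame.iterrows():
        try:
            out.append((row["id"], parse_smiles(row["smiles"], id=row["id"])))
        except SmilesParseError as exc:
            bad_rows.append({"id": row["id"], "smiles": row["smiles"], "error": str(exc)})
    if bad_rows:
        sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".errors.csv")
        pd.DataFrame(bad_rows).to_csv(sidecar_path, index=False)
        logger.warning("%d unparseable rows written to %s", len(bad_rows), sidecar_path)
    if len(bad_rows) > len(frame) / 2:
        raise DataError(
            f"{path}: {len(bad_rows)} of {len(frame)} rows failed to parse"
        )
    return out


def read_screen_table(
    path: str | Path, radius: int = 2, nbits: int = 2048
) -> TrainingSet:
    """Read a training screen CSV (id, smiles, rfp, egfp) into a TrainingSet."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in ("id", "smiles", "rfp", "egfp") if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        mol = parse_smiles(str(row["smiles"]), id=str(row["id"]))
        records.append(
            ScreenRecord(
                id=str(row["id"]),
                fingerprint=ecfp(mol, radius=radius, nbits=nbits),
                rfp=float(row["rfp"]),
                egfp=float(row["egfp"]),
            )
        )
    return TrainingSet(records)


def read_reference_table(
    path: str | Path, radius: int = 2, nbits: int = 2048
) -> ReferenceSet:
    """Read a reference panel CSV (name, smiles, approved, in_training)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [
        c for c in ("name", "smiles", "approved", "in_training") if c not in frame.columns
    ]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    rows = [
        (str(r["name"]), str(r["smiles"]), bool(int(r["approved"])), bool(int(r["in_training"])))
        for _, r in frame.iterrows()
    ]
    return ReferenceSet.from_smiles(rows, radius=radius, nbits=nbits)


def hits_frame(
    hits: Sequence[Hit], assignments: Sequence[GroupAssignment]
) -> pd.DataFrame:
    """Audit table of all screened compounds, deterministically ordered by
    descending predicted RFP reduction (ascending predicted RFP), ties by id."""
    by_id = {a.hit_id: a for a in assignments}
    unknown = set(by_id) - {h.id for h in hits}
    if unknown:
        raise DataError(f"assignments reference unknown hit ids: {sorted(unknown)}")
    rows = []
    for h in hits:
        a = by_id.get(h.id)
        rows.append(
            {
                "id": h.id,
                "rfp_mean": h.prediction.rfp_mean,
                "egfp_mean": h.prediction.egfp_mean,
                "rfp_sd": h.prediction.rfp_sd,
                "egfp_sd": h.prediction.egfp_sd,
                "passed_activity": h.passed_activity,
                "passed_reliability": h.passed_reliability,
                "passed_novelty": h.passed_novelty,
                "group": a.label if a else "",
                "best_tanimoto": a.best_tanimoto if a else np.nan,
            }
        )
    frame = pd.DataFrame(rows, columns=HITS_COLUMNS)
    return frame.sort_values(["rfp_mean", "id"], kind="mergesort").reset_index(drop=True)


def write_hits(
    hits: Sequence[Hit],
    assignments: Sequence[GroupAssignment],
    path: str | Path,
) -> None:
    frame = hits_frame(hits, assignments)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_hits(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in HITS_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing hit column(s) {missing}")
    return frame


def simulate_study(
    outdir: str | Path,
    scenario: str = "paper-like",
    seed: int = 0,
    n_train: int = 640,
    n_library: int = 5000,
    radius: int = 2,
    nbits: int = 2048,
) -> dict[str, str]:
    """Materialise a synthetic study on disk: ``train.csv`` (id, smiles,
    rfp, egfp), ``library.csv`` (id, smiles), ``refs.csv`` and
    ``ground_truth.json``.  Returns the written paths."""
    from .synthetic_data import (
        _REFERENCE_ROWS,
        sample_library,
        scenario_heteroscedastic,
        scenario_paper_like,
        scenario_signal_free,
    )

    builders = {
        "paper-like": scenario_paper_like,
        "heteroscedastic": scenario_heteroscedastic,
        "signal-free": scenario_signal_free,
    }
    if scenario not in builders:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose from {sorted(builders)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = builders[scenario](seed, n=n_train, nbits=nbits, radius=radius)
    lib_seed = int(
        np.random.SeedSequence([seed, 1]).generate_state(1)[0] % 2**31
    )
    lib_mols = sample_library(n_library, seed=lib_seed, id_prefix="LIB")

    train = pd.DataFrame(
        {
            "id": [r.id for r in sc.training_set.records],
            "smiles": [m.source_text for m in sc.molecules],
            "rfp": [r.rfp for r in sc.training_set.records],
            "egfp": [r.egfp for r in sc.training_set.records],
        }
    )
    train.to_csv(outdir / "train.csv", index=False, float_format="%.12g")
    pd.DataFrame(
        {"id": [m.id for m in lib_mols], "smiles": [m.source_text for m in lib_mols]}
    ).to_csv(outdir / "library.csv", index=False)
    pd.DataFrame(
        [
            {"name": n, "smiles": s, "approved": int(a), "in_training": int(t)}
            for n, s, a, t in _REFERENCE_ROWS
        ]
    ).to_csv(outdir / "refs.csv", index=False)
    gt = sc.ground_truth
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "nbits": gt.nbits,
                "baseline": gt.baseline,
                "noise_sd": list(gt.noise_sd),
                "effect_bits": [list(e) for e in gt.effect_bits],
                "scenario": scenario,
                "seed": seed,
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "train": str(outdir / "train.csv"),
        "library": str(outdir / "library.csv"),
        "refs": str(outdir / "refs.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }


# ---------------------------------------------------------------------------
# report and pipeline


class StageCounts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    library_size: int
    skipped: int
    activity_pass: int
    reliability_pass: int
    dual_pass: int
    novelty_pass: int
    label_excluded: int
    final_hits: int


class ScreenReport(BaseModel):
    """End-of-run summary mirroring the screen's flowchart structure.

    The config echo deliberately omits filesystem paths so reruns into
    different directories remain byte-identical; paths go to the log.
    """

    model_config = ConfigDict(extra="forbid")
    version: str
    seed: int
    config: dict
    stages: StageCounts
    cv_mae: Optional[dict[str, float]] = None
    group_counts: dict[str, int]
    group_fractions: dict[str, float]
    labels_not_in_training: list[str]


def run_pipeline(cfg: RunConfig, write_cv: bool = True) -> ScreenReport:
    """Execute the full screen and write report/hits/CV files to outdir."""
    outdir = Path(cfg.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phenoscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    fp = cfg.fingerprint
    try:
        t0 = time.perf_counter()
        ts = read_screen_table(cfg.paths.training, radius=fp.radius, nbits=fp.nbits)
        logger.info("stage=read_training in=%s out=%d records", cfg.paths.training, len(ts))

        if cfg.paths.model and Path(cfg.paths.model).exists():
            ens = ensemble_from_json(Path(cfg.paths.model).read_text())
            logger.info("stage=load_model in=%s out=%d trees", cfg.paths.model, len(ens.trees))
        else:
            ens = fit_ensemble(ts, cfg.tree.to_params(), seed=cfg.seed)
            model_path = Path(cfg.paths.model) if cfg.paths.model else outdir / "model.json"
            model_path.write_text(ensemble_to_json(ens))
            logger.info("stage=train in=%d records out=%d trees", len(ts), len(ens.trees))

        cv_summary = None
        if write_cv and cfg.cv_folds >= 2:
            report = kfold_mae(ts, cfg.tree.to_params(), k=cfg.cv_folds, seed=cfg.seed)
            report.rows.to_csv(outdir / "cv.csv", index=False, float_format="%.12g")
            cv_summary = report.aggregate_mae
            logger.info(
                "stage=cv in=%d records out=MAE rfp=%.6f egfp=%.6f",
                len(ts), cv_summary["rfp"], cv_summary["egfp"],
            )

        lib_mols = read_compound_table(cfg.paths.library)
        library = [
            (cid, ecfp(mol, radius=fp.radius, nbits=fp.nbits))
            for cid, mol in lib_mols
        ]
        preds = screen_library(ens, library)
        logger.info(
            "stage=screen in=%d compounds out=%d predictions skipped=%d",
            len(library), len(preds), len(preds.skipped),
        )

        scfg = cfg.screen.to_config()
        table = filter_hits(preds, scfg)
        n_activity = sum(h.passed_activity for h in table)
        n_reliability = sum(h.passed_reliability for h in table)
        dual = [h for h in table if h.passed_activity and h.passed_reliability]
        logger.info(
            "stage=filter in=%d out=activity=%d reliability=%d dual=%d",
            len(table), n_activity, n_reliability, len(dual),
        )

        after_novelty = remove_training_overlap(dual, ts)
        novel = after_novelty.hits()
        logger.info("stage=novelty in=%d out=%d", len(dual), len(novel))

        refs = read_reference_table(cfg.paths.refs, radius=fp.radius, nbits=fp.nbits)
        assignments = group_by_reference(novel, refs, tau=scfg.similarity_cutoff)
        if scfg.exclude_labels:
            kept_ids = {
                a.hit_id for a in assignments if a.label not in scfg.exclude_labels
            }
            excluded = len(assignments) - len(kept_ids)
            assignments = [a for a in assignments if a.hit_id in kept_ids]
            novel = [h for h in novel if h.id in kept_ids]
        else:
            excluded = 0
        summary = summarize(assignments, refs)
        logger.info(
            "stage=group in=%d out=%d excluded=%d labels=%s",
            len(novel) + excluded, summary.n_hits, excluded, sorted(summary.counts),
        )

        write_hits(list(table), assignments, outdir / "hits.csv")

        report_obj = ScreenReport(
            version=__version__,
            seed=cfg.seed,
            config={
                "fingerprint": cfg.fingerprint.model_dump(),
                "tree": cfg.tree.model_dump(),
                "screen": cfg.screen.model_dump(),
                "cv_folds": cfg.cv_folds,
            },
            stages=StageCounts(
                library_size=len(library),
                skipped=len(preds.skipped),
                activity_pass=n_activity,
                reliability_pass=n_reliability,
                dual_pass=len(dual),
                novelty_pass=len(novel) + excluded,
                label_excluded=excluded,
                final_hits=summary.n_hits,
            ),
            cv_mae=cv_summary,
            group_counts=summary.counts,
            group_fractions=summary.fractions,
            labels_not_in_training=list(summary.labels_not_in_training),
        )
        (outdir / "report.json").write_text(
            json.dumps(report_obj.model_dump(), indent=2, sort_keys=True) + "\n"
        )
        logger.info("stage=report elapsed=%.1fs", time.perf_counter() - t0)
        return report_obj
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"pipeline stage failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
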