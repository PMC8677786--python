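"""Virtual screening, hit filtering, novelty exclusion and grouping.

The trained ensemble is applied to a candidate library; a compound is an
activity hit when its predicted RFP (αSMA) intensity is at least 25%
below the untreated control (predicted value ≤ 0.75 at control 1.0,
boundary inclusive).  Weak predictions are filtered by the reliability
score: only compounds whose tree-sd falls at or below a configurable
quantile of the library's sd distribution are kept.  Compounds already
present in the training screen are removed (fingerprint-identity keys),
and the surviving hits are grouped by their most similar reference drug
(maximum Tanimoto over the panel, with a similarity cutoff below which a
hit is labelled "other").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .chem import Fingerprint, ReferenceSet, compound_key, tanimoto
from .pct import Ensemble, Prediction, TrainingSet, predict_ensemble_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Hit-calling parameters.

    reduction_threshold: required fractional intensity reduction (0.25
        means predicted RFP ≤ 0.75 × control).
    control_level: untreated-control intensity (1.0 for fold-over-control).
    reliability_quantile: keep compounds whose tree-sd is at or below
        this quantile of the library sd distribution (0.5 = the more
        reliable half; 1.0 disables the filter).
    similarity_cutoff: minimum Tanimoto to a reference drug for group
        assignment; below it a hit is labelled "other".
    reliability_target: which target's sd the reliability filter uses.
    exclude_labels: group labels dropped from the final list on
        pharmacological grounds (e.g. a corticosteroid class); off by
        default.
    """

    reduction_threshold: float = 0.25
    control_level: float = 1.0
    reliability_quantile: float = 0.5
    similarity_cutoff: float = 0.4
    reliability_target: str = "rfp"
    exclude_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.reduction_threshold < 1.0:
            raise ValueError("reduction_threshold must be in (0, 1)")
        if not 0.0 < self.reliability_quantile <= 1.0:
            raise ValueError("reliability_quantile must be in (0, 1]")
        if not 0.0 <= self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in [0, 1]")
        if self.reliability_target not in ("rfp", "egfp", "both"):
            raise ValueError("reliability_target must be rfp, egfp or both")


@dataclass(frozen=True)
class LibraryPrediction:
    """One screened compound: id, fingerprint, ensemble prediction."""

    id: str
    fingerprint: Fingerprint
    prediction: Prediction


@dataclass
class LibraryPredictions:
    """Ordered predictions over a library plus skipped-compound audit."""

    items: list[LibraryPrediction]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[LibraryPrediction]:
        return iter(self.items)


@dataclass(frozen=True)
class Hit:
    """A screened compound with its three filter flags.

    A compound belongs to the final hit list only when all three flags
    are true; all compounds are retained with flags for audit.
    """

    id: str
    fingerprint: Fingerprint
    prediction: Prediction
    passed_activity: bool
    passed_reliability: bool
    passed_novelty: bool = True

    @property
    def is_hit(self) -> bool:
        return (
            self.passed_activity
            and self.passed_reliability
            and self.passed_novelty
        )


class HitTable(list):
    """List of :class:`Hit` (every screened compound, flags attached)."""

    def hits(self) -> list[Hit]:
        """Only the compounds passing all filters so far."""
        return [h for h in self if h.is_hit]


@dataclass(frozen=True)
class GroupAssignment:
    """A hit's nearest reference drug (or "other") with its Tanimoto."""

    hit_id: str
    label: str
    best_tanimoto: float
    clinical_status_of_reference: Optional[str] = None  # approved | novel-panel


def screen_library(
    ens: Ensemble,
    library: Sequence[tuple[str, Fingerprint]],
) -> LibraryPredictions:
    """Predict (RFP, EGFP) and reliability sds for every library compound.

    Order is preserved and the run is deterministic.  Compounds whose
    fingerprint length does not match the ensemble are skipped and
    collected (the run continues); duplicate ids are predicted normally
    with a logged warning.
    """
    seen: set[str] = set()
    valid: list[tuple[str, Fingerprint]] = []
    skipped: list[tuple[str, str]] = []
    for cid, fp in library:
        if cid in seen:
            logger.warning("duplicate library id %s: predicting both", cid)
        seen.add(cid)
        if fp.nbits != ens.nbits:
            skipped.append((cid, f"nbits {fp.nbits} != ensemble {ens.nbits}"))
            continue
        valid.append((cid, fp))
    preds = predict_ensemble_many(ens, [fp for _, fp in valid])
    items = [
        LibraryPrediction(id=cid, fingerprint=fp, prediction=pred)
        for (cid, fp), pred in zip(valid, preds)
    ]
    if skipped:
        logger.warning("skipped %d compounds with mismatched nbits", len(skipped))
    return LibraryPredictions(items=items, skipped=skipped)


def _reliability_pass(
    preds: Sequence[LibraryPrediction], cfg: ScreenConfig
) -> list[bool]:
    targets = (
        ("rfp", "egfp") if cfg.reliability_target == "both" else (cfg.reliability_target,)
    )
    passes = np.ones(len(preds), dtype=bool)
    for target in targets:
        sds = np.array([p.prediction.sd_for(target) for p in preds])
        cutoff = float(np.quantile(sds, cfg.reliability_quantile))
        passes &= sds <= cutoff
    return passes.tolist()


def filter_hits(
    predictions: LibraryPredictions | Sequence[LibraryPrediction],
    cfg: ScreenConfig = ScreenConfig(),
) -> HitTable:
    """Apply the activity and reliability filters.

    Activity: predicted RFP mean ≤ (1 − reduction_threshold) × control,
    boundary inclusive (a prediction of exactly 0.75 at the defaults
    passes).  Reliability: the configured target's tree-sd at or below
    the configured quantile of the sd distribution over the *full*
    prediction set (all-equal sds therefore all pass).
    """
    items = list(predictions)
    if not items:
        raise ValueError("no predictions to filter")
    activity_cutoff = (1.0 - cfg.reduction_threshold) * cfg.control_level
    rel = _reliability_pass(items, cfg)
    table = HitTable()
    for item, rel_ok in zip(items, rel):
        table.append(
            Hit(
                id=item.id,
                fingerprint=item.fingerprint,
                prediction=item.prediction,
                passed_activity=item.prediction.rfp_mean <= activity_cutoff,
                passed_reliability=bool(rel_ok),
            )
        )
    return table


def remove_training_overlap(
    hits: Sequence[Hit], training: TrainingSet | None
) -> HitTable:
    """Mark hits identical to a training compound as non-novel.

    Identity is fingerprint identity (:func:`compound_key`).  Candidate-
    internal key collisions are deduplicated: the first occurrence keeps
    its flags, later ones are dropped with a log line.
    """
    training_keys: set[str] = set()
    if training is not None:
        training_keys = {compound_key(r.fingerprint) for r in training.records}
    out = HitTable()
    seen_keys: set[str] = set()
    for hit in hits:
        key = compound_key(hit.fingerprint)
        if key in seen_keys:
            logger.info("dropping duplicate candidate %s (key collision)", hit.id)
            continue
        seen_keys.add(key)
        out.append(replace(hit, passed_novelty=key not in training_keys))
    return out


def group_by_reference(
    hits: Sequence[Hit], refs: ReferenceSet, tau: float = 0.4
) -> list[GroupAssignment]:
    """Assign each hit to its most similar reference drug.

    best_tanimoto is the maximum over the panel; the label is that
    reference's name when best_tanimoto ≥ τ, else "other".  Ties resolve
    to the earlier reference in the panel's fixed order.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    out = []
    for hit in hits:
        best_ref = None
        best_sim = -1.0
        for ref in refs:  # fixed panel order: first max wins ties
            sim = tanimoto(hit.fingerprint, ref.fingerprint)
            if sim > best_sim:
                best_sim = sim
                best_ref = ref
        if best_sim >= tau:
            label = best_ref.name
            status = "approved" if best_ref.approved else "novel-panel"
        else:
            label, status = "other", None
        out.append(
            GroupAssignment(
                hit_id=hit.id,
                label=label,
                best_tanimoto=max(best_sim, 0.0),
                clinical_status_of_reference=status,
            )
        )
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Per-label hit counts and fractions over the final hit list."""

    n_hits: int
    counts: dict[str, int]
    fractions: dict[str, float]
    labels_not_in_training: tuple[str, ...]


def summarize(
    assignments: Sequence[GroupAssignment],
    refs: Optional[ReferenceSet] = None,
) -> GroupSummary:
    """Count hits per group label and flag labels whose reference drug was
    absent from the original training library."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    n = len(assignments)
    fractions = {k: v / n for k, v in counts.items()} if n else {}
    novel_labels: tuple[str, ...] = ()
    if refs is not None:
        in_training = {r.name: r.in_training for r in refs}
        novel_labels = tuple(
            sorted(
                label
                for label in counts
                if label != "other" and not in_training.get(label, False)
            )
        )
    return GroupSummary(
        n_hits=n,
        counts=counts,
        fractions=fractions,
        labels_not_in_training=novel_labels,
    )
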