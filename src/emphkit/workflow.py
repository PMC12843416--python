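"""Cohort-level convenience pipeline.

Glues the per-scan stages (resample, densitometry, mid-lung patches,
embeddings) and the modeling stages (split, probe, fusion) into the two
experiment shapes used throughout: an embedding-only probe and a
logit+QCT fusion model, both evaluated on a held-out patient-level test
split. Feature selection, standardization and the L1 strength grid all
see the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .evaluation import balanced_accuracy, confusion_at_threshold, roc_auc
from .features import extract_embeddings, sample_mid_lung_patches
from .modeling import (
    LogisticProbe,
    build_fusion_features,
    choose_l1_strength,
    inverse_frequency_weights,
    stratified_patient_split,
)
from .phantom import PhantomTruth
from .qct import QCTMarkers, compute_markers
from .segment import resample_isotropic


@dataclass
class ScanRecord:
    """Everything the modeling stage needs for one scan."""

    patient_id: str
    embedding: np.ndarray
    markers: QCTMarkers
    label: int


def phantom_scan_record(
    truth: PhantomTruth,
    n_patches: int = 9,
    patch_size_px: int = 224,
    backend: str = "texture",
) -> ScanRecord:
    """Run the per-scan feature pipeline on one phantom with its truth
    mask (standing in for an external segmentation backend)."""
    vol = resample_isotropic(truth.volume, 1.0)
    mask = resample_isotropic(truth.lung_mask, 1.0)
    markers = compute_markers(vol, mask, resample=False)
    patches = sample_mid_lung_patches(vol, mask, n_patches, patch_size_px)
    emb = extract_embeddings(patches, backend=backend)
    return ScanRecord(
        patient_id=truth.volume.patient_id,
        embedding=emb.scan_vector,
        markers=markers,
        label=truth.true_label,
    )


@dataclass
class ExperimentResult:
    """Held-out comparison of the embedding probe and the fusion model."""

    probe_auc: float
    fusion_auc: float
    probe_bacc: float
    fusion_bacc: float
    l1_strength: float
    split_sizes: dict[str, int]


def run_probe_fusion_experiment(
    records: list[ScanRecord], seed: int = 0
) -> ExperimentResult:
    """Embedding-only L1 probe vs logit+QCT fusion on one cohort.

    Procedure: patient-level stratified 70/15/15 split; inverse-frequency
    class weights from the training split; L1 strength chosen on the
    validation split; fusion stacks the probe's raw test-time logits with
    %LAA-950, Perc15 and TLV, standardized with train statistics, under
    an L2 probe. Metrics are reported on the test split.
    """
    ids = [r.patient_id for r in records]
    y = np.array([r.label for r in records])
    X = np.stack([r.embedding for r in records])
    markers = [r.markers for r in records]

    split = stratified_patient_split(dict(zip(ids, y.tolist())), seed=seed)
    where = np.array([split.assignment[p] for p in ids])
    tr, va, te = where == "train", where == "val", where == "test"
    if y[te].min() == y[te].max() or y[va].min() == y[va].max():
        raise DegenerateDataError("a held-out split lacks a class")

    weights = inverse_frequency_weights(y[tr])
    strength, probe = choose_l1_strength(
        X[tr], y[tr], X[va], y[va], weights=weights
    )

    logits = probe.decision_function(X)
    fusion_X, _ = build_fusion_features(logits, markers, train_mask=tr)
    fusion = LogisticProbe(penalty="l2", class_weights=weights)
    fusion.fit(fusion_X[tr], y[tr])

    probe_p = probe.predict_proba(X[te])[:, 1]
    fusion_p = fusion.predict_proba(fusion_X[te])[:, 1]
    return ExperimentResult(
        probe_auc=roc_auc(probe_p, y[te]),
        fusion_auc=roc_auc(fusion_p, y[te]),
        probe_bacc=balanced_accuracy(confusion_at_threshold(probe_p, y[te])),
        fusion_bacc=balanced_accuracy(confusion_at_threshold(fusion_p, y[te])),
        l1_strength=strength,
        split_sizes={s: int((where == s).sum()) for s in ("train", "val", "test")},
    )
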