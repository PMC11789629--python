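"""End-to-end orchestration of the analysis stages.

These functions wire the per-module operations together the way the CLI
and the reproduction script use them: QC -> filtering -> peak matrix ->
markers -> modules -> deviation scores -> ternary gating, and pseudobulk
tracks -> binarization -> HMM -> segmentation -> transition table.
"""
from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .hmm import (
    BinaryTrackSet,
    HMMModel,
    Segmentation,
    binarize_tracks,
    fit_hmm,
    label_states,
    posterior_decode,
    state_transition_table,
)
from .intervals import intervals_to_frame
from .io import FragmentSet, GeneAnnotation
from .matrix import CellFeatureMatrix, build_matrix, find_marker_peaks, tfidf_normalize
from .modules import (
    PeakModule,
    define_modules,
    gate_subpopulation,
    normalize_ternary,
    score_modules,
    subpopulation_report,
)
from .qc import compute_qc_table, filter_fragments

log = logging.getLogger("epihet")


def run_qc(
    fragments: FragmentSet, peaks, blacklist, annotation: GeneAnnotation, config: PipelineConfig
) -> Tuple[pd.DataFrame, FragmentSet]:
    """QC table + fragments restricted to passing cells."""
    qc_table = compute_qc_table(fragments, peaks, blacklist, annotation, config)
    kept = filter_fragments(fragments, qc_table)
    log.info("QC: %d/%d cells pass", int(qc_table["pass"].sum()), len(qc_table))
    return qc_table, kept


def run_segmentation(
    bins: pd.DataFrame, mark_counts: np.ndarray, marks, config: PipelineConfig, seed: int
) -> Tuple[HMMModel, Segmentation, BinaryTrackSet]:
    """Binarize pseudobulk mark counts, fit the HMM, decode and label."""
    tracks = binarize_tracks(bins, mark_counts, marks, config.binarize_pvalue)
    model = fit_hmm(
        tracks,
        n_states=config.n_states,
        seed=seed,
        n_restarts=config.hmm_n_restarts,
        tol=config.hmm_tol,
        max_iter=config.hmm_max_iter,
        floor=config.hmm_prob_floor,
    )
    model.labels = label_states(model)
    seg = posterior_decode(model, tracks)
    return model, seg, tracks


def run_module_pipeline(
    fragments: FragmentSet,
    peaks: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig,
    seed: int,
    source: str,
    target: str,
) -> Dict[str, object]:
    """Markers -> top-N modules -> deviation Z -> ternary -> gate -> report.

    ``labels`` maps barcode -> condition for QC-passing cells.  ``source``
    is the primary condition whose cells are gated; ``target`` the
    progressed condition defining the second gate axis.
    """
    peaks_f = peaks if isinstance(peaks, pd.DataFrame) else intervals_to_frame(list(peaks))
    cells = [b for b in labels.index if b in set(fragments.barcodes)]
    cfm = build_matrix(fragments, peaks_f, cells=cells)
    keep = np.asarray(cfm.matrix.sum(axis=0)).ravel() > 0
    if not keep.all():
        cfm = CellFeatureMatrix(cfm.matrix[:, keep], cfm.features, list(np.array(cfm.cells)[keep]), "raw")
    tfidf = tfidf_normalize(cfm)
    markers = find_marker_peaks(tfidf, labels, alpha=config.marker_alpha, raw_p=config.marker_raw_p)
    modules = define_modules(markers, top_n=config.top_n_peaks)
    scores = score_modules(cfm, modules, n_background=config.n_background, seed=seed)
    coords = normalize_ternary(scores, shift_scope=config.ternary_shift_scope)
    variant = "both_above" if config.prepcr_gate_variant == "both_above" else "first_above_second_below"
    gate = gate_subpopulation(
        coords, (source, target), threshold=config.gate_threshold, variant=variant
    )
    # only source-condition cells can be called transitional
    lab = labels.reindex(coords.index)
    gate[lab != source] = "none"
    return {
        "matrix": cfm,
        "markers": markers,
        "modules": modules,
        "scores": scores,
        "coords": coords,
        "gate": gate,
    }


def attach_report(
    result: Dict[str, object],
    qc_table: pd.DataFrame,
    labels: pd.Series,
    source: str,
    target: str,
) -> Dict[str, object]:
    scores: pd.DataFrame = result["scores"]
    parent = [b for b in scores.index if labels.get(b) == source]
    progressed = [b for b in scores.index if labels.get(b) == target]
    result["report"] = subpopulation_report(
        result["gate"], scores, qc_table, parent, progressed, progressed_module=target
    )
    return result
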