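"""Chromatin-state segmentation with a multivariate hidden Markov model.

The segmenter mirrors the standard multi-mark chromatin-state workflow:
pseudobulk mark tracks are binarized per 200 bp bin against a genome-wide
Poisson background, a K-state HMM with independent Bernoulli emissions per
mark is fit by Baum-Welch (EM) with random restarts, bins are assigned by
forward-backward posterior decoding, and states are labelled E1..E5 from
their emission signatures:

    E1 weak promoter      H3K4me3 only
    E2 active promoter    H3K4me3 + H3K27ac
    E3 active enhancer    H3K27ac only
    E4 unmodified         no mark
    E5 heterochromatin    H3K27me3 only

Chromosomes are treated as independent observation sequences.  The scaled
forward-backward recursions are numba-jitted; everything else is numpy.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import poisson

log = logging.getLogger("epihet")

#: canonical emission signatures (H3K4me3, H3K27ac, H3K27me3) -> E-label
CANONICAL_PATTERNS: Dict[Tuple[int, int, int], str] = {
    (1, 0, 0): "E1",
    (1, 1, 0): "E2",
    (0, 1, 0): "E3",
    (0, 0, 0): "E4",
    (0, 0, 1): "E5",
}

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K27me3")


@dataclass
class BinaryTrackSet:
    """Binarized mark presence per 200 bp bin.

    ``tracks`` is bins x marks in {0,1}; ``bins`` the tiling frame (chrom,
    start, end); ``thresholds`` records the per-mark binarization count
    cutoff actually applied.
    """

    bins: pd.DataFrame
    marks: Tuple[str, ...]
    tracks: np.ndarray
    thresholds: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.tracks = np.asarray(self.tracks)
        if self.tracks.shape != (len(self.bins), len(self.marks)):
            raise ValueError("tracks shape must be (n_bins, n_marks)")
        if not np.isin(self.tracks, (0, 1)).all():
            raise ValueError("tracks must be binary")

    def sequences(self) -> List[np.ndarray]:
        """Per-chromosome observation matrices, in bin order."""
        out = []
        for _, sub in self.bins.groupby("chrom", sort=False):
            out.append(self.tracks[sub.index.to_numpy()])
        return out


@dataclass
class HMMModel:
    startprob: np.ndarray          # (K,)
    transmat: np.ndarray           # (K, K), rows sum to 1
    emissionprob: np.ndarray       # (K, M) Bernoulli P(mark present | state)
    marks: Tuple[str, ...]
    loglik_trace: List[float] = field(default_factory=list)
    labels: Optional[Dict[int, str]] = None

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    def validate(self, tol: float = 1e-12) -> None:
        if abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ValueError("startprob must sum to 1")
        if np.abs(self.transmat.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transmat rows must sum to 1")
        if ((self.emissionprob < -tol) | (self.emissionprob > 1 + tol)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emissionprob": self.emissionprob.tolist(),
            "marks": list(self.marks),
            "loglik_trace": list(map(float, self.loglik_trace)),
            "labels": {str(k): v for k, v in (self.labels or {}).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["startprob"]),
            np.asarray(d["transmat"]),
            np.asarray(d["emissionprob"]),
            tuple(d["marks"]),
            d.get("loglik_trace", []),
            {int(k): v for k, v in d.get("labels", {}).items()} or None,
        )


@dataclass
class Segmentation:
    bins: pd.DataFrame
    posterior: np.ndarray          # (n_bins, K)
    states: np.ndarray             # (n_bins,) argmax posterior
    labels: Dict[int, str]

    @property
    def state_labels(self) -> np.ndarray:
        lut = np.array([self.labels[k] for k in range(self.posterior.shape[1])])
        return lut[self.states]

    def to_bed(self, path: str | Path) -> None:
        lab = self.state_labels
        with open(path, "w") as fh:
            for (chrom, start, end), label in zip(
                self.bins[["chrom", "start", "end"]].itertuples(index=False), lab
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# binarization


def binarize_tracks(
    bins: pd.DataFrame,
    counts: np.ndarray,
    marks: Sequence[str] = DEFAULT_MARKS,
    pvalue: float = 1e-4,
) -> BinaryTrackSet:
    """Binarize per-bin mark counts against a genome-wide Poisson background.

    A bin is called present (1) for a mark iff the upper-tail Poisson
    p-value of its count under the mark's genome-wide mean rate is below
    ``pvalue``, i.e. count >= the smallest c with P(X >= c) < pvalue.
    """
    counts = np.asarray(counts)
    if counts.shape != (len(bins), len(marks)):
        raise ValueError("counts shape must be (n_bins, n_marks)")
    tracks = np.zeros_like(counts, dtype=np.int8)
    thresholds: Dict[str, float] = {}
    for j, mark in enumerate(marks):
        col = counts[:, j]
        total = col.sum()
        if total == 0:
            log.warning("mark %s has zero total signal; all-zero track", mark)
            thresholds[mark] = np.inf
            continue
        lam = total / len(col)
        # smallest count with upper-tail P(X >= c) < pvalue
        thr = int(poisson.isf(pvalue, lam)) + 1
        thresholds[mark] = thr
        tracks[:, j] = (col >= thr).astype(np.int8)
    return BinaryTrackSet(bins, tuple(marks), tracks, thresholds)


# ---------------------------------------------------------------------------
# numba kernels (scaled forward-backward)


@njit(cache=False)
def _forward_scaled(startprob, transmat, lik):
    T, K = lik.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = startprob * lik[0]
    s = a.sum()
    if s <= 0.0:
        s = 1e-300
    alpha[0] = a / s
    scale[0] = s
    for t in range(1, T):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * transmat[j, k]
            alpha[t, k] = acc * lik[t, k]
        s = alpha[t].sum()
        if s <= 0.0:
            s = 1e-300
        for k in range(K):
            alpha[t, k] /= s
        scale[t] = s
    return alpha, scale


@njit(cache=False)
def _backward_scaled(transmat, lik, scale):
    T, K = lik.shape
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += transmat[k, j] * lik[t + 1, j] * beta[t + 1, j]
            beta[t, k] = acc / scale[t + 1]
    return beta


@njit(cache=False)
def _xi_accumulate(alpha, beta, transmat, lik, scale):
    T, K = lik.shape
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j] * transmat[j, k] * lik[t + 1, k] * beta[t + 1, k] / scale[t + 1]
                )
    return xi_sum


def _emission_likelihood(emissionprob: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """(T, K) likelihood of each observation row under each state."""
    B = np.clip(emissionprob, 1e-12, 1 - 1e-12)
    loglik = obs @ np.log(B).T + (1 - obs) @ np.log(1 - B).T
    return np.exp(loglik)


def forward_backward(
    model: HMMModel, obs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Posterior state probabilities, pairwise transition expectations and
    the log-likelihood of one observation sequence."""
    lik = _emission_likelihood(model.emissionprob, obs.astype(np.float64))
    alpha, scale = _forward_scaled(model.startprob, model.transmat, lik)
    beta = _backward_scaled(model.transmat, lik, scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = _xi_accumulate(alpha, beta, model.transmat, lik, scale)
    return gamma, xi_sum, float(np.log(scale).sum())


# ---------------------------------------------------------------------------
# Baum-Welch


def _random_init(K: int, M: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    startprob = rng.dirichlet(np.ones(K))
    transmat = rng.uniform(0.0, 1.0, size=(K, K)) + 5.0 * np.eye(K)
    transmat /= transmat.sum(axis=1, keepdims=True)
    emissionprob = rng.uniform(0.1, 0.9, size=(K, M))
    return startprob, transmat, emissionprob


def _em_run(
    sequences: List[np.ndarray],
    startprob: np.ndarray,
    transmat: np.ndarray,
    emissionprob: np.ndarray,
    marks: Tuple[str, ...],
    tol: float,
    max_iter: int,
    floor: float,
) -> HMMModel:
    K = len(startprob)
    model = HMMModel(startprob, transmat, emissionprob, marks, [])
    prev_ll = -np.inf
    for _ in range(max_iter):
        start_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gamma_acc = np.zeros(K)
        gx_acc = np.zeros((K, len(marks)))
        ll = 0.0
        for obs in sequences:
            gamma, xi_sum, seq_ll = forward_backward(model, obs)
            ll += seq_ll
            start_acc += gamma[0]
            xi_acc += xi_sum
            gamma_acc += gamma.sum(axis=0)
            gx_acc += gamma.T @ obs
        model.loglik_trace.append(ll)
        new_start = start_acc / start_acc.sum()
        new_trans = xi_acc + floor
        new_trans /= new_trans.sum(axis=1, keepdims=True)
        new_emis = np.clip(gx_acc / np.maximum(gamma_acc[:, None], 1e-300), floor, 1 - floor)
        model = HMMModel(new_start, new_trans, new_emis, marks, model.loglik_trace)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return model


def fit_hmm(
    tracks: BinaryTrackSet,
    n_states: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    floor: float = 1e-6,
) -> HMMModel:
    """Fit a K-state Bernoulli-emission HMM by Baum-Welch with restarts.

    Each restart draws a random initialization from ``seed``; the model with
    the best final log-likelihood wins.  The log-likelihood trace of the
    winning run is monotone non-decreasing (an EM guarantee, up to the
    probability floor applied to transitions/emissions).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    sequences = [s.astype(np.float64) for s in tracks.sequences()]
    n_bins = sum(len(s) for s in sequences)
    if n_bins < n_states:
        raise ValueError("fewer bins than states")
    M = len(tracks.marks)

    if n_states == 1:
        # closed form: emission = empirical mark frequencies
        obs = np.vstack(sequences)
        emis = obs.mean(axis=0, keepdims=True)
        model = HMMModel(np.ones(1), np.ones((1, 1)), emis, tracks.marks, [])
        _, _, ll = forward_backward(model, obs)
        model.loglik_trace.append(ll)
        return model

    if np.ptp(np.vstack(sequences), axis=0).max() == 0:
        warnings.warn("all observations identical; effective single state")

    rng = np.random.Generator(np.random.PCG64(seed))
    best: HMMModel | None = None
    for _ in range(n_restarts):
        init = _random_init(n_states, M, rng)
        model = _em_run(sequences, *init, tracks.marks, tol, max_iter, floor)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    best.validate()
    return best


def posterior_decode(model: HMMModel, tracks: BinaryTrackSet) -> Segmentation:
    """Forward-backward posterior decoding per chromosome.

    Per-bin state = argmax posterior; ties break to the lowest state index
    (numpy argmax convention).
    """
    posteriors = []
    for obs in tracks.sequences():
        gamma, _, _ = forward_backward(model, obs.astype(np.float64))
        posteriors.append(gamma)
    posterior = np.vstack(posteriors)
    states = posterior.argmax(axis=1)
    labels = model.labels if model.labels is not None else label_states(model)
    return Segmentation(tracks.bins, posterior, states, labels)


def label_states(model: HMMModel, threshold: float = 0.5) -> Dict[int, str]:
    """Map HMM states to E1..E5 labels from their emission signatures.

    Each state's Bernoulli row is thresholded at ``threshold`` per mark and
    matched against the canonical patterns.  Unmatched signatures get a
    descriptive mark-combination label; duplicate matches are suffixed.
    """
    labels: Dict[int, str] = {}
    seen: Dict[str, int] = {}
    for k in range(model.n_states):
        sig = tuple((model.emissionprob[k] >= threshold).astype(int))
        base = CANONICAL_PATTERNS.get(sig)
        if base is None:
            present = [m for m, bit in zip(model.marks, sig) if bit]
            base = "+".join(present) if present else "E4"
        if base in seen:
            seen[base] += 1
            warnings.warn(f"states share emission signature {base}; disambiguating")
            labels[k] = f"{base}.{seen[base]}"
        else:
            seen[base] = 1
            labels[k] = base
    return labels


def state_transition_table(
    seg_a: Segmentation, seg_b: Segmentation, exclude: Tuple[str, str] = ("E4", "E4")
) -> Dict[str, object]:
    """Count bins by (label in A, label in B) between two segmentations.

    Bins unmodified in both conditions (E4 -> E4) are excluded from the
    reported table but retained in totals; their fraction is reported
    separately.  Requires identical bin tilings.
    """
    if not seg_a.bins[["chrom", "start", "end"]].equals(seg_b.bins[["chrom", "start", "end"]]):
        raise ValueError("segmentations must share an identical bin tiling")
    la, lb = seg_a.state_labels, seg_b.state_labels
    pairs = pd.DataFrame({"from": la, "to": lb})
    counts = pairs.value_counts().rename("n_bins").reset_index()
    excluded_mask = (counts["from"] == exclude[0]) & (counts["to"] == exclude[1])
    n_excluded = int(counts.loc[excluded_mask, "n_bins"].sum())
    reported = counts[~excluded_mask].sort_values("n_bins", ascending=False).reset_index(drop=True)
    total = len(la)
    return {
        "table": reported,
        "n_excluded_stable_unmodified": n_excluded,
        "stable_unmodified_fraction": n_excluded / total if total else 0.0,
        "n_bins_total": total,
    }
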