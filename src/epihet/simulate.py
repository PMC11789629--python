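"""Ground-truthed synthetic cohorts with the statistical structure the
pipeline assumes.

The generator inverts the models the analysis fits:

* a hidden 5-state chromatin landscape (Markov chain over 200 bp bins)
  emitting three histone marks (H3K4me3, H3K27ac, H3K27me3) as independent
  Bernoulli draws per bin;
* per-cell fragment sampling at rates proportional to state activity x
  (CN/2) x a condition-specific boost inside that condition's planted
  marker-peak module, with a planted "transitional" subpopulation whose
  rate profile is a 50/50 mixture of two conditions;
* integer copy-number segments that multiplicatively scale fragment rate
  and additively shift expression;
* per-gene expression with CN, chromatin-state and CN x state interaction
  effects.

Everything is reproducible bit-for-bit from (config, seed), and all planted
structure (state paths, modules, labels, CN, coefficients) is emitted in a
machine-readable truth object.

The default toy genome (2 chromosomes x 5 Mb, 200 bp bins) is deliberately
desk-scale; effect sizes are chosen for testability of the pipeline's
operating characteristics and are synthetic, not estimates of any real
tumor's biology.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import make_genome_bins, merge_intervals
from .io import FragmentSet, GeneAnnotation
from .hmm import DEFAULT_MARKS

log = logging.getLogger("epihet")

STATE_LABELS = ("E1", "E2", "E3", "E4", "E5")

#: default emission matrix (states x marks): P(mark present | state)
DEFAULT_EMISSION = np.array(
    [
        [0.90, 0.08, 0.03],  # E1 weak promoter: H3K4me3 only
        [0.90, 0.90, 0.02],  # E2 active promoter: both activating marks
        [0.08, 0.90, 0.03],  # E3 active enhancer: H3K27ac only
        [0.02, 0.02, 0.02],  # E4 unmodified
        [0.03, 0.03, 0.90],  # E5 heterochromatin: H3K27me3 only
    ]
)

#: default transition matrix: diagonal-dominant, E4 heavily occupied so most
#: of the genome is unmodified, as in real chromatin landscapes
DEFAULT_TRANSITION = np.array(
    [
        [0.800, 0.060, 0.020, 0.110, 0.010],
        [0.050, 0.820, 0.050, 0.070, 0.010],
        [0.020, 0.060, 0.800, 0.110, 0.010],
        [0.0030, 0.0015, 0.0030, 0.9900, 0.0025],
        [0.004, 0.002, 0.004, 0.080, 0.910],
    ]
)

#: fragment-sampling activity per state (arbitrary rate units per bin),
#: for an H3K27ac-like assay: promoters/enhancers active, E4/E5 background
DEFAULT_ACTIVITY = np.array([0.30, 1.00, 1.00, 0.02, 0.05])


@dataclass
class SimulationConfig:
    genome: Dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    bin_width: int = 200
    marks: Tuple[str, ...] = DEFAULT_MARKS
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    emission: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION.copy())
    activity: np.ndarray = field(default_factory=lambda: DEFAULT_ACTIVITY.copy())
    conditions: Tuple[str, ...] = ("PRI", "MET", "PCR")
    state_change_fraction: float = 0.02   # bins re-drawn in each progressed condition

    # cells
    n_cells_per_condition: int = 300
    mean_depth: float = 3_000.0
    module_n_peaks: int = 50
    module_peak_bins: int = 5             # 1 kb module peaks
    module_boost: float = 8.0             # absolute activity in own-module bins
    transitional_fraction: float = 0.10   # of source-condition cells
    transitional_mixture: float = 0.5
    transitional_source: str = "PRI"
    transitional_target: str = "PCR"
    # fragment length mixture: sub-nucleosomal and mono-nucleosomal
    sub_fraction: float = 0.6
    sub_range: Tuple[int, int] = (50, 120)
    mono_range: Tuple[int, int] = (160, 250)
    n_qc_fail_per_mode: int = 3

    # copy number
    n_cn_segments_per_chrom: int = 10
    cn_values: Tuple[int, ...] = (1, 2, 3, 4, 5)
    cn_probs: Tuple[float, ...] = (0.06, 0.70, 0.15, 0.06, 0.03)
    amplicon: Tuple[str, int, int, str, int] = ("chr1", 0, 500_000, "MET", 4)

    # genes / expression
    n_genes: int = 2_000
    promoter_biased_fraction: float = 0.5  # genes placed at active-segment starts
    beta0: float = 0.0
    beta_cn: float = 0.3
    beta_state: float = 0.5
    beta_int: float = 0.3
    sigma: float = 0.5
    n_replicates: int = 3
    base_log2_expr_mean: float = 5.0
    base_log2_expr_sd: float = 1.0

    # blacklist
    blacklist: Tuple[Tuple[str, int, int], ...] = (
        ("chr1", 2_000_000, 2_050_000),
        ("chr2", 2_000_000, 2_050_000),
    )

    # pseudobulk mark-count emission rates (per 200 bp bin)
    mark_bg_rate: float = 0.1
    mark_signal_rate: float = 10.0


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for consumption by tests."""

    config: SimulationConfig
    bins: pd.DataFrame
    state_paths: Dict[str, np.ndarray]
    mark_tracks: Dict[str, np.ndarray]            # binary, bins x marks
    module_bins: Dict[str, np.ndarray]            # global bin indices
    module_peaks: Dict[str, pd.DataFrame]
    cell_labels: pd.DataFrame                     # barcode, condition, subpop
    cn_segments: Dict[str, pd.DataFrame]          # chrom, start, end, cn
    cn_per_bin: Dict[str, np.ndarray]
    genes: pd.DataFrame                           # symbol, chrom, tss, strand
    gene_truth: pd.DataFrame                      # per gene x condition: cn, active, z
    coefficients: Dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_labels": list(STATE_LABELS),
            "transition": self.config.transition.tolist(),
            "emission": self.config.emission.tolist(),
            "activity": self.config.activity.tolist(),
            "state_paths": {c: p.tolist() for c, p in self.state_paths.items()},
            "module_bins": {c: b.tolist() for c, b in self.module_bins.items()},
            "cell_labels": self.cell_labels.to_dict(orient="list"),
            "cn_segments": {c: df.to_dict(orient="list") for c, df in self.cn_segments.items()},
            "coefficients": self.coefficients,
            "gene_truth": self.gene_truth.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# hidden landscape


def simulate_genome_states(
    n_bins: int,
    n_states: int,
    transition: np.ndarray,
    emission: np.ndarray,
    seed: int,
    startprob: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample a Markov state path and per-bin Bernoulli mark tracks.

    Returns (path, tracks) with path in {0..K-1} and tracks binary
    (n_bins x n_marks).
    """
    transition = np.asarray(transition, dtype=float)
    emission = np.asarray(emission, dtype=float)
    if transition.shape != (n_states, n_states):
        raise ValueError("transition must be K x K")
    if np.abs(transition.sum(axis=1) - 1.0).max() > 1e-8 or (transition < 0).any():
        raise ValueError("transition rows must be non-negative and sum to 1")
    if ((emission < 0) | (emission > 1)).any():
        raise ValueError("emission probabilities must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    if startprob is None:
        # stationary distribution of the chain
        vals, vecs = np.linalg.eig(transition.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        startprob = pi / pi.sum()
    path = np.empty(n_bins, dtype=np.int64)
    path[0] = rng.choice(n_states, p=startprob)
    # draw all uniforms up front; step through the chain with the CDF rows
    cdf = np.cumsum(transition, axis=1)
    u = rng.random(n_bins)
    for t in range(1, n_bins):
        path[t] = np.searchsorted(cdf[path[t - 1]], u[t])
    tracks = (rng.random((n_bins, emission.shape[1])) < emission[path]).astype(np.int8)
    return path, tracks


def simulate_mark_counts(
    tracks: np.ndarray, seed: int, bg_rate: float = 0.1, signal_rate: float = 10.0
) -> np.ndarray:
    """Pseudobulk per-bin mark counts: Poisson(bg) off-track, Poisson(signal) on."""
    rng = np.random.Generator(np.random.PCG64(seed))
    lam = np.where(tracks > 0, signal_rate, bg_rate)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# cohort assembly helpers


def _per_bin_cn(bins: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    cn = np.full(len(bins), 2, dtype=np.int64)
    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    for row in segments.itertuples(index=False):
        mask = (chroms == row.chrom) & (starts >= row.start) & (starts < row.end)
        cn[mask] = row.cn
    return cn


def _draw_cn_segments(cfg: SimulationConfig, condition: str, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, length in cfg.genome.items():
        if condition == cfg.conditions[0]:
            rows.append((chrom, 0, length, 2))  # primary condition kept diploid
            continue
        n_seg = cfg.n_cn_segments_per_chrom
        cuts = np.sort(rng.choice(np.arange(1, length // cfg.bin_width), n_seg - 1, replace=False)) * cfg.bin_width
        bounds = np.concatenate([[0], cuts, [length]])
        cns = rng.choice(cfg.cn_values, size=n_seg, p=cfg.cn_probs)
        for s, e, c in zip(bounds[:-1], bounds[1:], cns):
            rows.append((chrom, int(s), int(e), int(c)))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    a_chrom, a_start, a_end, a_cond, a_cn = cfg.amplicon
    if condition == a_cond:
        # plant a deterministic amplicon so amplified-locus tests are stable
        keep = ~((seg["chrom"] == a_chrom) & (seg["start"] < a_end) & (seg["end"] > a_start))
        clipped = seg[keep].copy()
        partial = seg[~keep].copy()
        partial_rows = []
        for row in partial.itertuples(index=False):
            if row.start < a_start:
                partial_rows.append((row.chrom, row.start, a_start, row.cn))
            if row.end > a_end:
                partial_rows.append((row.chrom, a_end, row.end, row.cn))
        seg = pd.concat(
            [
                clipped,
                pd.DataFrame(partial_rows, columns=seg.columns),
                pd.DataFrame([(a_chrom, a_start, a_end, a_cn)], columns=seg.columns),
            ],
            ignore_index=True,
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return seg


def _place_modules(
    cfg: SimulationConfig, n_bins: int, rng: np.random.Generator, forbidden: np.ndarray
) -> Dict[str, np.ndarray]:
    """Disjoint per-condition marker-peak bin sets (module_n_peaks peaks of
    module_peak_bins consecutive bins each)."""
    taken = forbidden.copy()
    out: Dict[str, np.ndarray] = {}
    width = cfg.module_peak_bins
    for cond in cfg.conditions:
        chosen = []
        attempts = 0
        while len(chosen) < cfg.module_n_peaks:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError("could not place module peaks; genome too small")
            start = int(rng.integers(0, n_bins - width))
            span = np.arange(start, start + width)
            if taken[span].any():
                continue
            taken[span] = True
            chosen.append(span)
        out[cond] = np.sort(np.concatenate(chosen))
    return out


def _bins_to_intervals(bins: pd.DataFrame, idx: np.ndarray) -> pd.DataFrame:
    sel = bins.iloc[idx][["chrom", "start", "end"]].reset_index(drop=True)
    return merge_intervals(sel)


def _condition_rates(
    cfg: SimulationConfig,
    path: np.ndarray,
    module_bins: np.ndarray,
    cn_per_bin: np.ndarray,
    blacklist_bins: np.ndarray,
) -> np.ndarray:
    rate = cfg.activity[path].astype(float)
    rate[module_bins] = cfg.module_boost
    rate = rate * (cn_per_bin / 2.0)
    rate[blacklist_bins] = 0.0
    return rate


def _sample_fragment_lengths(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    is_sub = rng.random(n) < cfg.sub_fraction
    lo_s, hi_s = cfg.sub_range
    lo_m, hi_m = cfg.mono_range
    lengths = np.where(
        is_sub,
        rng.integers(lo_s, hi_s + 1, size=n),
        rng.integers(lo_m, hi_m + 1, size=n),
    )
    return lengths


def _fragments_from_bins(
    cfg: SimulationConfig,
    bins: pd.DataFrame,
    bin_idx: np.ndarray,
    lengths: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    chrom = bins["chrom"].to_numpy()[bin_idx]
    bstart = bins["start"].to_numpy()[bin_idx]
    bend = bins["end"].to_numpy()[bin_idx]
    centers = bstart + rng.integers(0, np.maximum(bend - bstart, 1))
    starts = centers - lengths // 2
    chrom_len = pd.Series(cfg.genome)[chrom].to_numpy()
    starts = np.clip(starts, 0, chrom_len - lengths)
    return chrom, starts, starts + lengths


def simulate_cells(
    truth: "SyntheticTruth",
    n_cells_per_condition: Optional[int] = None,
    mean_depth: Optional[float] = None,
    seed: int = 0,
) -> Tuple[FragmentSet, pd.DataFrame]:
    """Sample per-cell fragments for every condition in the truth object.

    Returns the fragment set and a label frame (barcode, condition, subpop).
    Planted cells: ``transitional`` cells mix two conditions' rate profiles;
    ``qc_*`` cells each violate exactly one QC threshold by a wide margin.
    """
    cfg = truth.config
    n_cells = n_cells_per_condition if n_cells_per_condition is not None else cfg.n_cells_per_condition
    depth = mean_depth if mean_depth is not None else cfg.mean_depth
    if depth <= 0:
        raise ValueError("mean depth must be positive")
    rng = np.random.Generator(np.random.PCG64(seed))
    bins = truth.bins
    n_bins = len(bins)

    blacklist_bins = _blacklist_bin_mask(cfg, bins)
    rates = {
        c: _condition_rates(cfg, truth.state_paths[c], truth.module_bins[c], truth.cn_per_bin[c], blacklist_bins)
        for c in cfg.conditions
    }
    src, tgt = cfg.transitional_source, cfg.transitional_target
    if src not in rates or tgt not in rates:
        raise ValueError("transitional source/target must be simulated conditions")
    mix = cfg.transitional_mixture
    rates_trans = mix * rates[src] + (1.0 - mix) * rates[tgt]

    tss = truth.genes["tss"].to_numpy()
    tss_chrom = truth.genes["chrom"].to_numpy()

    records: List[pd.DataFrame] = []
    labels: List[Tuple[str, str, str]] = []

    def emit(barcode: str, cond: str, subpop: str, bin_p: np.ndarray, nf: int, mono_only=False):
        if nf == 0:
            records.append(pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"]))
        else:
            cdf = np.cumsum(bin_p)
            cdf /= cdf[-1]
            idx = np.searchsorted(cdf, rng.random(nf), side="right")
            if mono_only:
                lo, hi = cfg.mono_range
                lengths = rng.integers(lo, hi + 1, size=nf)
            else:
                lengths = _sample_fragment_lengths(cfg, nf, rng)
            chrom, starts, ends = _fragments_from_bins(cfg, bins, idx, lengths, rng)
            records.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "barcode": barcode, "count": 1}
                )
            )
        labels.append((barcode, cond, subpop))

    # regular + transitional cells
    n_trans = int(round(cfg.transitional_fraction * n_cells))
    for cond in cfg.conditions:
        trans_ids = set(rng.choice(n_cells, size=n_trans, replace=False).tolist()) if cond == src else set()
        for i in range(n_cells):
            barcode = f"{cond}_{i:04d}"
            nf = int(rng.poisson(depth))
            if i in trans_ids:
                emit(barcode, cond, "transitional", rates_trans, nf)
            else:
                emit(barcode, cond, "normal", rates[cond], nf)

    # planted QC failures (source condition), one violated threshold each
    n_fail = cfg.n_qc_fail_per_mode
    base = rates[src]
    uniform = (~blacklist_bins).astype(float)
    for j in range(n_fail):
        emit(f"{src}_faillow{j}", src, "qc_low_umr", base, int(rng.poisson(400)))
        emit(f"{src}_failhigh{j}", src, "qc_high_umr", base, int(rng.poisson(220_000)))
        emit(f"{src}_failfrip{j}", src, "qc_low_frip", uniform, int(rng.poisson(depth)))
        # 80% normal profile + 20% of fragments inside the blacklist
        nf = int(rng.poisson(depth))
        n_bl = int(round(0.2 * nf))
        bl_p = blacklist_bins.astype(float)
        cdf = np.cumsum(base) / base.sum()
        idx_norm = np.searchsorted(cdf, rng.random(nf - n_bl), side="right")
        cdf_bl = np.cumsum(bl_p) / bl_p.sum()
        idx_bl = np.searchsorted(cdf_bl, rng.random(n_bl), side="right")
        idx = np.concatenate([idx_norm, idx_bl])
        lengths = _sample_fragment_lengths(cfg, nf, rng)
        chrom, starts, ends = _fragments_from_bins(cfg, bins, idx, lengths, rng)
        bc = f"{src}_failbl{j}"
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "barcode": bc, "count": 1}))
        labels.append((bc, src, "qc_high_blacklist"))
        emit(f"{src}_failnuc{j}", src, "qc_high_nucleosome", base, int(rng.poisson(depth)), mono_only=True)
        # low TSS enrichment: fragments only in promoter flanks
        nf = int(rng.poisson(depth))
        gi = rng.integers(0, len(tss), size=nf)
        offset = rng.integers(910, 991, size=nf) * rng.choice([-1, 1], size=nf)
        centers = tss[gi] + offset
        length = 80
        starts = centers - length // 2
        chrom = tss_chrom[gi]
        chrom_len = pd.Series(cfg.genome)[chrom].to_numpy()
        starts = np.clip(starts, 0, chrom_len - length)
        bc = f"{src}_failtss{j}"
        records.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + length, "barcode": bc, "count": 1})
        )
        labels.append((bc, src, "qc_low_tss"))

    frame = pd.concat(records, ignore_index=True)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    frame["count"] = frame["count"].astype(np.int64)
    label_frame = pd.DataFrame(labels, columns=["barcode", "condition", "subpop"])
    return FragmentSet(frame, dict(cfg.genome)), label_frame


def _blacklist_bin_mask(cfg: SimulationConfig, bins: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, s, e in cfg.blacklist:
        mask |= (
            (bins["chrom"].to_numpy() == chrom)
            & (bins["start"].to_numpy() < e)
            & (bins["end"].to_numpy() > s)
        )
    return mask


def _peak_bin_mask(truth: "SyntheticTruth") -> np.ndarray:
    cfg = truth.config
    mask = np.zeros(len(truth.bins), dtype=bool)
    for cond in cfg.conditions:
        path = truth.state_paths[cond]
        mask |= np.isin(path, (0, 1, 2))  # E1/E2/E3 active states
        mask[truth.module_bins[cond]] = True
    mask &= ~_blacklist_bin_mask(cfg, truth.bins)
    return mask


def truth_peaks(truth: "SyntheticTruth") -> pd.DataFrame:
    """Peak set implied by the planted landscape: merged runs of active
    (E1/E2/E3) bins in any condition plus all module peaks, minus blacklist."""
    mask = _peak_bin_mask(truth)
    return _bins_to_intervals(truth.bins, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# genes and expression


def _place_genes(cfg: SimulationConfig, bins: pd.DataFrame, path: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_biased = int(round(cfg.promoter_biased_fraction * n))
    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    # candidate promoter sites: midpoints of active-state segments, so the
    # mark is centered on the TSS (as at real promoters) and the 900-1000 bp
    # flanks fall outside the marked run
    active = np.isin(path, (0, 1, 2))
    edges = np.diff(np.concatenate([[0], active.view(np.int8), [0]]))
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)
    same_chrom = chroms[run_starts] == chroms[np.maximum(run_ends - 1, 0)]
    candidates = ((run_starts + run_ends - 1) // 2)[same_chrom]
    chosen_biased = rng.choice(candidates, size=min(n_biased, len(candidates)), replace=False)
    lengths = pd.Series(cfg.genome)
    rows = []
    for i, b in enumerate(chosen_biased):
        rows.append((f"G{i:04d}", chroms[b], int(starts[b]) + cfg.bin_width // 2))
    n_rest = n - len(rows)
    for j in range(n_rest):
        chrom = rng.choice(list(cfg.genome))
        tss = int(rng.integers(5_000, lengths[chrom] - 5_000))
        rows.append((f"G{len(chosen_biased) + j:04d}", chrom, tss))
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "tss"])
    genes["strand"] = rng.choice(["+", "-"], size=len(genes))
    return genes.sort_values(["chrom", "tss"]).reset_index(drop=True)


def simulate_expression(truth: "SyntheticTruth", seed: int = 0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene expression Z-scores and replicate counts per condition.

    Z = beta0 + beta_cn*(CN-2) + beta_state*active + beta_int*(CN-2)*active
    + N(0, sigma^2), where ``active`` indicates an activating promoter mark
    in that condition.  Replicate counts are Poisson around 2^(base + Z), so
    the count table is monotone in Z.
    """
    cfg = truth.config
    rng = np.random.Generator(np.random.PCG64(seed))
    gt = truth.gene_truth.copy()
    noise = rng.normal(0.0, cfg.sigma, size=len(gt))
    gt["z"] = (
        cfg.beta0
        + cfg.beta_cn * (gt["cn"] - 2)
        + cfg.beta_state * gt["active"]
        + cfg.beta_int * (gt["cn"] - 2) * gt["active"]
        + noise
    )
    base = rng.normal(cfg.base_log2_expr_mean, cfg.base_log2_expr_sd, size=len(truth.genes))
    base_map = dict(zip(truth.genes["symbol"], base))
    count_rows = {}
    for cond in cfg.conditions:
        sub = gt[gt["condition"] == cond].set_index("symbol")
        mu = 2.0 ** (sub.index.map(base_map).to_numpy() + sub["z"].to_numpy())
        for r in range(cfg.n_replicates):
            count_rows[f"{cond}_rep{r + 1}"] = pd.Series(rng.poisson(mu), index=sub.index)
    counts = pd.DataFrame(count_rows)
    counts.index.name = "symbol"
    z_table = gt.pivot(index="symbol", columns="condition", values="z")
    return z_table, counts


# ---------------------------------------------------------------------------
# orchestrator


def build_truth(cfg: SimulationConfig, seed: int) -> SyntheticTruth:
    """Sample the hidden landscape, modules, CN and gene truth (no cells)."""
    from .integrate import promoter_state_call  # shared printed rule; no cycle

    rng = np.random.Generator(np.random.PCG64(seed))
    bins = make_genome_bins(cfg.genome, cfg.bin_width)
    n_bins = len(bins)
    K = cfg.transition.shape[0]

    # condition state paths: primary sampled from the chain; progressed
    # conditions perturb a fraction of bins
    base_path, base_tracks = simulate_genome_states(
        n_bins, K, cfg.transition, cfg.emission, seed=int(rng.integers(2**31))
    )
    state_paths = {cfg.conditions[0]: base_path}
    mark_tracks = {cfg.conditions[0]: base_tracks}
    for cond in cfg.conditions[1:]:
        path = base_path.copy()
        n_change = int(round(cfg.state_change_fraction * n_bins))
        idx = rng.choice(n_bins, size=n_change, replace=False)
        path[idx] = rng.integers(0, K, size=n_change)
        tracks = (rng.random((n_bins, cfg.emission.shape[1])) < cfg.emission[path]).astype(np.int8)
        state_paths[cond] = path
        mark_tracks[cond] = tracks

    blacklist_bins = np.zeros(n_bins, dtype=bool)
    for chrom, s, e in cfg.blacklist:
        blacklist_bins |= (
            (bins["chrom"].to_numpy() == chrom)
            & (bins["start"].to_numpy() < e)
            & (bins["end"].to_numpy() > s)
        )
    module_bins = _place_modules(cfg, n_bins, rng, blacklist_bins)
    module_peaks = {c: _bins_to_intervals(bins, b) for c, b in module_bins.items()}

    cn_segments = {c: _draw_cn_segments(cfg, c, rng) for c in cfg.conditions}
    cn_per_bin = {c: _per_bin_cn(bins, cn_segments[c]) for c in cfg.conditions}

    genes = _place_genes(cfg, bins, base_path, rng)

    # per-gene truth: CN at TSS and activating-mark status per condition
    pcfg = PipelineConfig()
    gene_rows = []
    chrom_offsets = {}
    off = 0
    for chrom, length in cfg.genome.items():
        chrom_offsets[chrom] = (off, int(np.ceil(length / cfg.bin_width)))
        off += chrom_offsets[chrom][1]
    label_lut = np.array(STATE_LABELS)
    for cond in cfg.conditions:
        labels = label_lut[state_paths[cond]]
        cn_bin = cn_per_bin[cond]
        for row in genes.itertuples(index=False):
            offset, nb = chrom_offsets[row.chrom]
            if row.strand == "+":
                w_s, w_e = row.tss - pcfg.promoter_upstream, row.tss + pcfg.promoter_downstream
            else:
                w_s, w_e = row.tss - pcfg.promoter_downstream, row.tss + pcfg.promoter_upstream
            b0 = max(w_s // cfg.bin_width, 0)
            b1 = min((w_e - 1) // cfg.bin_width, nb - 1)
            win = labels[offset + b0 : offset + b1 + 1]
            cat = promoter_state_call(win, pcfg)
            active = int(cat in ("both_marks", "H3K4me3_only", "H3K27ac_only"))
            tss_bin = offset + min(row.tss // cfg.bin_width, nb - 1)
            gene_rows.append((row.symbol, cond, int(cn_bin[tss_bin]), active, cat))
    gene_truth = pd.DataFrame(gene_rows, columns=["symbol", "condition", "cn", "active", "state_category"])

    return SyntheticTruth(
        config=cfg,
        bins=bins,
        state_paths=state_paths,
        mark_tracks=mark_tracks,
        module_bins=module_bins,
        module_peaks=module_peaks,
        cell_labels=pd.DataFrame(columns=["barcode", "condition", "subpop"]),
        cn_segments=cn_segments,
        cn_per_bin=cn_per_bin,
        genes=genes,
        gene_truth=gene_truth,
        coefficients={
            "beta0": cfg.beta0,
            "beta_cn": cfg.beta_cn,
            "beta_state": cfg.beta_state,
            "beta_int": cfg.beta_int,
            "sigma": cfg.sigma,
        },
    )


def simulate_cohort(cfg: SimulationConfig, seed: int):
    """Full synthetic cohort: truth + fragments + labels + expression."""
    truth = build_truth(cfg, seed)
    fragments, labels = simulate_cells(truth, seed=seed + 1)
    truth.cell_labels = labels
    z_table, counts = simulate_expression(truth, seed=seed + 2)
    return truth, fragments, z_table, counts


def write_cohort(truth: SyntheticTruth, fragments: FragmentSet, z_table: pd.DataFrame, counts: pd.DataFrame, outdir: str | Path) -> None:
    from .io import write_fragments, write_gene_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    write_fragments(fragments, outdir / "fragments.tsv.gz")
    truth_peaks(truth).to_csv(outdir / "peaks.bed", sep="\t", header=False, index=False)
    pd.DataFrame(list(cfg.blacklist), columns=["chrom", "start", "end"]).to_csv(
        outdir / "blacklist.bed", sep="\t", header=False, index=False
    )
    write_gene_annotation(GeneAnnotation(truth.genes[["symbol", "chrom", "tss", "strand"]]), outdir / "genes.tsv")
    for cond, seg in truth.cn_segments.items():
        seg.to_csv(outdir / f"cn_segments.{cond}.tsv", sep="\t", index=False)
    z_table.to_csv(outdir / "expression.tsv", sep="\t")
    counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
    truth.cell_labels.to_csv(outdir / "cell_labels.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
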