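"""Pipeline configuration.

Every threshold, window size and count used anywhere in the pipeline lives
here, with the defaults the analysis was designed around.  All stochastic
operations take their randomness from ``seed`` — there is no hidden global
state.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class QCThresholds:
    """Per-cell exclusion thresholds, applied with strict inequalities.

    A cell is *excluded* iff any of the following holds: umr < umr_min,
    umr > umr_max, frip < frip_min, blacklist fraction > blacklist_max,
    nucleosome signal > nucleosome_max, TSS enrichment < tss_min — or a
    metric is missing.
    """

    umr_min: int = 1_000
    umr_max: int = 100_000
    frip_min: float = 0.25
    blacklist_max: float = 0.01
    nucleosome_max: float = 5.0
    tss_min: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0

    # genomic bin widths
    cell_bin_width: int = 10_000   # cell x bin matrix resolution
    state_bin_width: int = 200     # chromatin-state segmentation resolution

    # QC
    qc: QCThresholds = field(default_factory=QCThresholds)
    tss_center_halfwidth: int = 100       # TSS +/- 100 bp signal window
    tss_flank: Tuple[int, int] = (900, 1000)  # flank window, bp from TSS
    nucleosome_mono_range: Tuple[int, int] = (147, 294)
    nucleosome_sub_max: int = 147

    # chromatin-state HMM
    n_states: int = 5
    binarize_pvalue: float = 1e-4
    hmm_n_restarts: int = 10
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    hmm_prob_floor: float = 1e-6

    # marker peaks / modules
    marker_alpha: float = 0.05       # BH-adjusted significance for ranking
    marker_raw_p: float | None = None  # optional raw p filter (e.g. 0.005)
    top_n_peaks: int = 50
    n_background: int = 50
    background_bins: int = 10        # accessibility strata (deciles)

    # ternary gating
    gate_threshold: float = 0.4
    prepcr_gate_variant: str = "both_above"  # or "first_above_second_below"
    ternary_shift_scope: str = "cohort"      # or "per_cell"

    # gene-state assignment
    promoter_upstream: int = 2_000
    promoter_downstream: int = 3_000
    min_marked_bins: int = 2          # "> 2 bins" rule: marked iff count > this
    single_mark_fraction: float = 0.6
    similar_band: Tuple[float, float] = (0.40, 0.60)
    hetero_fraction: float = 0.6

    # expression classing for transition enrichment
    up_lfc: float = 1.0
    down_lfc: float = -0.5
    de_pvalue: float = 0.001

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        for key in ("tss_flank", "nucleosome_mono_range", "similar_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML or JSON config file; missing keys keep defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(data or {})
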