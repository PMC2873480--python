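"""Microarray normalization, detection calling and candidate validation.

Raw probe intensities (probe x sample x replicate, long format) follow an
additive-background + multiplicative-noise model. Normalization is a
background-anchored generalized-log transform: per-array global background
subtraction (mean of the dimmest decile of features), multiplicative
inter-array calibration to a common median, the glog transform

    h(x) = log2(x + sqrt(x^2 + c^2)) - 1

(defined and smooth for x < 0, variance-stabilizing under the assumed noise
model), and replicate summarization by the median. Expression calls use a
fixed threshold on this glog2 scale: a target is detected in a sample when
its mature value exceeds the threshold, or rescued when the star value does;
a target whose star consistently outshines its mature is flagged
star-dominant (a likely arm-choice annotation error rather than a failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ArrayConfig:
    detection_threshold: float = 7.0  # glog2 units
    glog_c: float | None = None  # None: MAD of background features after subtraction
    background_quantile: float = 0.10


@dataclass
class NormalizedMatrix:
    """glog2-scale intensities, replicate-summarized.

    ``values`` is indexed by (target_id, kind) with one column per sample.
    """

    values: pd.DataFrame
    background: dict[str, float] = field(default_factory=dict)
    calibration: dict[str, float] = field(default_factory=dict)
    glog_c: float = 1.0

    def get(self, target: str, kind: str, sample: str) -> float:
        return float(self.values.loc[(target, kind), sample])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def targets(self) -> list[str]:
        return sorted({t for t, _ in self.values.index})


@dataclass
class DetectionCall:
    target: str
    sample: str
    detected: bool
    rescued_by_star: bool = False
    star_dominant: bool = False


@dataclass
class ValidationVerdict:
    candidate_id: str
    validated: bool
    basis: str | None  # 'array' | 'conserved_no_signal' | None
    novel: bool


@dataclass
class ValidationSummary:
    n_validated: int
    n_novel: int
    n_false_positive: int
    per_locus_expressed: dict[str, int] = field(default_factory=dict)


def glog(x, c: float):
    """Generalized log2: strictly increasing, ~log2(2x)-1 for x >> c."""
    x = np.asarray(x, dtype=float)
    return np.log2(x + np.sqrt(x * x + c * c)) - 1.0


def normalize(raw: pd.DataFrame, config: ArrayConfig | None = None) -> NormalizedMatrix:
    """Background-subtract, calibrate, glog-transform and summarize replicates.

    ``raw`` columns: probe_id, target_id, kind, sample, replicate, intensity.
    All samples must share the probe set.
    """
    config = config or ArrayConfig()
    required = {"probe_id", "target_id", "kind", "sample", "replicate", "intensity"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")

    probe_sets = raw.groupby("sample")["probe_id"].apply(frozenset)
    if probe_sets.nunique() != 1:
        raise ValueError("samples do not share the same probe design")

    work = raw.copy()
    background: dict[str, float] = {}
    bg_values: list[np.ndarray] = []
    for sample, grp in work.groupby("sample"):
        v = grp["intensity"].to_numpy(dtype=float)
        q = np.quantile(v, config.background_quantile)
        bg_feats = v[v <= q]
        b = float(bg_feats.mean())
        background[sample] = b
        work.loc[grp.index, "intensity"] = v - b
        bg_values.append(bg_feats - b)

    # multiplicative inter-array calibration to the common median
    medians = work.groupby("sample")["intensity"].median()
    target_median = float(medians.median())
    calibration: dict[str, float] = {}
    for sample, m in medians.items():
        f = target_median / m if m > 0 else 1.0
        calibration[sample] = float(f)
        idx = work["sample"] == sample
        work.loc[idx, "intensity"] = work.loc[idx, "intensity"] * f

    if config.glog_c is not None:
        c = float(config.glog_c)
    else:
        pooled = np.concatenate(bg_values) if bg_values else np.array([1.0])
        mad = float(np.median(np.abs(pooled - np.median(pooled))))
        c = mad if mad > 0 else 1.0

    work["glog"] = glog(work["intensity"].to_numpy(), c)
    values = (
        work.groupby(["target_id", "kind", "sample"])["glog"]
        .median()
        .unstack("sample")
        .sort_index()
    )
    values.index.names = ["target_id", "kind"]
    return NormalizedMatrix(
        values=values, background=background, calibration=calibration, glog_c=c
    )


def call_detection(
    matrix: NormalizedMatrix, config: ArrayConfig | None = None
) -> list[DetectionCall]:
    """Per-target, per-sample detected/rescued calls plus star dominance.

    Detected iff mature > threshold (strict), or star > threshold (strict;
    sets rescued_by_star). Star-dominant iff the star value exceeds the
    mature value in every sample where either exceeds the threshold (and
    there is at least one such sample).
    """
    config = config or ArrayConfig()
    t = config.detection_threshold
    calls: list[DetectionCall] = []
    values = matrix.values
    for target in matrix.targets:
        mature = values.loc[(target, "mature")] if (target, "mature") in values.index else None
        star = values.loc[(target, "star")] if (target, "star") in values.index else None
        above = []
        for sample in matrix.samples:
            m = float(mature[sample]) if mature is not None else -math.inf
            s = float(star[sample]) if star is not None else -math.inf
            if m > t or s > t:
                above.append(s > m)
        star_dom = bool(above) and all(above)
        for sample in matrix.samples:
            m = float(mature[sample]) if mature is not None else -math.inf
            s = float(star[sample]) if star is not None else -math.inf
            rescued = (m <= t) and (s > t)
            calls.append(
                DetectionCall(
                    target=target,
                    sample=sample,
                    detected=(m > t) or rescued,
                    rescued_by_star=rescued,
                    star_dominant=star_dom,
                )
            )
    return calls


def validate(
    predicted: dict[str, bool],
    conserved_flagged: set[str],
    calls: list[DetectionCall],
    loci: list[str] | None = None,
) -> tuple[list[ValidationVerdict], ValidationSummary]:
    """Produce the validated miRNA set from array calls plus conservation rescue.

    ``predicted`` maps candidate id -> known (True) / novel prediction
    (False). A candidate is validated when it is detected in at least one
    sample (basis 'array'), or when it is conservation-flagged and shows no
    signal anywhere (basis 'conserved_no_signal'). A candidate missing from
    the probe design raises.
    """
    by_target: dict[str, list[DetectionCall]] = {}
    for c in calls:
        by_target.setdefault(c.target, []).append(c)
    missing = [t for t in predicted if t not in by_target]
    if missing:
        raise ValueError(f"candidates absent from probe design: {sorted(missing)}")

    verdicts: list[ValidationVerdict] = []
    for target, known in predicted.items():
        detected_any = any(c.detected for c in by_target[target])
        if detected_any:
            verdicts.append(ValidationVerdict(target, True, "array", not known))
        elif target in conserved_flagged:
            verdicts.append(
                ValidationVerdict(target, True, "conserved_no_signal", not known)
            )
        else:
            verdicts.append(ValidationVerdict(target, False, None, False))

    n_validated = sum(v.validated for v in verdicts)
    n_novel = sum(v.validated and v.novel for v in verdicts)
    n_fp = sum(not v.validated for v in verdicts)
    per_locus: dict[str, int] = {}
    samples = loci or sorted({c.sample for c in calls})
    validated_ids = {v.candidate_id for v in verdicts if v.validated}
    for sample in samples:
        per_locus[sample] = sum(
            1
            for c in calls
            if c.sample == sample and c.detected and c.target in validated_ids
        )
    return verdicts, ValidationSummary(n_validated, n_novel, n_fp, per_locus)


def novel_fraction(n_novel: int, n_total: int) -> int:
    """Percentage of novel miRNAs among all expressed, rounded half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(math.floor(100 * n_novel / n_total + 0.5))
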