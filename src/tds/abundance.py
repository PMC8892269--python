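"""Polysome-association scoring, siRNA quartiles, qPCR arithmetic.

The polysome association score of a feature is the log2 fold-change of its
abundance (RPKM) in polysome-fraction libraries versus total RNA.  qPCR
relative expression and copy-number estimation use perfect-doubling delta-Ct
arithmetic (amplification efficiency 2, configurable), with Ct values averaged
over replicates and over the named reference targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureAbundance",
    "CtTable",
    "polysome_score",
    "quartile_partition",
    "relative_expression",
    "copy_number",
]


@dataclass(frozen=True)
class FeatureAbundance:
    """Abundance of one feature in total and polysome libraries."""

    feature_id: str
    total_rpkm: float
    polysome_rpkm: float
    sirna_level: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_rpkm < 0 or self.polysome_rpkm < 0 or self.sirna_level < 0:
            raise ValueError(f"{self.feature_id}: abundances must be >= 0")


@dataclass
class CtTable:
    """Long-format qPCR Ct values: one row per (sample, target, replicate)."""

    data: pd.DataFrame  # columns: sample, target, replicate, ct
    reference_targets: tuple[str, ...] = ("ACT2",)

    def __post_init__(self) -> None:
        required = {"sample", "target", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45)")

    def mean_ct(self, sample: str, target: str) -> float:
        sel = self.data[(self.data["sample"] == sample) & (self.data["target"] == target)]
        if sel.empty:
            raise KeyError(f"no Ct values for sample {sample!r}, target {target!r}")
        return float(sel["ct"].mean())

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))


def polysome_score(
    features: Iterable[FeatureAbundance], pseudocount: float = 0.01
) -> dict[str, float]:
    """log2((polysome RPKM + q) / (total RPKM + q)) per feature."""
    return {
        f.feature_id: math.log2((f.polysome_rpkm + pseudocount) / (f.total_rpkm + pseudocount))
        for f in features
    }


def quartile_partition(
    features: Sequence[FeatureAbundance], key: str = "sirna_level"
) -> dict[str, int]:
    """Quartile labels 1-4 by the empirical 25/50/75 percentiles of ``key``.

    Features whose key falls at or below a boundary take the lower quartile;
    tied keys share a label.  A fully degenerate key (all values equal) puts
    everything in quartile 1 with a warning.
    """
    feats = sorted(features, key=lambda f: (getattr(f, key), f.feature_id))
    vals = np.array([getattr(f, key) for f in feats], dtype=float)
    if len(vals) == 0:
        return {}
    if np.all(vals == vals[0]):
        warnings.warn("degenerate quartile key: all values equal; everything in quartile 1")
        return {f.feature_id: 1 for f in feats}
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    out = {}
    for f in feats:
        v = getattr(f, key)
        out[f.feature_id] = 1 if v <= q25 else 2 if v <= q50 else 3 if v <= q75 else 4
    return out


def relative_expression(
    ct: CtTable,
    targets: Sequence[str],
    references: Sequence[str] | None = None,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample relative expression level = E^(mean ref Ct - mean target Ct).

    Replicate Cts are averaged per (sample, target); the reference Ct is the
    arithmetic mean over the named reference targets.  Missing reference Cts
    for a sample raise an error.
    """
    references = tuple(references) if references else ct.reference_targets
    rows = []
    for sample in ct.samples:
        try:
            ref_ct = float(np.mean([ct.mean_ct(sample, r) for r in references]))
        except KeyError as exc:
            raise ValueError(f"sample {sample!r} lacks a reference Ct") from exc
        for target in targets:
            try:
                tgt_ct = ct.mean_ct(sample, target)
            except KeyError:
                continue
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "delta_ct": ref_ct - tgt_ct,
                    "relative_level": efficiency ** (ref_ct - tgt_ct),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "target", "delta_ct", "relative_level"])


def copy_number(
    ct: CtTable,
    calibrator_sample: str,
    target: str = "EVD",
    reference: str = "ACT2",
    calibrator_copies: float = 2.0,
    efficiency: float = 2.0,
) -> dict[str, float]:
    """Copies per haploid genome from genomic-DNA qPCR against a calibrator.

    delta-Ct(s) = mean Ct(reference, s) - mean Ct(target, s); copies(s) =
    calibrator_copies * E^(delta-Ct(s) - delta-Ct(calibrator)).  The default
    calibrator carries two target copies against a single-copy reference gene.
    """
    if calibrator_sample not in ct.samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")
    d_cal = ct.mean_ct(calibrator_sample, reference) - ct.mean_ct(calibrator_sample, target)
    out = {}
    for sample in ct.samples:
        d = ct.mean_ct(sample, reference) - ct.mean_ct(sample, target)
        out[sample] = calibrator_copies * efficiency ** (d - d_cal)
    return out
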