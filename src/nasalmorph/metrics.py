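"""Registration/averaging quality metrics.

The headline statistic is the multi-image similarity coefficient
``|intersection of all S_i| / |union of all S_i|`` over the deformed scan
images S_i of one slice - the multi-set generalization of the Jaccard index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import AveragingConfig, run_averaging_pipeline
from .io_alignment import PipelineError
from .registration import RPMConfig
from .template import TemplateSlice

__all__ = [
    "SimilarityReport",
    "similarity",
    "jaccard",
    "lambda_sweep",
    "matching_accuracy_proxy",
]


class UndefinedSimilarityError(PipelineError):
    """The union of the mask stack is empty."""


@dataclass
class SimilarityReport:
    per_slice: pd.DataFrame  # columns: lambda, y_mm, similarity, n_scans
    epsilon: float


def similarity(images: list[np.ndarray]) -> float:
    """|AND of all masks| / |OR of all masks|; order-invariant, in [0, 1]."""
    if len(images) < 2:
        raise PipelineError("similarity needs at least two masks")
    masks = [np.asarray(m, dtype=bool) for m in images]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise PipelineError("masks must share one grid")
    inter = masks[0].copy()
    union = masks[0].copy()
    for m in masks[1:]:
        inter &= m
        union |= m
    n_union = int(union.sum())
    if n_union == 0:
        raise UndefinedSimilarityError("empty union: similarity undefined")
    return float(inter.sum()) / n_union


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return similarity([a, b])


def lambda_sweep(
    scans: list,
    template: list[TemplateSlice],
    lambdas,
    averaging: AveragingConfig | None = None,
    rpm: RPMConfig | None = None,
    epsilon: float = 1.0,
) -> SimilarityReport:
    """Run registration + warping at each stiffness value and report the
    per-slice similarity of the deformed images along the AMS-choana axis."""
    averaging = averaging or AveragingConfig()
    base_rpm = rpm or RPMConfig()
    rows = []
    for lam in lambdas:
        cfg = RPMConfig(
            stiffness=float(lam),
            t_init=base_rpm.t_init,
            t_final=base_rpm.t_final,
            anneal_rate=base_rpm.anneal_rate,
            outlier_weight=base_rpm.outlier_weight,
            inner_iterations=base_rpm.inner_iterations,
            sinkhorn_iterations=base_rpm.sinkhorn_iterations,
            lambda_anneal=base_rpm.lambda_anneal,
        )
        geometry = run_averaging_pipeline(scans, template, averaging, cfg)
        for sl in geometry.slices:
            if sl.contributing >= 2:
                sim = similarity([w.mask for w in sl.warped.values()])
            else:
                sim = np.nan
            rows.append(
                {"lambda": float(lam), "y_mm": sl.y_position, "similarity": sim,
                 "n_scans": sl.contributing}
            )
    return SimilarityReport(pd.DataFrame(rows), epsilon)


def matching_accuracy_proxy(
    recovered: np.ndarray, truth: np.ndarray, threshold_mm: float = 1.0
) -> float:
    """Fraction of recovered control points within ``threshold_mm`` of their
    ground-truth positions.

    An automated stand-in for a manual feature-matching assessment, usable
    only where ground truth exists (synthetic data); intended for testing
    and reporting, not as a clinical matching score.
    """
    recovered = np.asarray(recovered, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    if recovered.shape != truth.shape or not len(recovered):
        raise PipelineError("recovered and truth control points must pair up")
    d = np.linalg.norm(recovered - truth, axis=1)
    return float((d <= threshold_mm).mean())


def plot_similarity(report: SimilarityReport, path) -> None:
    """Similarity vs slice position, one curve per lambda."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for lam, grp in report.per_slice.groupby("lambda"):
        ax.plot(grp["y_mm"], grp["similarity"], marker="o", label=f"$\\lambda$={lam:g}")
    ax.set_xlabel("distance posterior to AMS (mm)")
    ax.set_ylabel("similarity coefficient")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
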