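"""Registration-quality metrics, paired tests, and hyperparameter forward
selection.

Registration quality is summarized by the structural similarity index
between selected registered frames and the final template: a perfect
groupwise registration makes every registered frame indistinguishable from
the template.  To avoid within-sequence correlation, only two *distant*
frames per sequence (maximum contraction and rest — systole and diastole in
cardiac terms) enter the SSIM sample.  Samples from competing
configurations are compared with paired one-sided t-tests, with sign tests
alongside to guard against non-normality.

The forward-selection procedure searches the regularization weights
greedily: starting from the all-zero configuration it activates one weight
at a time, keeping an addition only when it significantly improves the
validation SSIM sample, and stops otherwise.  With five candidate weights
and two candidate values each, stage 1 trains 10 networks and stage 2
trains 8 (4 remaining weights x 2 values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .data import CineSequence, DeformationSequence
from .losses import LossConfig
from .trainer import RegistrationResult

__all__ = [
    "ssim",
    "ser",
    "mutual_information",
    "pearson_cc",
    "mean_endpoint_error",
    "sample_ssim",
    "paired_tests",
    "ForwardSelectionReport",
    "forward_select",
]

#: SER returned for numerically identical images (the dB cap).
SER_CAP_DB = 300.0


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity with the standard published constants.

    Gaussian window (sigma = 1.5, 11x11), K1 = 0.01, K2 = 0.03, dynamic
    range 1 (images are expected in [0, 1]); mean over pixels, in [-1, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=1.0,
            K1=0.01,
            K2=0.03,
        )
    )


def ser(ref: np.ndarray, img: np.ndarray) -> float:
    """Signal-to-error ratio in dB: 10 log10(sum ref^2 / sum (ref-img)^2)."""
    ref = np.asarray(ref, dtype=np.float64)
    img = np.asarray(img, dtype=np.float64)
    if ref.shape != img.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {img.shape}")
    err = float(((ref - img) ** 2).sum())
    sig = float((ref**2).sum())
    if err <= 0 or sig <= 0:
        return SER_CAP_DB
    return float(min(10.0 * np.log10(sig / err), SER_CAP_DB))


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Mutual information in bits from a joint histogram over [0, 1]."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=[[0.0, 1.0], [0.0, 1.0]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Global Pearson correlation; 0 (with a warning) for constant images."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant image in correlation; returning 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mean_endpoint_error(
    fields_a: DeformationSequence | np.ndarray,
    fields_b: DeformationSequence | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Mean Euclidean distance between two displacement-field sequences (px)."""
    ua = fields_a.displacements if isinstance(fields_a, DeformationSequence) else np.asarray(fields_a)
    ub = fields_b.displacements if isinstance(fields_b, DeformationSequence) else np.asarray(fields_b)
    if ua.shape != ub.shape:
        raise ValueError("shape mismatch")
    epe = np.linalg.norm(ua - ub, axis=-1)
    if mask is not None:
        epe = epe[:, mask]
    return float(epe.mean())


def sample_ssim(
    result: RegistrationResult, frame_pair: tuple[int, int]
) -> tuple[float, float]:
    """SSIM of the two selected registered frames against the final template."""
    n = result.registered.n_frames
    for idx in frame_pair:
        if not 0 <= idx < n:
            raise IndexError(f"frame index {idx} out of range for N={n}")
    tpl = result.final_template.image
    return (
        ssim(result.registered.frames[frame_pair[0]], tpl),
        ssim(result.registered.frames[frame_pair[1]], tpl),
    )


def paired_tests(sample_a, sample_b) -> tuple[float, float]:
    """One-sided paired t-test and sign-test p-values (alternative: a > b).

    The sign test is the exact binomial test on the signs of the paired
    differences with ties dropped; when every pair is tied it is undefined
    and 1.0 is returned with a warning.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("samples must be equal-length 1D with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # degenerate t statistic: 0/0 for identical samples, +-inf otherwise
        if np.allclose(d.mean(), 0.0):
            t_p = 0.5
        else:
            t_p = 0.0 if d.mean() > 0 else 1.0
    else:
        t_p = float(stats.ttest_rel(a, b, alternative="greater").pvalue)
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    n_eff = pos + neg
    if n_eff == 0:
        warnings.warn("sign test undefined for all-tied samples", stacklevel=2)
        sign_p = 1.0
    else:
        sign_p = float(stats.binomtest(pos, n_eff, alternative="greater").pvalue)
    return t_p, sign_p


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

DEFAULT_GRID: dict[str, list[float]] = {
    "lambda1": [1e-7, 5e-7],
    "lambda2": [1e-7, 5e-7],
    "lambda3": [1e-7, 5e-7],
    "lambda4": [1e-7, 5e-7],
    "lambda_c": [1e-7, 1e-5],
}


@dataclass
class StageRecord:
    stage: int
    candidates: list[dict]  # one entry per trained cell
    selected: str | None
    selected_value: float | None
    n_trained: int


@dataclass
class ForwardSelectionReport:
    selected: dict[str, float]
    stages: list[StageRecord]
    baseline_sample: np.ndarray

    def to_loss_config(self, **kwargs) -> LossConfig:
        return LossConfig(**self.selected, **kwargs)


def forward_select(
    train_fn,
    grid: dict[str, list[float]] | None = None,
    alpha: float = 0.05,
) -> ForwardSelectionReport:
    """Greedy forward selection of regularization weights.

    ``train_fn`` maps a dict of active weights (e.g. ``{"lambda3": 1e-7}``)
    to a 1D array of validation SSIM values; samples from different calls
    must be paired (same validation items in the same order).  Stage 0
    trains the all-zero configuration.  Each subsequent stage tries every
    remaining weight at every candidate value on top of the current
    selection, picks the best value per weight by median paired SSIM
    difference, and activates the weight with the highest median difference
    provided its one-sided paired t-test is significant at ``alpha``; the
    procedure stops when no addition is significantly positive.  Training
    failures are recorded and the cell is skipped.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty with at least one value per weight")

    baseline = np.asarray(train_fn({}), dtype=np.float64)
    current_sample = baseline
    selected: dict[str, float] = {}
    remaining = list(grid)
    stages: list[StageRecord] = []
    stage_no = 0
    while remaining:
        stage_no += 1
        candidates: list[dict] = []
        n_trained = 0
        best_per_param: dict[str, dict] = {}
        for param in remaining:
            for value in grid[param]:
                config = {**selected, param: value}
                try:
                    sample = np.asarray(train_fn(config), dtype=np.float64)
                except Exception as exc:  # noqa: BLE001 - record and move on
                    warnings.warn(
                        f"training failed for {config}: {exc}", stacklevel=2
                    )
                    candidates.append(
                        {"param": param, "value": value, "failed": True}
                    )
                    continue
                n_trained += 1
                diff = sample - current_sample
                t_p, sign_p = paired_tests(sample, current_sample)
                rec = {
                    "param": param,
                    "value": value,
                    "median_diff": float(np.median(diff)),
                    "t_p": t_p,
                    "sign_p": sign_p,
                    "sample": sample,
                    "diffs": diff,
                    "failed": False,
                }
                candidates.append(rec)
                best = best_per_param.get(param)
                if best is None or rec["median_diff"] > best["median_diff"]:
                    best_per_param[param] = rec
        winner = None
        for rec in best_per_param.values():
            if rec["median_diff"] > 0 and rec["t_p"] < alpha:
                if winner is None or rec["median_diff"] > winner["median_diff"]:
                    winner = rec
        stages.append(
            StageRecord(
                stage=stage_no,
                candidates=candidates,
                selected=winner["param"] if winner else None,
                selected_value=winner["value"] if winner else None,
                n_trained=n_trained,
            )
        )
        if winner is None:
            break
        selected[winner["param"]] = winner["value"]
        remaining.remove(winner["param"])
        current_sample = winner["sample"]
    return ForwardSelectionReport(selected, stages, baseline)
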