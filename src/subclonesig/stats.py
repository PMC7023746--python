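"""Burden and profile statistics for control vs experimental subclones.

Quantitative question — did the perturbation add mutations? A bootstrap
of the control burdens draws the expected background burden distribution,
and a label-permutation test supplies the p-value for an excess in the
experimental group (significant at p <= 0.01 by default).

Qualitative question — did it change the spectrum? The signal-to-noise
ratio compares the Euclidean separation of the mean control and
experimental profiles (signal) to the within-group per-channel spread
combined in quadrature (noise). Stability of an extracted signature
across replicate subclones is summarised by pairwise cosine similarity
(stable above 0.9 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .catalog import Catalog, SignatureProfile
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingControlsError,
    SchemeMismatchError,
    UndefinedSimilarityError,
    ZeroBurdenError,
)

P_CUTOFF = 0.01
COSINE_STABILITY_CUTOFF = 0.9


@dataclass
class BurdenTestResult:
    """Outcome of the burden excess test for one condition."""

    observed_burden: float  # mean over experimental subclones
    control_burden: float  # mean over control subclones
    null_quantiles: dict  # bootstrap distribution of control means (reference)
    p_value: float
    significant: bool
    n_boot: int
    seed: int
    alternative: str = "greater"

    def __post_init__(self):
        assert self.p_value >= 1.0 / (self.n_boot + 1)


def burden_test(
    control_burdens: Sequence[int],
    experimental_burdens: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    alternative: str = "greater",
    p_cutoff: float = P_CUTOFF,
) -> BurdenTestResult:
    """Test for excess mutation burden in experimental subclones.

    The expected background distribution is built by bootstrap-resampling
    the control burdens (``n_boot`` resamples with replacement of size
    ``len(control_burdens)``) and is reported through ``null_quantiles``.
    The p-value itself comes from a permutation test: condition labels
    are shuffled ``n_boot`` times and the difference of group means
    recomputed, with the +1 correction so p is never exactly 0. One-sided
    for excess by default (``alternative="greater"``); ``"two-sided"``
    uses the absolute difference.

    Reproducible bit-for-bit given ``(seed, n_boot)``.
    """
    ctrl = np.asarray(control_burdens, dtype=float)
    exp = np.asarray(experimental_burdens, dtype=float)
    if ctrl.size < 2:
        raise MissingControlsError(
            f"burden test needs >= 2 control subclones, got {ctrl.size}"
        )
    if exp.size < 1:
        raise InvalidInputError("burden test needs >= 1 experimental subclone")
    if n_boot < 1000:
        raise InvalidInputError("n_boot must be >= 1000")
    if alternative not in ("greater", "two-sided"):
        raise InvalidInputError(f"unknown alternative {alternative!r}")

    rng = np.random.default_rng(seed)
    # bootstrap reference distribution of the control mean burden
    boot = ctrl[rng.integers(0, ctrl.size, size=(n_boot, ctrl.size))].mean(axis=1)
    qs = (0.005, 0.025, 0.25, 0.5, 0.75, 0.975, 0.995)
    null_quantiles = {q: float(v) for q, v in zip(qs, np.quantile(boot, qs))}

    # permutation p-value for the difference of group means
    pool = np.concatenate([ctrl, exp])
    obs = exp.mean() - ctrl.mean()
    order = np.argsort(rng.random((n_boot, pool.size)), axis=1)
    is_exp = order < exp.size
    perm = (pool[None, :] * is_exp).sum(axis=1) / exp.size - (
        pool[None, :] * ~is_exp
    ).sum(axis=1) / ctrl.size
    if alternative == "two-sided":
        extreme = np.abs(perm) >= abs(obs)
    else:
        extreme = perm >= obs
    p = (1 + int(extreme.sum())) / (n_boot + 1)
    return BurdenTestResult(
        observed_burden=float(exp.mean()),
        control_burden=float(ctrl.mean()),
        null_quantiles=null_quantiles,
        p_value=p,
        significant=p <= p_cutoff,
        n_boot=n_boot,
        seed=seed,
        alternative=alternative,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (for multiple conditions)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class ProfileStats:
    """Per-channel mean and spread of normalized profiles over a sample group."""

    scheme_name: str
    labels: tuple
    mu: np.ndarray
    sigma: np.ndarray
    n_samples: int


def profile_stats(
    catalog: Catalog, sample_ids: Sequence[str], ddof: int = 0
) -> ProfileStats:
    """Mean (mu) and per-channel SD (sigma) of normalized sample profiles.

    Profiles are normalized per sample before aggregation, so subclones
    with different burdens contribute equally. ``ddof=0`` (population SD)
    reads sigma as a descriptive spread over the group; set ``ddof=1``
    for the sample SD.
    """
    if not sample_ids:
        raise InvalidInputError("profile_stats needs at least one sample")
    profiles = []
    for s in sample_ids:
        col = catalog.column(s).astype(float)
        total = col.sum()
        if total == 0:
            raise ZeroBurdenError(f"sample {s!r} has zero burden")
        profiles.append(col / total)
    mat = np.vstack(profiles)
    sigma = mat.std(axis=0, ddof=ddof) if mat.shape[0] > ddof else np.zeros(mat.shape[1])
    return ProfileStats(
        scheme_name=catalog.scheme.name,
        labels=catalog.scheme.labels,
        mu=mat.mean(axis=0),
        sigma=sigma,
        n_samples=len(sample_ids),
    )


@dataclass
class SNRResult:
    signal: float
    noise: float
    snr: float
    infinite: bool = False


def snr(control: ProfileStats, experimental: ProfileStats) -> SNRResult:
    """Signal-to-noise ratio between control and experimental spectra.

    signal = ||mu_Exp - mu_Control||_2 ;
    noise = sqrt(||sigma_Control||_2^2 + ||sigma_Exp||_2^2) (the two
    group spreads combined in quadrature). 0/0 is defined as 0; a
    positive signal over exactly zero noise is flagged infinite.
    """
    if control.labels != experimental.labels:
        raise SchemeMismatchError(
            f"profile stats on different schemes: {control.scheme_name} "
            f"vs {experimental.scheme_name}"
        )
    signal = float(np.linalg.norm(experimental.mu - control.mu))
    noise = float(
        math.sqrt(np.sum(control.sigma**2) + np.sum(experimental.sigma**2))
    )
    if noise > 0:
        return SNRResult(signal, noise, signal / noise)
    if signal == 0:
        return SNRResult(0.0, 0.0, 0.0)
    return SNRResult(signal, 0.0, math.inf, infinite=True)


def cosine_similarity(p: SignatureProfile, q: SignatureProfile) -> float:
    """Cosine of the angle between two profiles; in [0, 1] for non-negative input."""
    if p.scheme.labels != q.scheme.labels:
        raise SchemeMismatchError("profiles on different schemes")
    np_, nq = np.linalg.norm(p.weights), np.linalg.norm(q.weights)
    if np_ == 0 or nq == 0:
        raise UndefinedSimilarityError("cosine similarity with a zero profile")
    return float(np.dot(p.weights, q.weights) / (np_ * nq))


@dataclass
class StabilityReport:
    sample_count: int
    cosine_matrix: np.ndarray
    min_cosine: float
    mean_cosine: float
    stable: bool
    cutoff: float = COSINE_STABILITY_CUTOFF


def stability_report(
    signatures: Sequence[SignatureProfile],
    cutoff: float = COSINE_STABILITY_CUTOFF,
) -> StabilityReport:
    """Pairwise cosine similarity of per-subclone signatures.

    The extracted signature is called stable when the minimum pairwise
    cosine exceeds ``cutoff`` (default 0.9): replicate subclones of one
    parental clone should yield near-identical signatures.
    """
    k = len(signatures)
    if k < 2:
        raise InsufficientDataError("stability needs >= 2 replicate signatures")
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = cosine_similarity(signatures[i], signatures[j])
    off = mat[np.triu_indices(k, 1)]
    return StabilityReport(
        sample_count=k,
        cosine_matrix=mat,
        min_cosine=float(off.min()),
        mean_cosine=float(off.mean()),
        stable=bool(off.min() > cutoff),
        cutoff=cutoff,
    )
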