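"""Bootstrap background subtraction.

The profile of an experimental subclone is modelled as a linear
combination of the background (intrinsic/culture) signature and the
signature generated by the perturbation. The background is estimated
from control subclones — their averaged normalized profile and averaged
burden — and subtracted from the centroid of the experimental subclone
profiles on the *count* scale:

    residual_c = centroid_c - alpha * B_bg * q_c

where ``B_bg`` is the background burden, ``q`` its profile and
``alpha <= 1`` a background scale. Each experimental subclone is
bootstrapped (multinomial redraws of its own counts) and the replicates
averaged across subclones, giving a per-channel 99% confidence interval
for the centroid counts. Channels driven slightly negative by
subtraction are clamped to zero as long as the shortfall is within the
channel's CI half-width; when some channel would fall further below
zero than its CI allows, the background scale is reduced — computed
here in closed form as the largest admissible ``alpha`` rather than by
iteration. The clamped residuals, normalized, are the experiment-
associated signature, and their sum is the burden attributed to the
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .catalog import Catalog, SignatureProfile
from .errors import (
    DegenerateSubtractionError,
    EmptySampleError,
    InvalidInputError,
    MissingControlsError,
    SchemeMismatchError,
)

CI_LEVEL = 0.99
MIN_BACKGROUND_SCALE = 1e-9


@dataclass
class BackgroundModel:
    """Averaged control profile and burden, standing in for intrinsic mutagenesis."""

    profile: SignatureProfile
    burden: float

    def __post_init__(self):
        if self.burden < 0:
            raise InvalidInputError("background burden must be non-negative")

    @property
    def expected_counts(self) -> np.ndarray:
        return self.burden * self.profile.weights


def fit_background(control_catalog: Catalog) -> BackgroundModel:
    """Average the control subclones into a background model.

    Profile = mean of the per-sample normalized profiles (equal weight per
    subclone); burden = mean column sum. Needs at least two controls,
    each with at least one mutation.
    """
    if len(control_catalog.samples) < 2:
        raise MissingControlsError(
            f"background fit needs >= 2 control subclones, got "
            f"{len(control_catalog.samples)}"
        )
    profiles = [
        control_catalog.profile(s).weights for s in control_catalog.samples
    ]
    mean_profile = np.mean(profiles, axis=0)
    mean_profile = mean_profile / mean_profile.sum()
    burden = float(control_catalog.burdens().mean())
    return BackgroundModel(
        SignatureProfile(control_catalog.scheme, mean_profile), burden
    )


def bootstrap_channel_distribution(
    counts: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = CI_LEVEL,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bootstrap one sample's channel counts; return replicates and CI.

    Each replicate redraws the sample's N mutations from the multinomial
    with probabilities equal to the observed profile. Returns
    ``(replicates, ci)`` with ``replicates`` of shape (n_boot, channels)
    and ``ci`` of shape (2, channels) holding the lower/upper percentile
    bounds of the central ``ci_level`` interval.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < 1:
        raise EmptySampleError("cannot bootstrap a sample with zero mutations")
    if n_boot < 1000:
        raise InvalidInputError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, counts / n, size=n_boot)
    tail = (1.0 - ci_level) / 2.0
    ci = np.percentile(reps, [100 * tail, 100 * (1 - tail)], axis=0)
    return reps, ci


@dataclass
class SubtractionResult:
    """Experiment-associated signature after background subtraction."""

    signature: SignatureProfile
    attributed_burden: float
    channel_ci: np.ndarray  # (2, channels): lower/upper 99% bounds of centroid counts
    zeroed_channels: List[str]
    background_scale: float
    n_boot: int
    seed: int
    residuals: Optional[np.ndarray] = None  # pre-clamp residual counts


def subtract_background(
    experimental_catalog: Catalog,
    background: BackgroundModel,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = CI_LEVEL,
) -> SubtractionResult:
    """Subtract the background model from experimental subclone profiles.

    See the module docstring for the model. The returned signature is
    non-negative and sums to 1 (or is empty with zero attributed burden
    when nothing remains above background noise).
    """
    scheme = experimental_catalog.scheme
    if scheme.labels != background.profile.scheme.labels:
        raise SchemeMismatchError("catalog and background use different schemes")
    samples = experimental_catalog.samples
    if not samples:
        raise InvalidInputError("need >= 1 experimental subclone")

    burdens = experimental_catalog.burdens().to_numpy(dtype=float)
    mean_burden = float(burdens.mean())
    profiles = np.vstack(
        [experimental_catalog.profile(s).weights for s in samples]
    )
    centroid_profile = profiles.mean(axis=0)
    centroid = mean_burden * centroid_profile  # expected counts per channel

    # bootstrap each subclone, average replicate profiles across subclones,
    # rescale to the mean burden -> CI of the centroid counts
    rng = np.random.default_rng(seed)
    rep_profiles = np.zeros((n_boot, len(scheme)))
    for s in samples:
        col = experimental_catalog.column(s)
        n = int(col.sum())
        reps = rng.multinomial(n, col / n, size=n_boot)
        rep_profiles += reps / n
    rep_centroids = mean_burden * rep_profiles / len(samples)
    tail = (1.0 - ci_level) / 2.0
    ci = np.percentile(rep_centroids, [100 * tail, 100 * (1 - tail)], axis=0)
    boot_mean = rep_centroids.mean(axis=0)
    w_exp = boot_mean - ci[0]

    # the background is bootstrapped too (multinomial at its averaged burden
    # and profile); its lower-tail half-width combines with the experimental
    # one in quadrature into the per-channel tolerance for negative residuals
    bg_counts = background.expected_counts
    if background.burden > 0:
        n_bg = int(round(background.burden))
        bg_reps = rng.multinomial(n_bg, background.profile.weights, size=n_boot)
        bg_low = np.percentile(bg_reps, 100 * tail, axis=0)
        w_bg = bg_reps.mean(axis=0) - bg_low
    else:
        w_bg = np.zeros(len(scheme))
    halfwidth = np.sqrt(w_exp**2 + w_bg**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        limits = np.where(bg_counts > 0, (centroid + halfwidth) / bg_counts, np.inf)
    alpha = float(min(1.0, limits.min()))
    if background.burden > 0 and alpha < MIN_BACKGROUND_SCALE:
        raise DegenerateSubtractionError(
            "background subtraction degenerate: experimental counts are "
            "indistinguishable from (or below) the background in some channel"
        )

    residuals = centroid - alpha * bg_counts
    zeroed = [scheme.labels[i] for i in np.flatnonzero(residuals < 0)]
    clamped = np.clip(residuals, 0.0, None)
    attributed = float(clamped.sum())
    signature = SignatureProfile.from_counts(scheme, clamped)
    return SubtractionResult(
        signature=signature,
        attributed_burden=attributed,
        channel_ci=ci,
        zeroed_channels=zeroed,
        background_scale=alpha,
        n_boot=n_boot,
        seed=seed,
        residuals=residuals,
    )
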