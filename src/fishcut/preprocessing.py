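"""Raw-frame cleaning: threshold segmentation and Kalman + median filtering.

Segmentation removes the conveyor-belt points from each laser frame by
scanning the absolute height differences of adjacent points: the fish region
is the maximal contiguous run bounded by the first and last adjacent-pair
jump exceeding a threshold ``T``.  The retained fish profile is then
denoised with a scalar constant-position (random-walk) Kalman filter
followed by a short asymmetric sliding-window median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PointCloud, RadialProfile
from .errors import EmptyResultError, InvalidArgumentError

__all__ = [
    "FilterConfig",
    "SegmentationResult",
    "DEFAULT_THRESHOLD_MM",
    "threshold_segment",
    "kalman_filter",
    "kalman_gains",
    "kalman_steady_state",
    "median_filter",
    "preprocess_cloud",
]

# Segmentation threshold, mm.  The body-edge jump of a fish lying on the
# belt is tens of mm while belt noise stays well below 1 mm, so 5 mm
# separates the two with a wide margin.
DEFAULT_THRESHOLD_MM = 5.0


@dataclass(frozen=True)
class FilterConfig:
    """Denoising parameters.

    The Kalman covariances parameterize a scalar random-walk model:
    ``kalman_process_cov`` (mm^2) is the system-noise covariance,
    ``kalman_measurement_cov`` the measurement-noise covariance and
    ``kalman_initial_cov`` the initial state covariance.  The median window
    covers index offsets ``[-median_window_left, +median_window_right]``
    around each point (shrinking at the edges).
    """

    kalman_process_cov: float = 1e-4
    kalman_measurement_cov: float = 0.1
    kalman_initial_cov: float = 1.0
    median_window_left: int = 2
    median_window_right: int = 1
    min_fish_points: int = 5

    def __post_init__(self) -> None:
        for name in ("kalman_process_cov", "kalman_measurement_cov",
                     "kalman_initial_cov"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.median_window_left < 0 or self.median_window_right < 0:
            raise InvalidArgumentError("median window extents must be >= 0")
        if self.median_window_left + self.median_window_right + 1 < 1:
            raise InvalidArgumentError("median window must cover >= 1 point")
        if self.min_fish_points < 1:
            raise InvalidArgumentError("min_fish_points must be >= 1")


@dataclass
class SegmentationResult:
    """Partition of one frame into left belt (M1), fish (M2), right belt (M3).

    ``fish_start``/``fish_stop`` are half-open indices of the fish run into
    the original frame; the three pieces are disjoint, contiguous, ordered
    left to right, and concatenate back to the input frame.
    """

    frame: RadialProfile
    fish_start: int
    fish_stop: int
    threshold_used: float

    @property
    def fish(self) -> RadialProfile:
        s = slice(self.fish_start, self.fish_stop)
        return RadialProfile(self.frame.x, self.frame.y[s], self.frame.z[s])

    @property
    def left_belt(self) -> RadialProfile:
        s = slice(0, self.fish_start)
        return RadialProfile(self.frame.x, self.frame.y[s], self.frame.z[s])

    @property
    def right_belt(self) -> RadialProfile:
        s = slice(self.fish_stop, self.frame.n_points)
        return RadialProfile(self.frame.x, self.frame.y[s], self.frame.z[s])

    @property
    def fish_empty(self) -> bool:
        return self.fish_stop <= self.fish_start

    def belt_heights(self) -> np.ndarray:
        return np.concatenate(
            [self.frame.z[: self.fish_start], self.frame.z[self.fish_stop :]]
        )


def threshold_segment(frame: RadialProfile, T: float = DEFAULT_THRESHOLD_MM) -> SegmentationResult:
    """Split a frame into belt / fish / belt by adjacent height jumps > ``T``.

    The fish run starts right after the first adjacent pair whose absolute
    height difference exceeds ``T`` and ends at the last such pair.  If no
    jump exceeds ``T`` (or only one does), the fish region is empty and the
    whole frame is belt.
    """
    if T <= 0:
        raise InvalidArgumentError("threshold T must be > 0")
    if frame.n_points < 1:
        raise InvalidArgumentError("frame must contain at least one point")
    jumps = np.flatnonzero(np.abs(np.diff(frame.z)) > T)
    if jumps.size == 0:
        return SegmentationResult(frame, 0, 0, T)
    start = int(jumps[0]) + 1
    stop = int(jumps[-1]) + 1
    if stop <= start:  # a single jump cannot bound a fish run
        return SegmentationResult(frame, 0, 0, T)
    return SegmentationResult(frame, start, stop, T)


def kalman_gains(n: int, config: FilterConfig) -> np.ndarray:
    """Kalman gain sequence K_1..K_n of the scalar random-walk recursion.

    The gain depends only on the covariance recursion (not the data):
    predict ``P <- P + q``; update ``K = P / (P + r)``, ``P <- (1 - K) P``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    q = config.kalman_process_cov
    r = config.kalman_measurement_cov
    P = config.kalman_initial_cov
    gains = np.empty(n)
    for t in range(n):
        P = P + q
        K = P / (P + r)
        P = (1.0 - K) * P
        gains[t] = K
    return gains


def kalman_steady_state(config: FilterConfig) -> tuple[float, float]:
    """Closed-form steady state ``(P_inf, K_inf)`` of the gain recursion.

    The predicted covariance fixed point solves ``Pp**2 = q*Pp + q*r``;
    ``K_inf = Pp / (Pp + r)`` and the post-update covariance is
    ``P_inf = (1 - K_inf) * Pp``.
    """
    q = config.kalman_process_cov
    r = config.kalman_measurement_cov
    pp = 0.5 * (q + np.sqrt(q * q + 4.0 * q * r))
    k = pp / (pp + r)
    return float((1.0 - k) * pp), float(k)


def kalman_filter(z: np.ndarray, config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Scalar constant-position Kalman smoothing along a height vector.

    The state is initialized at ``z[0]`` with covariance
    ``kalman_initial_cov``; each later sample is fused with gain from
    :func:`kalman_gains`.  Accepts a 2-D array to filter many equal-length
    vectors at once (recursion along the last axis).
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise InvalidArgumentError("kalman_filter: empty input")
    squeeze = z.ndim == 1
    Z = np.atleast_2d(z)
    n = Z.shape[1]
    out = np.empty_like(Z)
    out[:, 0] = Z[:, 0]
    if n > 1:
        gains = kalman_gains(n - 1, config)
        x = Z[:, 0].copy()
        for t in range(1, n):
            K = gains[t - 1]
            x = x + K * (Z[:, t] - x)
            out[:, t] = x
    return out[0] if squeeze else out


def median_filter(z: np.ndarray, config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Sliding-window median over offsets [-left, +right], edges truncated.

    Window extents come from ``median_window_left``/``median_window_right``;
    at the vector edges the window shrinks to the valid indices rather than
    padding, so no data is invented at fish boundaries.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise InvalidArgumentError("median_filter: empty input")
    left = config.median_window_left
    right = config.median_window_right
    if left == 0 and right == 0:
        return z.copy()
    padded = np.concatenate([np.full(left, np.nan), z, np.full(right, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, left + right + 1)
    return np.nanmedian(windows, axis=1)


def preprocess_cloud(
    cloud: PointCloud,
    T: float = DEFAULT_THRESHOLD_MM,
    config: FilterConfig = FilterConfig(),
) -> PointCloud:
    """Segment and denoise every frame of a cloud; drop belt-only frames.

    Per frame: threshold segmentation, keep the fish run, Kalman filter then
    median filter (in that order).  The belt level of each frame is
    estimated as the median height of its flanking belt points and stored on
    the output profile.

    Impulse outliers on the belt can fake an edge jump and stretch the
    segmented run far beyond the fish, so before filtering each raw run is
    refined to the contiguous region exceeding the belt level by more than
    ``T`` around the run maximum — a genuine cross-section sits well above
    the belt at every point, an impulse does not.  Runs that are empty,
    narrower than ``min_fish_points``, or whose maximum never clears the
    belt by more than ``T`` are discarded.
    """
    if cloud.n_frames == 0:
        raise InvalidArgumentError("preprocess_cloud: empty cloud")

    runs: list[tuple[float, np.ndarray, np.ndarray, float]] = []
    n_candidates = 0
    for frame in cloud:
        seg = threshold_segment(frame, T)
        if seg.fish_empty:
            continue
        n_candidates += 1
        y = frame.y[seg.fish_start : seg.fish_stop]
        z = frame.z[seg.fish_start : seg.fish_stop]
        belt = seg.belt_heights()
        belt_level = float(np.median(belt)) if belt.size else (
            cloud.belt_height if cloud.belt_height is not None else float("nan")
        )
        if not np.isnan(belt_level):
            above = z > belt_level + T
            peak = int(np.argmax(z))
            if not above[peak]:
                continue  # spurious run: nothing clears the belt by > T
            lo = peak
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = peak + 1
            while hi < z.size and above[hi]:
                hi += 1
            y, z = y[lo:hi], z[lo:hi]
        if z.size < config.min_fish_points:
            continue
        runs.append((frame.x, y, z, belt_level))

    if not runs:
        raise EmptyResultError(
            f"no usable fish run in {cloud.n_frames} frames "
            f"({n_candidates} candidate runs, T={T} mm)"
        )

    # Kalman-filter all fish runs in one batch (the gain sequence is shared);
    # shorter runs are padded by repeating their last value and trimmed
    # afterwards — the recursion is causal, so padding cannot affect the
    # retained samples.
    lengths = [z.size for _, _, z, _ in runs]
    lmax = max(lengths)
    Z = np.empty((len(runs), lmax))
    for i, (_, _, z, _) in enumerate(runs):
        Z[i, : z.size] = z
        if z.size < lmax:
            Z[i, z.size :] = z[-1]
    filtered = kalman_filter(Z, config)

    frames_out: list[RadialProfile] = []
    belt_levels: list[float] = []
    for i, (x, y, _, belt_level) in enumerate(runs):
        zf = median_filter(filtered[i, : lengths[i]], config)
        frames_out.append(
            RadialProfile(
                x=x,
                y=y,
                z=zf,
                belt_level=None if np.isnan(belt_level) else belt_level,
            )
        )
        if not np.isnan(belt_level):
            belt_levels.append(belt_level)

    if not frames_out:
        raise EmptyResultError(
            f"no frame survived preprocessing ({len(segs)} candidate runs, T={T} mm)"
        )
    belt_height = cloud.belt_height
    if belt_height is None and belt_levels:
        belt_height = float(np.median(belt_levels))
    return PointCloud(
        frames_out,
        frame_spacing=cloud.frame_spacing,
        belt_height=belt_height,
        metadata=dict(cloud.metadata),
    )
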