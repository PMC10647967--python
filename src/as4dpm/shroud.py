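"""Amsterdam Shroud image construction and diaphragm waveform extraction.

Each projection frame is log-transformed, differentiated along the vertical
(cranial-caudal) axis and collapsed to a single column by averaging across
detector columns; concatenating the columns over time yields the shroud
image, in which diaphragm motion appears as a sinuous ridge.  Dual-imager
shrouds are superimposed after SI registration, the image is trimmed to the
band containing the ridge, locally normalized, and the respiratory waveform
is taken as the first principal-component score of the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure
from sklearn.decomposition import PCA

from .core import Waveform
from .simulate import ProjectionStack

__all__ = [
    "ASImage",
    "ASWaveform",
    "make_as_image",
    "superimpose_as",
    "trim_as",
    "local_normalize",
    "extract_as_waveform",
    "shroud_waveform",
]


@dataclass(frozen=True)
class ASImage:
    """Shroud image: rows = SI pixel positions, columns = frames."""

    matrix: np.ndarray  # (rows, n_frames)
    row_pitch_mm: float
    frame_times: np.ndarray  # s
    provenance: str = "single"  # "single" | "dual"
    row_offset: int = 0  # original index of the first retained row

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("shroud matrix must be 2-D (rows x frames)")
        if not np.all(np.isfinite(m)):
            raise ValueError("shroud matrix must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ASWaveform:
    """Respiratory waveform extracted from a shroud image.

    Samples are in arbitrary units; ``sign_convention`` +1 means larger
    values correspond to inferior diaphragm displacement.
    """

    samples: np.ndarray
    frame_times: np.ndarray
    sign_convention: int = 1

    def as_waveform(self) -> Waveform:
        dt = float(np.median(np.diff(self.frame_times)))
        return Waveform(self.samples, dt=dt, t0=float(self.frame_times[0]))

    def __len__(self) -> int:
        return len(self.samples)


def make_as_image(
    stack: ProjectionStack, *, log_offset: float | None = None
) -> ASImage:
    """Collapse a projection stack into a shroud image.

    Per frame: log transform, vertical derivative (central differences,
    one-sided at the first/last rows), then the mean across detector columns
    forms one shroud column.  Pixel values must be strictly positive unless a
    ``log_offset`` is supplied.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if log_offset is not None:
        frames = frames + log_offset
    if frames.min() <= 0:
        raise ValueError(
            "projection frames contain non-positive pixels; pass log_offset "
            "to shift them before the log transform"
        )
    # The vertical derivative commutes with the across-column mean, so
    # collapse the log image to one column per frame before differentiating.
    log_profile = np.log(frames).mean(axis=2)  # (n_frames, rows)
    columns = np.gradient(log_profile, axis=1)
    return ASImage(
        matrix=columns.T,
        row_pitch_mm=stack.pixel_size_mm,
        frame_times=np.asarray(stack.times, dtype=float),
        provenance="single",
    )


def _registration_shift(p1: np.ndarray, p2: np.ndarray, max_shift: int) -> int:
    """Integer row shift of profile p2 maximizing correlation with p1."""
    best_s, best_r = 0, -np.inf
    n = len(p1)
    for s in range(-max_shift, max_shift + 1):
        # aligned2[r] = p2[r - s]; overlap rows r in [max(0, s), n + min(0, s))
        lo, hi = max(0, s), n + min(0, s)
        if hi - lo < 3:
            continue
        a = p1[lo:hi]
        b = p2[lo - s : hi - s]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r + 1e-12 or (abs(r - best_r) <= 1e-12 and abs(s) < abs(best_s)):
            best_r, best_s = r, s
    return best_s


def superimpose_as(as1: ASImage, as2: ASImage, *, max_shift: int | None = None) -> ASImage:
    """Register the second shroud to the first in SI and average them.

    Registration uses the integer row shift that maximizes the correlation of
    the two time-averaged row profiles.  Rows without overlap keep the first
    image's values, so superimposing an image with a shifted copy of itself
    reproduces the original in the overlap.
    """
    if as1.matrix.shape != as2.matrix.shape:
        raise ValueError("shroud images must have identical shapes")
    if as1.row_pitch_mm != as2.row_pitch_mm:
        raise ValueError("shroud images must share the row pitch")
    n_rows = as1.n_rows
    if max_shift is None:
        max_shift = n_rows // 2
    p1 = as1.matrix.mean(axis=1)
    p2 = as2.matrix.mean(axis=1)
    s = _registration_shift(p1, p2, max_shift)
    out = as1.matrix.copy()
    lo, hi = max(0, s), n_rows + min(0, s)
    out[lo:hi] = 0.5 * (as1.matrix[lo:hi] + as2.matrix[lo - s : hi - s])
    return replace(as1, matrix=out, provenance="dual")


def _variance_profile(as_img: ASImage) -> np.ndarray:
    return as_img.matrix.var(axis=1)


def trim_as(
    as_img: ASImage,
    band: tuple[int, int] | str = "auto",
    *,
    margin: int = 25,
    support_fraction: float = 0.05,
    support_pad: int = 10,
) -> ASImage:
    """Retain only the row band containing the breathing ridge.

    ``band`` may be an explicit ``(first, last_exclusive)`` row range,
    ``"auto"`` (row of maximum temporal variance ± ``margin``), or
    ``"support"`` (all rows whose temporal variance exceeds
    ``support_fraction`` of the maximum, padded by ``support_pad`` — wide
    enough to cover the full breathing excursion).
    """
    n_rows = as_img.n_rows
    if band == "auto":
        center = int(np.argmax(_variance_profile(as_img)))
        lo, hi = center - margin, center + margin + 1
    elif band == "support":
        var = _variance_profile(as_img)
        rows = np.flatnonzero(var >= support_fraction * var.max())
        lo, hi = int(rows[0]) - support_pad, int(rows[-1]) + support_pad + 1
    else:
        lo, hi = band
    lo, hi = max(0, lo), min(n_rows, hi)
    if hi <= lo:
        raise ValueError("empty trim band")
    return replace(
        as_img,
        matrix=as_img.matrix[lo:hi],
        row_offset=as_img.row_offset + lo,
    )


def local_normalize(
    as_img: ASImage,
    window: int | None = None,
    *,
    mode: str = "mean",
    tile_rows: int | None = None,
    clip_limit: float = 0.01,
) -> ASImage:
    """Local-mean subtraction followed by clip-limited local equalization.

    Subtracts the local-mean map (a ``window x window`` moving average; a
    moving-minimum map via ``mode="min"``), then applies tile-based adaptive
    histogram equalization so the local average and variance of pixel values
    are approximately uniform across the image.  The default tile height is
    an eighth of the trimmed image height.

    The default window is the largest odd size not exceeding ~2/3 of the
    trimmed image height: wide enough not to flatten the breathing ridge,
    local enough to level slow illumination trends.  The clip limit is kept
    moderate: aggressive equalization makes the intensity map strongly
    nonlinear in the ridge position, which degrades the principal-component
    waveform downstream.
    """
    if window is None:
        window = max(3, min(min(as_img.matrix.shape), int(0.65 * as_img.n_rows)))
        if window % 2 == 0:
            window -= 1
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(as_img.matrix.shape):
        raise ValueError("window larger than the image")
    if mode == "mean":
        lm = ndimage.uniform_filter(as_img.matrix, size=window, mode="nearest")
    elif mode == "min":
        lm = ndimage.minimum_filter(as_img.matrix, size=window, mode="nearest")
    else:
        raise ValueError("mode must be 'mean' or 'min'")
    residual = as_img.matrix - lm
    span = residual.max() - residual.min()
    if span == 0:
        return replace(as_img, matrix=np.zeros_like(residual))
    scaled = (residual - residual.min()) / span
    if tile_rows is None:
        tile_rows = max(3, as_img.n_rows // 8)
    tile_cols = max(3, min(as_img.n_frames, tile_rows))
    eq = exposure.equalize_adapthist(
        scaled, kernel_size=(tile_rows, tile_cols), clip_limit=clip_limit
    )
    return replace(as_img, matrix=eq)


def _centroid_reference(matrix: np.ndarray, *, polarity: str = "auto") -> np.ndarray:
    """Intensity-weighted centroid row per column: the ridge-row trace.

    On a raw shroud image the diaphragm ridge is the *negative* lobe of the
    vertical log-intensity gradient (lung above is brighter than abdomen
    below), so ``polarity="negative"`` weights by the clipped negative part.
    ``polarity="auto"`` picks the lobe holding more squared mass, which also
    works on normalized images whose polarity is arbitrary.
    """
    if polarity == "negative":
        w = np.clip(-matrix, 0.0, None) ** 2
    elif polarity == "auto":
        neg = np.clip(-(matrix - matrix.mean()), 0.0, None) ** 2
        pos = np.clip(matrix - matrix.mean(), 0.0, None) ** 2
        w = neg if neg.sum() >= pos.sum() else pos
    else:
        raise ValueError("polarity must be 'negative' or 'auto'")
    rows = np.arange(matrix.shape[0], dtype=float)[:, None]
    total = w.sum(axis=0)
    total[total == 0] = 1.0
    return (rows * w).sum(axis=0) / total


def extract_as_waveform(
    as_norm: ASImage, reference: np.ndarray | Waveform | None = None
) -> ASWaveform:
    """First principal-component score per frame of the shroud columns.

    Columns are the observations, rows the features.  The PCA sign is
    arbitrary, so it is fixed to correlate positively with ``reference``
    (default: the intensity-weighted centroid row trace, which increases
    with inferior diaphragm displacement).
    """
    if as_norm.n_frames < 2:
        raise ValueError("need at least two frames")
    X = as_norm.matrix.T  # (n_frames, rows): observations x features
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("zero-variance shroud image; no waveform present")
    scores = PCA(n_components=1, svd_solver="full").fit_transform(X).ravel()
    if reference is None:
        ref = _centroid_reference(as_norm.matrix)
    elif isinstance(reference, Waveform):
        ref = reference.values
    else:
        ref = np.asarray(reference, dtype=float)
    if len(ref) != len(scores):
        raise ValueError("reference length must match the frame count")
    if ref.std() > 0 and scores.std() > 0:
        r = np.corrcoef(scores, ref)[0, 1]
        if r < 0:
            scores = -scores
    return ASWaveform(
        samples=scores,
        frame_times=as_norm.frame_times,
        sign_convention=1,
    )


def shroud_waveform(
    stacks: list[ProjectionStack] | ProjectionStack,
    *,
    band: tuple[int, int] | str = "support",
    window: int | None = None,
    mode: str = "mean",
    log_offset: float | None = None,
) -> ASWaveform:
    """Full shroud pipeline: build, superimpose (dual), trim, normalize, PCA.

    The PCA sign reference is the centroid trace of the trimmed image before
    normalization, which is more robust to equalization artifacts than the
    normalized image's own centroid.
    """
    if isinstance(stacks, ProjectionStack):
        stacks = [stacks]
    if not 1 <= len(stacks) <= 2:
        raise ValueError("expected one or two projection stacks")
    images = [make_as_image(s, log_offset=log_offset) for s in stacks]
    img = images[0] if len(images) == 1 else superimpose_as(*images)
    img = trim_as(img, band)
    reference = _centroid_reference(img.matrix, polarity="negative")
    img = local_normalize(img, window=window, mode=mode)
    return extract_as_waveform(img, reference=reference)
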