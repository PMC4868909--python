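"""Per-pixel stereo disparity estimation with a bank of trained disparity cells.

For every pixel of a rectified pair, a patch of the left image and the
patch of the right image at the same rows are spliced side by side into
one binocular window — the spliced window is what layer-4 ocular
dominance columns present to a downstream disparity cell.  Each cell of
a trained bank (one cell per disparity) responds to the binarized
window; the disparity of the most responsive cell is the pixel's
disparity estimate.

Because detection is template matching, the window handed to the bank
must be registered the way the training patterns were: by default the
window is anchored on the nearest texture landmark (the leading edge of
a bar) at or left of the pixel, which makes every interior window of a
bar-textured surface identical to the training pattern of its true
disparity.  A ``center`` alignment (window centred on the pixel) is
also available.

Optional prefilters mirror the two remedies for noisy input: Gaussian
smoothing of both images, and an edge-detector (gradient magnitude)
front end.  With the edge prefilter the bank must be trained on
edge-style patterns (see ``synth.make_disparity_pattern``), since the
landmark the cells see is then a bar's pair of flanks, not the bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cell import DisparityCellState, cell_response
from .synth import DisparityPattern, StereoPair

__all__ = [
    "PipelineConfig",
    "DisparityMap",
    "extract_and_splice",
    "splice_at",
    "gaussian_prefilter",
    "edge_prefilter",
    "binarize",
    "detect_disparity",
    "anchor_columns",
    "matched_pattern_set",
    "disparity_map",
    "average_error",
    "interior_mask",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Patch geometry, prefilters and window alignment for the map stage.

    ``h`` x ``w_l`` patches are taken from the left image, ``h`` x
    ``w_r`` from the right, giving spliced windows of width w_l + w_r
    (9x4 | 9x5 for the 4-disparity bank; 10x20 | 10x20 for 20
    disparities).  ``sigma`` is the Gaussian prefilter width in pixels
    (0 disables); ``edges`` switches the gradient-magnitude front end
    on.  ``align`` is ``"edge"`` (anchor windows on texture landmarks)
    or ``"center"``.  ``min_gap`` is the number of clear columns that
    must precede a landmark for it to count as a leading edge.
    """

    h: int = 9
    w_l: int = 4
    w_r: int = 5
    sigma: float = 0.0
    edges: bool = False
    align: str = "edge"
    min_gap: int = 3

    def __post_init__(self) -> None:
        if self.h < 1 or self.w_l < 1 or self.w_r < 1:
            raise ValueError("patch geometry must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.align not in ("edge", "center"):
            raise ValueError("align must be 'edge' or 'center'")


@dataclass
class DisparityMap:
    """Per-pixel integer disparity estimates with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must share one shape")


def splice_at(pair: StereoPair, row0: int, col0: int, h: int, w_l: int, w_r: int):
    """Spliced window whose patches start at (row0, col0) in both images.

    Both patches come from the same epipolar rows.  Patches reaching
    outside the images are replicate-padded and the window is flagged
    invalid.  Returns ``(window, valid)``.
    """
    height, width = pair.left.shape
    valid = (
        0 <= row0
        and row0 + h <= height
        and 0 <= col0
        and col0 + max(w_l, w_r) <= width
    )
    rows = np.clip(np.arange(row0, row0 + h), 0, height - 1)
    cols_l = np.clip(np.arange(col0, col0 + w_l), 0, width - 1)
    cols_r = np.clip(np.arange(col0, col0 + w_r), 0, width - 1)
    window = np.hstack(
        [pair.left[np.ix_(rows, cols_l)], pair.right[np.ix_(rows, cols_r)]]
    )
    return window, valid


def extract_and_splice(
    pair: StereoPair, pixel: tuple[int, int], h: int, w_l: int, w_r: int
):
    """Window for a pixel under the centred convention.

    The left patch's top-left corner sits at
    ``(row - h//2, col - w_l//2)``; the right patch shares rows and the
    starting column.  Returns ``(window, valid)``; border pixels get a
    replicate-padded window with ``valid=False``.
    """
    r, c = pixel
    return splice_at(pair, r - h // 2, c - w_l // 2, h, w_l, w_r)


def gaussian_prefilter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing with reflective boundaries (identity at 0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


def edge_prefilter(image: np.ndarray) -> np.ndarray:
    """Gradient-magnitude (Sobel) edge map, normalised to peak 1.

    A constant image maps to all zeros.
    """
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def binarize(image: np.ndarray, threshold: float | None = None, method: str = "median") -> np.ndarray:
    """Binary version of a grayscale patch or image.

    ``median`` thresholds strictly above the median — parameter-free and
    contrast-invariant, right for small windows whose foreground covers
    less than half the area.  ``midrange`` thresholds at the midpoint of
    the robust (1st/99th percentile) intensity range — right for whole
    images of sparse texture, where the median sits inside the
    background and would turn background noise ON.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        if method == "median":
            t = float(np.median(img))
        elif method == "midrange":
            lo, hi = np.percentile(img, [1, 99])
            t = 0.5 * (lo + hi)
        else:
            raise ValueError(f"unknown binarization method {method!r}")
    else:
        t = threshold
    return img > t


def detect_disparity(window: np.ndarray, bank: list[DisparityCellState]):
    """Winner-cell disparity of one spliced window.

    The window is binarized at its median and shown to every cell; the
    disparity of the cell with the highest response wins.  An exact tie
    is resolved to the lowest disparity and reported (``valid=False``).
    Returns ``(disparity, responses, valid)``.
    """
    if not bank:
        raise ValueError("empty cell bank")
    for c in bank:
        if c.learned_disparity is None:
            raise ValueError("bank contains an untrained (ambiguous) cell")
    bits = binarize(window)
    w_l = bank[0].rf.w_l
    probe = DisparityPattern(bits=bits, disparity=-1, w_l=w_l)
    responses = np.array([cell_response(c, probe) for c in bank])
    top = np.flatnonzero(responses == responses.max())
    winner = int(bank[top[0]].learned_disparity)
    return winner, responses, top.size == 1


def anchor_columns(image: np.ndarray, h: int, min_gap: int = 3) -> np.ndarray:
    """Per-pixel landmark column for edge-aligned window extraction.

    The reference (left) image's texture landmarks are vertical bars
    crossing every epipolar row, so the profile is the full column mean
    — averaging over all rows makes the landmark set essentially immune
    to pixel noise.  A column is a landmark when the profile has a local
    maximum there (the crest of a bar, a location that survives
    smoothing unmoved) dominating its ``min_gap`` neighbourhood and
    rising above the midpoint of the profile's robust intensity range.
    Each pixel is assigned the nearest landmark at or left of it
    (falling back to the nearest one on the right); -1 if the image has
    no landmark at all.  ``h`` is kept for geometry context but the
    profile is global.
    """
    img = np.asarray(image, dtype=float)
    height, width = img.shape
    prof = np.tile(img.mean(axis=0), (height, 1))
    lo, hi = np.percentile(prof, [5, 95])
    thresh = 0.5 * (lo + hi)
    local_max = prof >= ndimage.maximum_filter1d(prof, 2 * min_gap + 1, axis=1)
    lead = local_max & (prof > thresh)
    for k in range(1, min_gap + 1):  # exact ties: keep the leftmost landmark
        shifted = np.zeros_like(lead)
        shifted[:, k:] = lead[:, :-k]
        lead &= ~shifted
    cols = np.arange(width)
    anchored = np.where(lead, cols, -1)
    last = np.maximum.accumulate(anchored, axis=1)  # nearest landmark <= c
    nxt = np.where(lead, cols, width)
    nxt = np.minimum.accumulate(nxt[:, ::-1], axis=1)[:, ::-1]  # nearest >= c
    return np.where(last >= 0, last, np.where(nxt < width, nxt, -1))


def ridge_sharpen(image: np.ndarray, h: int, min_gap: int = 3) -> np.ndarray:
    """Column-wise non-maximum suppression of a smoothed (or edge) image.

    Smoothing stabilises a bar's location but smears its profile, so the
    smoothed image is reduced back to its ridges: a pixel survives when
    its column is a local maximum of the h-row vertical mean dominating
    the ``min_gap`` neighbourhood and above the midpoint of the
    profile's robust range.  The result is near-binary, so the window
    binarization sees the same crisp landmarks a clean unfiltered bar
    texture provides — only the ridge *position* matters, which is what
    smoothing makes noise-stable.
    """
    img = np.asarray(image, dtype=float)
    prof = ndimage.uniform_filter1d(img, size=h, axis=0, mode="nearest")
    lo, hi = np.percentile(prof, [5, 95])
    thresh = 0.5 * (lo + hi)
    peak = prof >= ndimage.maximum_filter1d(prof, 2 * min_gap + 1, axis=1)
    mask = peak & (prof > thresh)
    for k in range(1, min_gap + 1):  # exact ties: keep the leftmost ridge
        shifted = np.zeros_like(mask)
        shifted[:, k:] = mask[:, :-k]
        mask &= ~shifted
    return np.where(mask, 1.0, 0.0)


def _apply_prefilters(pair: StereoPair, config: PipelineConfig) -> StereoPair:
    left, right = pair.left, pair.right
    if config.sigma > 0:
        left = gaussian_prefilter(left, config.sigma)
        right = gaussian_prefilter(right, config.sigma)
    if config.edges:
        # derivative-of-Gaussian ordering: smooth first, then
        # differentiate, so the edge map is not a noise amplifier; the
        # second smoothing merges a bar's two gradient flanks into one
        # stable ridge centred on the bar
        post = max(1.5, 1.5 * config.sigma)
        left = gaussian_prefilter(edge_prefilter(left), post)
        right = gaussian_prefilter(edge_prefilter(right), post)
    if config.edges or config.sigma > 0:
        left = ridge_sharpen(left, config.h, config.min_gap)
        right = ridge_sharpen(right, config.h, config.min_gap)
    return StereoPair(
        left=left, right=right, ground_truth=pair.ground_truth, occlusion=pair.occlusion
    )


def matched_pattern_set(
    config: PipelineConfig,
    n_disparities: int,
    bar_period: int = 8,
    background: float = 0.2,
    foreground: float = 1.0,
):
    """Training patterns matched to a pipeline configuration.

    Detection is template matching, so the bank must be trained on
    patterns that look the way real windows look *after* the configured
    prefilters.  For each disparity a clean single-region reference pair
    with the default bar texture is generated, passed through the
    pipeline's filters and window extraction, and the binarized interior
    window becomes the training pattern (complements included).  With no
    prefilters this reproduces the plain single-bar pattern.
    """
    from .synth import make_stereo_pair  # local import to avoid cycle at load

    h, w_l, w_r = config.h, config.w_l, config.w_r
    if n_disparities > min(w_l, w_r):
        raise ValueError("more disparities than the window geometry can encode")
    height = 3 * h
    width = bar_period * 4 + w_r + n_disparities
    patterns = []
    for d in range(n_disparities):
        pair = make_stereo_pair(
            height,
            width,
            [(0, height, 0, width, d)],
            texture="bars",
            seed=0,
            bar_period=bar_period,
            background=background,
            foreground=foreground,
        )
        f = _apply_prefilters(pair, config)
        anchors = anchor_columns(f.left, h, config.min_gap)
        r, c = height // 2, 2 * bar_period  # interior pixel past the first bar
        a = int(anchors[r, c])
        if a < 0:
            raise RuntimeError("reference texture produced no landmark")
        window, ok = splice_at(f, r - h // 2, a, h, w_l, w_r)
        if not ok:
            raise RuntimeError("reference window fell outside the reference image")
        patterns.append(
            DisparityPattern(bits=binarize(window), disparity=d, w_l=w_l)
        )
    out = patterns + [p.complement() for p in patterns]
    if len({p.bits.tobytes() for p in out}) != len(out):
        raise RuntimeError(
            "prefilter-matched patterns are not pairwise distinct for this geometry"
        )
    return out


def disparity_map(
    pair: StereoPair,
    bank: list[DisparityCellState],
    config: PipelineConfig = PipelineConfig(),
) -> DisparityMap:
    """Per-pixel disparity over a stereo pair, deterministic given inputs.

    Both images pass the configured prefilters; windows are extracted at
    each pixel (edge-anchored or centred per config), binarized and
    judged by the bank.  Pixels whose window is padded, tied, or — in
    edge alignment — has no landmark are flagged invalid (their value is
    still the winner's disparity, or 0 where no window exists).
    """
    height, width = pair.left.shape
    h, w_l, w_r = config.h, config.w_l, config.w_r
    if h > height or max(w_l, w_r) > width:
        raise ValueError("patch geometry exceeds image size")
    filtered = _apply_prefilters(pair, config)
    left = filtered.left

    values = np.zeros((height, width), dtype=int)
    valid = np.zeros((height, width), dtype=bool)

    if config.align == "edge":
        anchors = anchor_columns(left, h, config.min_gap)
        for r in range(height):
            row0 = r - h // 2  # band centred on the pixel row, like the profile
            cache: dict[int, tuple[int, bool]] = {}
            for c in range(width):
                a = anchors[r, c]
                if a < 0:
                    continue  # no landmark in this band: invalid, value 0
                if a not in cache:
                    window, ok = splice_at(filtered, row0, int(a), h, w_l, w_r)
                    d, _, unique = detect_disparity(window, bank)
                    cache[a] = (d, ok and unique)
                values[r, c], valid[r, c] = cache[a]
    else:
        for r in range(height):
            for c in range(width):
                window, ok = extract_and_splice(filtered, (r, c), h, w_l, w_r)
                d, _, unique = detect_disparity(window, bank)
                values[r, c] = d
                valid[r, c] = ok and unique
    return DisparityMap(values=values, valid_mask=valid)


def average_error(
    estimate: DisparityMap | np.ndarray,
    truth: np.ndarray,
    where: np.ndarray | None = None,
) -> float:
    """Percentage of valid pixels whose disparity differs from ground truth.

    ``where`` optionally restricts the comparison (e.g. to region
    interiors); it is intersected with the estimate's validity mask.
    Raises if no valid pixel remains.
    """
    if isinstance(estimate, DisparityMap):
        values, valid = estimate.values, estimate.valid_mask.copy()
    else:
        values, valid = np.asarray(estimate), np.ones(truth.shape, dtype=bool)
    if values.shape != truth.shape:
        raise ValueError("shape mismatch between estimate and ground truth")
    if where is not None:
        valid = valid & where
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid pixels: average error undefined")
    return 100.0 * float((values[valid] != truth[valid]).sum()) / n


def interior_mask(layout, shape: tuple[int, int], margin: int = 10) -> np.ndarray:
    """Pixels at least ``margin`` pixels from every region and image border."""
    height, width = shape
    mask = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1, _ in layout:
        rr0, rr1 = max(r0, 0) + margin, min(r1, height) - margin
        cc0, cc1 = max(c0, 0) + margin, min(c1, width) - margin
        if rr0 < rr1 and cc0 < cc1:
            mask[rr0:rr1, cc0:cc1] = True
    mask[:margin, :] = False
    mask[-margin:, :] = False
    mask[:, :margin] = False
    mask[:, -margin:] = False
    return mask
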