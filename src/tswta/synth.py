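"""Synthetic stimuli: interlaced disparity patterns and ground-truthed stereo pairs.

Training stimuli for a disparity cell are binary interlaced windows, the
left |w_L| columns drawn from the left-eye subfield and the right |w_R|
columns from the right-eye subfield, juxtaposed the way ocular-dominance
columns interleave the two eyes' views.  ON bits stand for a high-voltage
input pulse, OFF bits for the low-voltage complement.  A pattern of
disparity ``d`` has its right subfield equal to the left subfield shifted
``d`` columns (zero-fill at vacated columns).

Stereo pairs are rectified grayscale images: disparity is purely
horizontal, so corresponding points lie on the same row (epipolar line),
and a left pixel at column ``c`` with disparity ``d`` appears in the
right image at column ``c + d``.  Occluded / unpainted right columns are
filled from the nearest painted column and flagged rather than
synthesised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DisparityPattern",
    "StereoPair",
    "make_disparity_pattern",
    "make_pattern_set",
    "quadrant_layout",
    "make_stereo_pair",
]


@dataclass
class DisparityPattern:
    """Binary interlaced stimulus with a disparity label.

    ``bits`` is an h x (w_L + w_R) boolean matrix; the first ``w_l``
    columns are the left-eye subfield.  ``complement()`` flips every bit
    (the OFF-phase stimulus that drives the opposing synapses).
    """

    bits: np.ndarray
    disparity: int
    w_l: int
    is_complement: bool = False

    @property
    def h(self) -> int:
        return self.bits.shape[0]

    @property
    def w(self) -> int:
        return self.bits.shape[1]

    @property
    def w_r(self) -> int:
        return self.w - self.w_l

    def complement(self) -> "DisparityPattern":
        return DisparityPattern(
            bits=~self.bits,
            disparity=self.disparity,
            w_l=self.w_l,
            is_complement=not self.is_complement,
        )


@dataclass
class StereoPair:
    """Rectified grayscale pair with per-pixel integer ground truth.

    ``ground_truth`` is aligned to the left image; ``occlusion`` flags
    left pixels whose right-image correspondence was overwritten or
    hole-filled during synthesis.
    """

    left: np.ndarray
    right: np.ndarray
    ground_truth: np.ndarray
    occlusion: np.ndarray

    def __post_init__(self) -> None:
        if not (self.left.shape == self.right.shape == self.ground_truth.shape):
            raise ValueError("left, right and ground_truth must share one shape")


def _bar_subfields(h: int, w_l: int, w_r: int, d: int, ref: int, edge_style: bool):
    left = np.zeros((h, w_l), dtype=bool)
    right = np.zeros((h, w_r), dtype=bool)
    if edge_style:
        # the two gradient flanks of a bar, as an edge-filtered image
        # presents it: ON at ref +/- 1
        for c in (ref - 1, ref + 1):
            if 0 <= c < w_l:
                left[:, c] = True
            if 0 <= c + d < w_r:
                right[:, c + d] = True
    else:
        left[:, ref] = True
        right[:, ref + d] = True
    return left, right


def make_disparity_pattern(
    h: int,
    w_l: int,
    w_r: int,
    d: int,
    style: str = "random_dot",
    seed: int | None = 0,
    ref: int = 0,
) -> DisparityPattern:
    """One interlaced training pattern of disparity ``d``.

    Styles
    ------
    ``bar``
        A single vertical ON bar at column ``ref`` of the left subfield
        and at ``ref + d`` of the right subfield.
    ``bar_edges``
        The edge-transform of ``bar``: ON at the two flank columns
        ``ref +/- 1`` (clipped to the subfield), matching what a
        gradient-magnitude prefilter makes of a bar.
    ``random_dot``
        Seeded iid binary left subfield (density 0.5); right subfield is
        the left one shifted ``d`` columns with zero-fill.
    """
    if not 0 <= d < min(w_l, w_r):
        raise ValueError(f"disparity {d} outside [0, {min(w_l, w_r)})")
    if style in ("bar", "bar_edges"):
        if not 0 <= ref + d < w_r or not 0 <= ref < w_l:
            raise ValueError("bar reference column out of range for this disparity")
        left, right = _bar_subfields(h, w_l, w_r, d, ref, style == "bar_edges")
    elif style == "random_dot":
        rng = np.random.default_rng(seed)
        left = rng.random((h, w_l)) < 0.5
        right = np.zeros((h, w_r), dtype=bool)
        src_w = min(w_l, w_r - d)
        right[:, d : d + src_w] = left[:, :src_w]
    else:
        raise ValueError(f"unknown pattern style {style!r}")
    return DisparityPattern(np.hstack([left, right]), disparity=d, w_l=w_l)


def make_pattern_set(
    h: int,
    w: int,
    n_disparities: int,
    style: str = "random_dot",
    seed: int = 0,
) -> list[DisparityPattern]:
    """The training set: one pattern per disparity plus every complement.

    The total width ``w`` is split near-evenly, w_L = floor(w/2) and
    w_R = ceil(w/2), so a 9-wide window is a 4|5 splice.  Random-dot
    left subfields are drawn independently per disparity (child seeds of
    ``seed``), and the draw is repeated until the set is mutually
    quasi-orthogonal: no two patterns (in either phase) agree on more
    than ``max_overlap`` of their bits.  Orthogonality is a property of
    the training set, not luck — strongly overlapping patterns are not
    distinct stimuli.  Bar-style sets are intentionally correlated and
    skip the check.
    """
    w_l, w_r = w // 2, w - w // 2
    if n_disparities > min(w_l, w_r):
        raise ValueError(
            f"{n_disparities} disparities exceed the capacity {min(w_l, w_r)} "
            f"of a {w}-wide spliced field"
        )
    if n_disparities < 1:
        raise ValueError("need at least one disparity")
    max_overlap = 0.65
    ss = np.random.SeedSequence(seed)
    best, best_score = None, np.inf
    for _ in range(20):
        child_seeds = ss.generate_state(n_disparities)
        candidate = [
            make_disparity_pattern(h, w_l, w_r, d, style=style, seed=int(child_seeds[d]))
            for d in range(n_disparities)
        ]
        score = _worst_overlap(candidate) if style == "random_dot" else 0.0
        if score < best_score:
            best, best_score = candidate, score
        if score <= max_overlap:
            break
        # large shifts under zero-fill share structural blank columns, so
        # the bound may be unreachable; keep the most orthogonal draw
        ss = ss.spawn(1)[0]
    patterns = best
    out = patterns + [p.complement() for p in patterns]
    # pairwise distinctness is a contract of the set
    flat = {p.bits.tobytes() for p in out}
    if len(flat) != len(out):
        raise ValueError("generated patterns are not pairwise distinct; change the seed")
    return out


def _worst_overlap(patterns) -> float:
    worst = 0.0
    for i, a in enumerate(patterns):
        for b in patterns[i + 1 :]:
            agree = float(np.mean(a.bits == b.bits))
            worst = max(worst, agree, 1.0 - agree)
    return worst


def quadrant_layout(height: int, width: int, disparities=(0, 1, 2, 3)):
    """Four-rectangle layout: quadrants with the given disparities."""
    if len(disparities) != 4:
        raise ValueError("quadrant layout needs exactly four disparities")
    r, c = height // 2, width // 2
    d = list(disparities)
    return [
        (0, r, 0, c, d[0]),
        (0, r, c, width, d[1]),
        (r, height, 0, c, d[2]),
        (r, height, c, width, d[3]),
    ]


def _check_layout(layout, height: int, width: int) -> None:
    cover = np.zeros((height, width), dtype=np.int8)
    for r0, r1, c0, c1, _ in layout:
        if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
            raise ValueError("layout rectangle outside the image")
        cover[r0:r1, c0:c1] += 1
    if (cover > 1).any():
        raise ValueError("layout rectangles overlap")
    if (cover == 0).any():
        raise ValueError("layout rectangles do not tile the image")


def make_stereo_pair(
    height: int,
    width: int,
    layout=None,
    texture: str = "bars",
    seed: int = 0,
    bar_period: int = 8,
    background: float = 0.2,
    foreground: float = 1.0,
    noise_sigma: float = 0.0,
    shading: float = 0.0,
) -> StereoPair:
    """Ground-truthed rectified stereo pair.

    The left image is textured (``bars``: full-height vertical bars every
    ``bar_period`` columns; ``random_dot``: iid binary dots); the right
    image is painted by displacing every left pixel ``d`` columns to the
    right, where ``d`` is its region's disparity.  Nearer surfaces
    (larger d) overwrite farther ones; unpainted right columns are filled
    from the nearest painted neighbour, and every left pixel involved in
    an overwrite or adjacent to a fill is flagged in the occlusion mask.
    Optional iid Gaussian noise (std ``noise_sigma``) is added to both
    images after synthesis, seeded.
    """
    if layout is None:
        layout = quadrant_layout(height, width)
    _check_layout(layout, height, width)
    rng = np.random.default_rng(seed)

    left = np.full((height, width), background, dtype=float)
    if texture == "bars":
        # phase offset keeps bars away from the image edge, where the
        # disparity shift would otherwise duplicate one into the fill
        left[:, bar_period // 2 :: bar_period] = foreground
    elif texture == "random_dot":
        left = np.where(rng.random((height, width)) < 0.5, foreground, background)
    else:
        raise ValueError(f"unknown texture {texture!r}")

    truth = np.zeros((height, width), dtype=int)
    for r0, r1, c0, c1, d in layout:
        if d < 0:
            raise ValueError("disparities must be non-negative")
        truth[r0:r1, c0:c1] = d

    right = np.full((height, width), np.nan)
    src_col = np.full((height, width), -1, dtype=int)  # left col painted at each right px
    occl = np.zeros((height, width), dtype=bool)
    cols = np.arange(width)
    # paint far-to-near so nearer (larger d) surfaces win
    order = np.argsort(truth, axis=1, kind="stable")  # per-row stable sort by d
    for r in range(height):
        for c in cols[order[r]]:
            d = truth[r, c]
            tc = c + d
            if tc >= width:
                occl[r, c] = True  # falls off the right image
                continue
            if src_col[r, tc] >= 0:
                occl[r, src_col[r, tc]] = True  # overwritten: occluded
            right[r, tc] = left[r, c]
            src_col[r, tc] = c
    # hole fill from nearest painted column in the row
    for r in range(height):
        holes = np.where(np.isnan(right[r]))[0]
        if holes.size == 0:
            continue
        painted = np.where(~np.isnan(right[r]))[0]
        for hc in holes:
            nearest = painted[np.argmin(np.abs(painted - hc))]
            right[r, hc] = right[r, nearest]
            # flag the left pixels whose correspondence was synthesised
            lc = hc - truth[r, min(hc, width - 1)]
            if 0 <= lc < width:
                occl[r, lc] = True
    if shading != 0.0:
        # smooth multiplicative-free illumination ramp across the image,
        # the low-frequency nuisance an edge front end removes
        ramp = (
            shading
            * (np.arange(width) / max(width - 1, 1))[None, :]
            * np.ones((height, 1))
        )
        left = left + ramp
        right = right + ramp
    if noise_sigma > 0:
        left = left + rng.normal(0.0, noise_sigma, left.shape)
        right = right + rng.normal(0.0, noise_sigma, right.shape)
    return StereoPair(left=left, right=right, ground_truth=truth, occlusion=occl)
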