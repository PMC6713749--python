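"""Hierarchical 3D block matching by normalized cross-correlation (NCC).

The moving image (one cardiac frame) is decomposed into a nested hierarchy of
cubic blocks — templates (t), segments (t/2), chunks (t/4) and windows (t/8).
Each template is matched into the reference (end-diastolic) image by finding
the lag maximising the NCC

    lambda = sum[(f - fbar)(b - bbar)] /
             sqrt( sum[(f - fbar)^2] * sum[(b - bbar)^2] )

where ``b`` is the moving block and ``f`` the overlapped reference patch.
Children are then matched only inside their parent's matched block, which
restricts the search monotonically down to windows.  Template, segment and
chunk matches are validated against overlapping blocks of neighbouring
sizes (a "pyramid" of blocks centred on the validated block); disagreement,
a weak correlation peak, or a template peak stuck on the search boundary
marks the whole subtree non-displaced.  The first (minimum-index) corner of
every window becomes one control-point correspondence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .core import BlockSpec, HierarchyParams

__all__ = [
    "MatchResult",
    "ControlPointSet",
    "decompose",
    "ncc",
    "ncc_surface",
    "match_block",
    "pyramid_validate",
    "hierarchical_match",
]

# Direct (exact summation) NCC is used when block_voxels * n_lags is below
# this; larger searches go through FFT correlation.
_DIRECT_LIMIT = 4_000_000

# Relative variance threshold below which a patch counts as constant
# (degenerate for NCC; the correlation is defined as 0 there).
_VAR_RTOL = 1e-12

# Overlap ("pyramid") block edge lengths as multiples of t/8: three sizes
# strictly between segment (4/8 t) and template (8/8 t), one between chunk
# (2/8 t) and segment, and three above the template for template-level
# validation (the template's "parent" is the whole search region).
_SEGMENT_OVERLAP_EIGHTHS = (5, 6, 7)
_CHUNK_OVERLAP_EIGHTHS = (3,)
_TEMPLATE_OVERLAP_EIGHTHS = (9, 10, 11)


@dataclass
class MatchResult:
    """Outcome of matching one moving block into a reference region."""

    moving_block: BlockSpec
    matched_origin: tuple[int, int, int]
    cc: float
    valid: bool

    @property
    def displacement(self) -> np.ndarray:
        return np.asarray(self.matched_origin) - np.asarray(self.moving_block.origin)


@dataclass
class ControlPointSet:
    """Paired window representative points: moving frame vs. reference frame.

    ``valid`` is False for windows that failed pyramid validation (emitted
    non-displaced, ``reference == moving``).  ``degenerate`` additionally
    marks windows whose intensities carried no texture at some hierarchy
    level (zero-variance blocks), for which no correspondence information
    exists at all.
    """

    moving: np.ndarray  # (N, 3) int voxel coords
    reference: np.ndarray  # (N, 3) int voxel coords
    cc: np.ndarray  # (N,) float
    valid: np.ndarray  # (N,) bool
    degenerate: np.ndarray = field(default=None)  # (N,) bool

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=int).reshape(-1, 3)
        self.reference = np.asarray(self.reference, dtype=int).reshape(-1, 3)
        self.cc = np.asarray(self.cc, dtype=float).ravel()
        self.valid = np.asarray(self.valid, dtype=bool).ravel()
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.moving), dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool).ravel()
        n = len(self.moving)
        if not (len(self.reference) == len(self.cc) == len(self.valid) == n):
            raise ValueError("control point arrays must have equal lengths")
        bad = ~self.valid & np.any(self.moving != self.reference, axis=1)
        if bad.any():
            raise ValueError("invalid pairs must be non-displaced (reference == moving)")

    def __len__(self) -> int:
        return len(self.moving)

    @property
    def displacements(self) -> np.ndarray:
        return self.reference - self.moving

    def informative(self) -> "ControlPointSet":
        """The subset of pairs whose windows carried texture."""
        m = ~self.degenerate
        return ControlPointSet(
            self.moving[m], self.reference[m], self.cc[m], self.valid[m], self.degenerate[m]
        )


def decompose(image_shape, params: HierarchyParams) -> list[BlockSpec]:
    """Tile the image with template blocks of edge ``t``.

    Templates cover the largest sub-grid divisible by ``t`` starting at the
    origin; trailing partial blocks are skipped.  Children (segments, chunks,
    windows) are generated on demand via :meth:`BlockSpec.children`.
    """
    t = params.template_size
    shape = tuple(int(s) for s in image_shape)
    counts = [s // t for s in shape]
    if any(c < 1 for c in counts):
        raise ValueError(f"image shape {shape} smaller than one template ({t}^3)")
    out = []
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                out.append(BlockSpec((ix * t, iy * t, iz * t), t, "template"))
    return out


def _is_constant(a: np.ndarray) -> bool:
    a = np.asarray(a, dtype=float)
    v = a - a.mean()
    return float(np.dot(v.ravel(), v.ravel())) <= _VAR_RTOL * float(np.dot(a.ravel(), a.ravel()) + 1.0)


def ncc(block: np.ndarray, region: np.ndarray, lag) -> float:
    """Correlation coefficient of ``block`` against ``region`` at one lag.

    ``lag`` is the offset of the block's minimum corner relative to the
    region's minimum corner.  Returns 0 for zero-variance patches.
    """
    block = np.asarray(block, dtype=float)
    region = np.asarray(region, dtype=float)
    lag = tuple(int(p) for p in lag)
    if any(b > r for b, r in zip(block.shape, region.shape)):
        raise ValueError("block larger than region")
    if any(p < 0 or p + b > r for p, b, r in zip(lag, block.shape, region.shape)):
        raise ValueError(f"block does not fit inside region at lag {lag}")
    patch = region[tuple(slice(p, p + b) for p, b in zip(lag, block.shape))]
    db = block - block.mean()
    df = patch - patch.mean()
    den = math.sqrt(float((df * df).sum()) * float((db * db).sum()))
    if _is_constant(block) or _is_constant(patch) or den == 0.0:
        return 0.0
    return float(np.clip((df * db).sum() / den, -1.0, 1.0))


def _box_sum(a: np.ndarray, window) -> np.ndarray:
    """Sum of ``a`` over every sliding window of the given shape (valid mode)."""
    out = a
    for ax, w in enumerate(window):
        c = np.cumsum(out, axis=ax)
        lead = [slice(None)] * out.ndim
        lead[ax] = slice(w - 1, None)
        s = c[tuple(lead)].copy()
        tail = [slice(None)] * out.ndim
        tail[ax] = slice(None, -w)
        head = [slice(None)] * out.ndim
        head[ax] = slice(1, None)
        s[tuple(head)] -= c[tuple(tail)]
        out = s
    return out


def ncc_surface(block: np.ndarray, region: np.ndarray) -> np.ndarray:
    """NCC of ``block`` against ``region`` at every admissible lag.

    Uses exact sliding-window summation for small searches and FFT
    correlation for large ones; both share the box-sum normalisation.
    Zero-variance patches (and a zero-variance block) yield 0.
    """
    block = np.asarray(block, dtype=float)
    region = np.asarray(region, dtype=float)
    if any(b > r for b, r in zip(block.shape, region.shape)):
        raise ValueError("block larger than region")
    out_shape = tuple(r - b + 1 for r, b in zip(region.shape, block.shape))
    V = block.size
    bsum = float(block.sum())
    db = block - bsum / V
    bss = float((db * db).sum())
    if bss <= _VAR_RTOL * float((block * block).sum() + 1.0):
        return np.zeros(out_shape)
    S1 = _box_sum(region, block.shape)
    S2 = _box_sum(region * region, block.shape)
    n_lags = int(np.prod(out_shape))
    if V * n_lags <= _DIRECT_LIMIT:
        win = sliding_window_view(region, block.shape)
        corr = np.tensordot(win, block, axes=3)
    else:
        corr = fftconvolve(region, block[::-1, ::-1, ::-1], mode="valid")
    num = corr - S1 * (bsum / V)
    den_f = S2 - S1 * S1 / V
    degenerate = den_f <= _VAR_RTOL * np.maximum(S2, 1.0)
    den = np.sqrt(np.clip(den_f, 0.0, None) * bss)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(degenerate | (den == 0.0), 0.0, num / np.where(den == 0.0, 1.0, den))
    return np.clip(lam, -1.0, 1.0)


def match_block(
    block: np.ndarray,
    region: np.ndarray,
    *,
    moving_block: BlockSpec,
    region_origin,
    cc_tolerance: float = 0.0,
) -> MatchResult:
    """Find the lag maximising NCC of ``block`` over ``region``.

    Correlations within ``cc_tolerance`` of the maximum are treated as tied;
    ties are broken by (1) smallest Euclidean displacement from the block's
    original position, then (2) lexicographic (z, y, x) order of the
    displacement.  A zero-variance moving block is degenerate: it is returned
    non-displaced with ``valid=False``.
    """
    region_origin = np.asarray(region_origin, dtype=int)
    if any(b > r for b, r in zip(block.shape, region.shape)):
        raise ValueError("empty lag set: block larger than search region")
    if _is_constant(block):
        return MatchResult(moving_block, moving_block.origin, 0.0, False)
    lam = ncc_surface(block, region)
    best = float(lam.max())
    cand = np.argwhere(lam >= best - cc_tolerance)
    origins = cand + region_origin
    disp = origins - np.asarray(moving_block.origin)
    d2 = np.einsum("ij,ij->i", disp, disp)
    # lexicographic (z, y, x): compare reversed displacement tuples
    order = np.lexsort((disp[:, 0], disp[:, 1], disp[:, 2], d2))
    pick = order[0]
    origin = tuple(int(v) for v in origins[pick])
    return MatchResult(moving_block, origin, float(lam[tuple(cand[pick])]), True)


def pyramid_validate(
    block_match: MatchResult,
    overlap_matches: list[MatchResult],
    tol: float,
) -> bool:
    """True iff every overlap block's displacement agrees with the block's.

    Agreement is Euclidean distance between displacement vectors <= ``tol``
    (voxels).  Overlap matches that are themselves degenerate are skipped;
    with no usable overlap the match stands.
    """
    d0 = block_match.displacement
    for om in overlap_matches:
        if not om.valid:
            continue
        if float(np.linalg.norm(om.displacement - d0)) > tol:
            return False
    return True


def _overlap_blocks(block: BlockSpec, sizes, image_shape) -> list[BlockSpec]:
    """Overlap blocks of the given edge lengths centred on ``block``.

    Blocks clipped by the image border are dropped (degenerate for NCC).
    """
    out = []
    for v in sizes:
        origin = tuple(o + (block.size - v) // 2 for o in block.origin)
        ob = BlockSpec(origin, v, "overlap")
        if ob.inside(image_shape):
            out.append(ob)
    return out


def _search_region(parent_origin, parent_size, block_size, image_shape, margin=0):
    """Reference region for a block constrained to its parent's matched block.

    The region equals the parent's matched block expanded per side by
    ``margin`` (zero for ordinary children; for overlap blocks, half their
    size excess over the child they validate, i.e. exactly the positions
    compatible with the child lying inside the parent), clipped to the image.
    """
    lo = [max(0, p - margin) for p in parent_origin]
    hi = [min(s, p + parent_size + margin) for p, s in zip(parent_origin, image_shape)]
    # widen degenerate regions so the block at least fits
    for ax in range(3):
        if hi[ax] - lo[ax] < block_size:
            lo[ax] = max(0, min(lo[ax], image_shape[ax] - block_size))
            hi[ax] = min(image_shape[ax], lo[ax] + block_size)
    return tuple(lo), tuple(hi)


def _match_in_parent(moving, reference, block, parent_match, cc_tol,
                     parent_size=None, margin=0):
    shape = reference.shape
    psize = parent_match.moving_block.size if parent_size is None else parent_size
    lo, hi = _search_region(parent_match.matched_origin, psize, block.size, shape, margin)
    region = reference[tuple(slice(a, b) for a, b in zip(lo, hi))]
    return match_block(
        moving[block.slices], region, moving_block=block, region_origin=lo, cc_tolerance=cc_tol
    )


def hierarchical_match(
    moving: np.ndarray, reference: np.ndarray, params: HierarchyParams
) -> ControlPointSet:
    """Match one moving frame into the reference and emit control points.

    Templates are searched within ``search_radius`` of their original
    position (``None`` = whole image); segments only inside their template's
    matched block, chunks inside matched segments, windows inside matched
    chunks.  Windows in subtrees that fail pyramid validation — or that carry
    no texture at some level — are emitted as non-displaced pairs.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(f"frame shape mismatch: {moving.shape} vs {reference.shape}")
    shape = moving.shape
    t8 = params.template_size // 8
    seg_ov_sizes = [k * t8 for k in _SEGMENT_OVERLAP_EIGHTHS]
    chunk_ov_sizes = [k * t8 for k in _CHUNK_OVERLAP_EIGHTHS]

    m_pts, r_pts, ccs, valids, degens = [], [], [], [], []

    def emit_subtree(block: BlockSpec, valid_cc: float, degenerate: bool) -> None:
        """Emit every window under ``block`` as a non-displaced pair."""
        if block.level == "window":
            m_pts.append(block.representative_point)
            r_pts.append(block.representative_point)
            ccs.append(valid_cc)
            valids.append(False)
            degens.append(degenerate)
            return
        for ch in block.children():
            emit_subtree(ch, valid_cc, degenerate)

    def search_bounds(block: BlockSpec):
        if params.search_radius is None:
            return (0, 0, 0), shape
        r = params.search_radius
        lo = tuple(max(0, o - r) for o in block.origin)
        hi = tuple(min(s, o + block.size + r) for o, s in zip(block.origin, shape))
        return lo, hi

    def match_free(block: BlockSpec) -> MatchResult:
        lo, hi = search_bounds(block)
        region = reference[tuple(slice(a, b) for a, b in zip(lo, hi))]
        return match_block(
            moving[block.slices], region, moving_block=block, region_origin=lo,
            cc_tolerance=params.cc_tolerance,
        )

    def peak_on_boundary(mres: MatchResult) -> bool:
        # only interior search-region faces count: at an image edge the
        # admissible lag set is genuinely exhausted, not artificially cut
        lo, hi = search_bounds(mres.moving_block)
        for o, a, b, s in zip(mres.matched_origin, lo, hi, shape):
            if o == a and a > 0:
                return True
            if o + mres.moving_block.size == b and b < s:
                return True
        return False

    tmpl_ov_sizes = [k * t8 for k in _TEMPLATE_OVERLAP_EIGHTHS]

    def match_template_overlap(template: BlockSpec, size: int) -> MatchResult | None:
        """Match a centred overlap box of the template, clipped to the image.

        Template-level overlaps are larger than the template, so at the
        image border they are clipped to a rectangular box rather than
        skipped — otherwise border templates would go unvalidated.
        """
        lo = [max(0, o + (template.size - size) // 2) for o in template.origin]
        hi = [min(s, o + (template.size - size) // 2 + size)
              for o, s in zip(template.origin, shape)]
        box = moving[tuple(slice(a, b) for a, b in zip(lo, hi))]
        if _is_constant(box):
            return None
        if params.search_radius is None:
            rlo, rhi = (0, 0, 0), shape
        else:
            r = params.search_radius
            rlo = tuple(max(0, a - r) for a in lo)
            rhi = tuple(min(s, b + r) for b, s in zip(hi, shape))
        region = reference[tuple(slice(a, b) for a, b in zip(rlo, rhi))]
        lam = ncc_surface(box, region)
        best = float(lam.max())
        cand = np.argwhere(lam >= best - params.cc_tolerance)
        disp = cand + np.asarray(rlo) - np.asarray(lo)
        d2 = np.einsum("ij,ij->i", disp, disp)
        pick = np.lexsort((disp[:, 0], disp[:, 1], disp[:, 2], d2))[0]
        origin = tuple(int(x) for x in np.asarray(lo) + disp[pick])
        # reuse MatchResult with a synthetic cubic spec; only .displacement
        # and .valid are consumed by pyramid_validate
        fake = BlockSpec(tuple(lo), 1, "overlap")
        return MatchResult(fake, origin, float(lam[tuple(cand[pick])]), True)

    for template in decompose(shape, params):
        tmpl_arr = moving[template.slices]
        if _is_constant(tmpl_arr):
            emit_subtree(template, 0.0, True)
            continue
        tmatch = match_free(template)
        # A correlation peak on the boundary of the search region means the
        # true optimum most likely lies outside it; a weak peak means the
        # content has no reliable counterpart.  Either way the subtree's
        # windows are emitted non-displaced.
        if peak_on_boundary(tmatch) or tmatch.cc < params.cc_min:
            emit_subtree(template, tmatch.cc, False)
            continue
        t_overlaps = [
            om for om in (match_template_overlap(template, v) for v in tmpl_ov_sizes)
            if om is not None
        ]
        if not pyramid_validate(tmatch, t_overlaps, params.pyramid_agreement_tol):
            emit_subtree(template, tmatch.cc, False)
            continue
        for segment in template.children():
            seg_arr = moving[segment.slices]
            if _is_constant(seg_arr):
                emit_subtree(segment, 0.0, True)
                continue
            smatch = _match_in_parent(moving, reference, segment, tmatch, params.cc_tolerance)
            if smatch.cc < params.cc_min:
                emit_subtree(segment, smatch.cc, False)
                continue
            overlaps = [
                _match_in_parent(moving, reference, ob, tmatch, params.cc_tolerance,
                                 parent_size=template.size,
                                 margin=(ob.size - segment.size) // 2)
                for ob in _overlap_blocks(segment, seg_ov_sizes, shape)
            ]
            if not pyramid_validate(smatch, overlaps, params.pyramid_agreement_tol):
                emit_subtree(segment, smatch.cc, False)
                continue
            for chunk in segment.children():
                chunk_arr = moving[chunk.slices]
                if _is_constant(chunk_arr):
                    emit_subtree(chunk, 0.0, True)
                    continue
                cmatch = _match_in_parent(moving, reference, chunk, smatch, params.cc_tolerance)
                if cmatch.cc < params.cc_min:
                    emit_subtree(chunk, cmatch.cc, False)
                    continue
                covs = [
                    _match_in_parent(moving, reference, ob, smatch, params.cc_tolerance,
                                     parent_size=segment.size,
                                     margin=(ob.size - chunk.size) // 2)
                    for ob in _overlap_blocks(chunk, chunk_ov_sizes, shape)
                ]
                if not pyramid_validate(cmatch, covs, params.pyramid_agreement_tol):
                    emit_subtree(chunk, cmatch.cc, False)
                    continue
                for window in chunk.children():
                    win_arr = moving[window.slices]
                    if _is_constant(win_arr):
                        emit_subtree(window, 0.0, True)
                        continue
                    wmatch = _match_in_parent(
                        moving, reference, window, cmatch, params.cc_tolerance
                    )
                    if wmatch.cc < params.cc_min:
                        emit_subtree(window, wmatch.cc, False)
                        continue
                    m_pts.append(window.representative_point)
                    r_pts.append(wmatch.matched_origin)
                    ccs.append(wmatch.cc)
                    valids.append(True)
                    degens.append(False)

    return ControlPointSet(
        np.array(m_pts), np.array(r_pts), np.array(ccs), np.array(valids), np.array(degens)
    )
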