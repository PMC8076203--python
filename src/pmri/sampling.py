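"""Line-based Cartesian undersampling schemes for parallel MRI.

Undersampling is one-dimensional along the phase-encode axis (ky): a line is
either fully acquired across kx or entirely missing.  Three mask families are
supported:

* **uniform** — a centred, fully sampled ACS (auto-calibration signal) block
  plus one line in every ``R`` outside it (the traditional GRAPPA pattern);
* **VDS** — variable-density sampling: the ACS block is shrunk and the freed
  lines are re-spent on a low-ORF band flanking it, with the outermost region
  kept on the original ``R`` grid;
* **MVDS** — multiple-variable-density sampling: the ACS block is kept at its
  original size and a ladder of bands with strictly increasing outer reduction
  factors (ORFs) fills the outer k-space, low ORF near the centre and high ORF
  at the edge, at an unchanged total line budget.

Masks carry per-line region labels (ACS / band k / unsampled) so that a
reconstruction driver can fit and apply one weight set per ORF region, and a
fill plan mapping every missing line to the acquired grid line it should be
interpolated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "Band",
    "SamplingScheme",
    "SamplingMask",
    "make_uniform_mask",
    "make_vds_mask",
    "make_mvds_mask",
    "from_scheme",
    "net_reduction_factor",
    "round_half_up",
    "scheme_report",
]

#: region code for unsampled lines outside every band annulus
UNSAMPLED = -1
#: region code for the ACS block
ACS = 0


@dataclass(frozen=True)
class Band:
    """One undersampling band: stride ``orf`` and its acquired line indices."""

    orf: int
    line_indices: tuple[int, ...]

    @property
    def n_lines(self) -> int:
        return len(self.line_indices)


@dataclass(frozen=True)
class SamplingScheme:
    """Declarative description of a multi-band undersampling scheme.

    Parameters
    ----------
    n_ky:
        Number of phase-encode lines of the fully sampled acquisition.
    acs_count:
        Number of fully sampled central (ACS) lines.
    r_nom:
        Nominal reduction factor of the scheme (stride of the traditional
        pattern it is budget-matched against).
    bands:
        ``(orf, n_lines)`` pairs from innermost to outermost; ORFs must be
        strictly increasing and every ``orf`` at least 2.
    """

    n_ky: int
    acs_count: int
    r_nom: int
    bands: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.acs_count < 2:
            raise ValueError("acs_count must be >= 2")
        total = self.acs_count + sum(n for _, n in self.bands)
        if total > self.n_ky:
            raise ValueError(
                f"requested {total} lines exceed n_ky={self.n_ky}"
            )
        orfs = [orf for orf, _ in self.bands]
        if any(orf < 2 for orf in orfs):
            raise ValueError("band ORFs must be >= 2")
        if any(b <= a for a, b in zip(orfs, orfs[1:])):
            raise ValueError("band ORFs must be strictly increasing outward")


@dataclass
class SamplingMask:
    """Realized per-line mask with region bookkeeping.

    Attributes
    ----------
    n_ky:
        Number of phase-encode lines.
    sampled:
        Boolean array of length ``n_ky``; True where the line is acquired.
    region:
        Integer array of length ``n_ky``: ``0`` for ACS lines, ``k >= 1`` for
        every line (acquired or missing) belonging to band ``k``'s annulus,
        ``-1`` for lines no band covers.
    acs_range:
        Half-open ``(start, stop)`` interval of the ACS block.
    bands:
        Ordered :class:`Band` records, innermost first.
    """

    n_ky: int
    sampled: np.ndarray
    region: np.ndarray
    acs_range: tuple[int, int]
    bands: list[Band] = field(default_factory=list)

    # -- derived accessors -------------------------------------------------

    @property
    def sampled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.sampled)

    @property
    def n_sampled(self) -> int:
        return int(self.sampled.sum())

    @property
    def acs_count(self) -> int:
        return self.acs_range[1] - self.acs_range[0]

    def counts(self) -> dict[str, int]:
        """Acquired-line count per region, keyed ``ACS`` / ``R{orf}``."""
        out = {"ACS": self.acs_count}
        for band in self.bands:
            key = f"R{band.orf}"
            out[key] = out.get(key, 0) + band.n_lines
        return out

    def fill_plan(self) -> list[tuple[int, int, int, int]]:
        """Synthesis plan for every missing line.

        Returns ``(line, region, orf, base)`` tuples where ``base`` is the
        grid line (acquired, or virtual beyond the matrix edge) directly
        below ``line`` on that band's stride, so ``1 <= line - base < orf``.
        """
        plan: list[tuple[int, int, int, int]] = []
        orf_of = {k + 1: band.orf for k, band in enumerate(self.bands)}
        phase_of = self._band_phases()
        for t in range(self.n_ky):
            k = int(self.region[t])
            if self.sampled[t] or k <= 0:
                continue
            orf = orf_of[k]
            phase = phase_of[(k, t >= self.acs_range[1])]
            r = (t - phase) % orf
            if r == 0:
                # grid-aligned missing line beyond the band's outermost
                # acquired line (non-tiling scheme): no valid offset, stays 0
                continue
            plan.append((t, k, orf, t - r))
        return plan

    def _band_phases(self) -> dict[tuple[int, bool], int]:
        """Grid anchor per (band, is_high_side); ACS edge when a side is empty."""
        lo_edge, hi_edge = self.acs_range[0], self.acs_range[1] - 1
        phases: dict[tuple[int, bool], int] = {}
        for k, band in enumerate(self.bands, start=1):
            lines = np.asarray(band.line_indices)
            hi = lines[lines > hi_edge]
            lo = lines[lines < lo_edge]
            phases[(k, True)] = int(hi[0]) if hi.size else hi_edge
            phases[(k, False)] = int(lo[-1]) if lo.size else lo_edge
        return phases

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "n_ky": self.n_ky,
            "acs": {"start": self.acs_range[0], "count": self.acs_count},
            "bands": [
                {"orf": b.orf, "line_indices": list(map(int, b.line_indices))}
                for b in self.bands
            ],
            "sampled_lines": [int(i) for i in self.sampled_indices],
            "r_net": round_half_up(net_reduction_factor(self.n_ky, self.n_sampled)),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SamplingMask":
        n_ky = int(d["n_ky"])
        acs_start = int(d["acs"]["start"])
        acs_count = int(d["acs"]["count"])
        bands = [
            Band(int(b["orf"]), tuple(int(i) for i in b["line_indices"]))
            for b in d["bands"]
        ]
        mask = _assemble(n_ky, (acs_start, acs_start + acs_count), bands)
        expect = set(int(i) for i in d["sampled_lines"])
        if set(mask.sampled_indices.tolist()) != expect:
            raise ValueError("sampled_lines inconsistent with acs/bands")
        return mask


# ---------------------------------------------------------------------------
# construction helpers


def _acs_interval(n_ky: int, acs_count: int) -> tuple[int, int]:
    """Centred ACS block: [center - floor(acs/2), center + ceil(acs/2))."""
    center = n_ky // 2
    start = center - acs_count // 2
    stop = start + acs_count
    if start < 0 or stop > n_ky:
        raise ValueError("ACS block does not fit in n_ky")
    return start, stop


def _assemble(
    n_ky: int, acs_range: tuple[int, int], bands: list[Band]
) -> SamplingMask:
    sampled = np.zeros(n_ky, dtype=bool)
    region = np.full(n_ky, UNSAMPLED, dtype=np.int16)
    sampled[acs_range[0] : acs_range[1]] = True
    region[acs_range[0] : acs_range[1]] = ACS
    # annuli: each band covers from the previous boundary out to its farthest
    # line on each side; the outermost band extends to the matrix edge.
    lo_bound, hi_bound = acs_range[0] - 1, acs_range[1]
    for k, band in enumerate(bands, start=1):
        lines = np.asarray(band.line_indices, dtype=int)
        if lines.size and (lines.min() < 0 or lines.max() >= n_ky):
            raise ValueError(
                f"band R{band.orf} does not fit: lines outside [0, {n_ky})"
            )
        if sampled[lines].any() or (region[lines] != UNSAMPLED).any():
            raise ValueError(f"band R{band.orf} overlaps a previous region")
        hi = lines[lines >= hi_bound]
        lo = lines[lines <= lo_bound]
        new_hi = int(hi.max()) + 1 if hi.size else hi_bound
        new_lo = int(lo.min()) if lo.size else lo_bound + 1
        region[hi_bound:new_hi] = k
        region[new_lo : lo_bound + 1] = k
        sampled[lines] = True
        hi_bound, lo_bound = new_hi, new_lo - 1
    if bands:  # outermost band owns the residual edges
        region[hi_bound:] = len(bands)
        region[: lo_bound + 1] = len(bands)
    return SamplingMask(
        n_ky=n_ky,
        sampled=sampled,
        region=region,
        acs_range=acs_range,
        bands=list(bands),
    )


def _grid_lines(n_ky: int, r: int, exclude: np.ndarray) -> np.ndarray:
    """Global congruence grid {i ≡ center (mod r)} minus excluded lines."""
    center = n_ky // 2
    grid = np.arange(center % r, n_ky, r)
    return grid[~exclude[grid]]


# ---------------------------------------------------------------------------
# public constructors


def make_uniform_mask(n_ky: int, acs_count: int, r_nom: int) -> SamplingMask:
    """Traditional GRAPPA pattern: centred ACS plus one line in every ``r_nom``.

    Outer lines sit on the single global grid ``{i ≡ center (mod r_nom)}``,
    which keeps ACS and outer samples phase-aligned and reproduces the
    conventional line budget ``acs + ceil((n_ky - acs) / r_nom)`` for centred
    blocks.
    """
    if acs_count <= 0 or r_nom < 1 or n_ky <= 0:
        raise ValueError("n_ky, acs_count and r_nom must be positive")
    if acs_count > n_ky:
        raise ValueError("acs_count exceeds n_ky")
    acs_range = _acs_interval(n_ky, acs_count)
    covered = np.zeros(n_ky, dtype=bool)
    covered[acs_range[0] : acs_range[1]] = True
    outer = _grid_lines(n_ky, r_nom, covered)
    bands = [Band(r_nom, tuple(outer.tolist()))] if outer.size else []
    return _assemble(n_ky, acs_range, bands)


def _flank_lines(
    acs_range: tuple[int, int], orf: int, n_lines: int, n_ky: int
) -> np.ndarray:
    """``n_lines`` at stride ``orf`` flanking the ACS block, split half per
    side with the odd remainder on the high-index side."""
    n_hi = n_lines - n_lines // 2
    n_lo = n_lines // 2
    hi = acs_range[1] - 1 + orf * np.arange(1, n_hi + 1)
    lo = acs_range[0] - orf * np.arange(1, n_lo + 1)
    lines = np.sort(np.concatenate([lo[::-1], hi]))
    if lines.size and (lines[0] < 0 or lines[-1] >= n_ky):
        raise ValueError(
            f"band R{orf} with {n_lines} lines does not fit in n_ky={n_ky}"
        )
    return lines


def make_mvds_mask(
    n_ky: int, acs_count: int, bands: list[tuple[int, int]]
) -> SamplingMask:
    """Multiple-variable-density mask.

    The ACS block keeps its size; band 1 (lowest ORF) flanks it at its own
    stride, each further band continues outward anchored on the previous
    band's outermost line, so that consecutive acquired lines within band k
    are exactly ``orf_k`` apart.  Per-band line counts are honoured exactly.

    Each band is split half per side of the ACS block (odd remainder to the
    high-index side).  When the even split would push a band past a matrix
    edge while room remains on the other side, single lines are moved across
    deterministically (smallest-ORF band first) until both sides fit; if no
    such split exists the scheme is rejected.
    """
    scheme = SamplingScheme(
        n_ky=n_ky,
        acs_count=acs_count,
        r_nom=bands[0][0] if bands else 1,
        bands=tuple(bands),
    )
    acs_range = _acs_interval(n_ky, acs_count)
    n_hi, n_lo = _split_bands(scheme.bands, acs_range, n_ky)
    placed: list[Band] = []
    lo_anchor, hi_anchor = acs_range[0], acs_range[1] - 1
    for (orf, _), nh, nl in zip(scheme.bands, n_hi, n_lo):
        hi = hi_anchor + orf * np.arange(1, nh + 1)
        lo = lo_anchor - orf * np.arange(1, nl + 1)
        lines = np.sort(np.concatenate([lo[::-1], hi]))
        placed.append(Band(orf, tuple(lines.tolist())))
        if nh:
            hi_anchor = int(hi[-1])
        if nl:
            lo_anchor = int(lo[-1])
    return _assemble(n_ky, acs_range, placed)


def _split_bands(
    bands: tuple[tuple[int, int], ...],
    acs_range: tuple[int, int],
    n_ky: int,
) -> tuple[list[int], list[int]]:
    """Per-side line counts for each band: even split with the odd remainder
    on the high-index side, rebalanced one line at a time when a side
    overflows its available span."""
    n_hi = [n - n // 2 for _, n in bands]
    n_lo = [n // 2 for _, n in bands]
    space_hi = n_ky - acs_range[1]
    space_lo = acs_range[0]

    def span(counts: list[int]) -> int:
        return sum(orf * c for (orf, _), c in zip(bands, counts))

    if span([n for _, n in bands]) > space_hi + space_lo:
        raise ValueError("bands do not fit in n_ky")
    for _ in range(sum(n for _, n in bands) + 2):
        over_hi = span(n_hi) - space_hi
        over_lo = span(n_lo) - space_lo
        if over_hi <= 0 and over_lo <= 0:
            return n_hi, n_lo
        src, dst = (n_hi, n_lo) if over_hi > 0 else (n_lo, n_hi)
        movable = [k for k, c in enumerate(src) if c > 0]
        if not movable:
            break
        k = min(movable, key=lambda i: bands[i][0])
        src[k] -= 1
        dst[k] += 1
    raise ValueError("bands do not fit in n_ky on either side")


def make_vds_mask(
    n_ky: int,
    acs_count: int,
    low_orf_lines: int,
    low_orf: int,
    r_nom: int,
) -> SamplingMask:
    """Variable-density mask: reduced ACS, a low-ORF flank, then the original
    ``r_nom`` grid out to the edges.

    The outermost region stays on the same global congruence grid as the
    traditional mask (VDS only re-spends ACS lines near the centre), so its
    line count matches the traditional pattern it is derived from.
    """
    if low_orf >= r_nom:
        raise ValueError("low_orf must be smaller than r_nom")
    acs_range = _acs_interval(n_ky, acs_count)
    flank = _flank_lines(acs_range, low_orf, low_orf_lines, n_ky)
    covered = np.zeros(n_ky, dtype=bool)
    covered[acs_range[0] : acs_range[1]] = True
    lo_bound = int(flank.min()) if flank.size else acs_range[0]
    hi_bound = int(flank.max()) if flank.size else acs_range[1] - 1
    covered[lo_bound : hi_bound + 1] = True  # inner annulus reserved
    outer = _grid_lines(n_ky, r_nom, covered)
    bands: list[Band] = []
    if flank.size:
        bands.append(Band(low_orf, tuple(flank.tolist())))
    if outer.size:
        bands.append(Band(r_nom, tuple(outer.tolist())))
    return _assemble(n_ky, acs_range, bands)


def from_scheme(scheme: SamplingScheme) -> SamplingMask:
    """Realize a :class:`SamplingScheme` (MVDS semantics; a single band equal
    to ``r_nom`` plus no extras reduces to the traditional pattern)."""
    if not scheme.bands:
        return make_mvds_mask(scheme.n_ky, scheme.acs_count, [])
    return make_mvds_mask(scheme.n_ky, scheme.acs_count, list(scheme.bands))


# ---------------------------------------------------------------------------
# accounting


def net_reduction_factor(n_full: int, sampled_total: int) -> float:
    """Net acceleration R_net = (total lines) / (acquired lines)."""
    if sampled_total <= 0:
        raise ValueError("sampled_total must be positive")
    if sampled_total > n_full:
        raise ValueError("sampled_total exceeds n_full")
    return n_full / sampled_total


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention), e.g. 3.365 -> 3.37."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def scheme_report(mask: SamplingMask) -> dict:
    """Line-budget summary: per-region counts, total, and rounded R_net."""
    counts = mask.counts()
    total = mask.n_sampled
    return {
        "counts": counts,
        "total": total,
        "n_ky": mask.n_ky,
        "r_net": round_half_up(net_reduction_factor(mask.n_ky, total)),
    }
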