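"""Diversity-reduction selection scan.

Domestication leaves a footprint of locally depressed diversity in the
cultivated gene pool.  The scan takes per-window pi for a reference group
(wild rice by default) and a focal cultivated group, forms the per-window
ratio pi_w / pi_c, and calls candidate selected regions where the ratio
falls in the top percentile (default 2.5%), merging adjacent windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .popgen_stats import WindowStat

#: Windows whose cultivated-group pi is below this floor are undefined
#: (excluded from ranking) rather than mapped to +inf.
PI_FLOOR: float = 1e-9


@dataclass
class RatioWindow:
    start: int
    end: int
    pi_w: float
    pi_c: float
    ratio: float  # NaN when pi_c < floor or either pi undefined


@dataclass
class CandidateRegion:
    group: str
    start: int
    end: int
    windows: list[RatioWindow]
    cutoff: float


def diversity_ratio_scan(wild_windows: list[WindowStat],
                         cult_windows: list[WindowStat],
                         floor: float = PI_FLOOR) -> list[RatioWindow]:
    """Per-window pi_w / pi_c over an identical window grid."""
    if len(wild_windows) != len(cult_windows) or any(
        (a.start, a.end) != (b.start, b.end)
        for a, b in zip(wild_windows, cult_windows)
    ):
        raise ValueError("window grids differ between groups")
    out = []
    for w, c in zip(wild_windows, cult_windows):
        if math.isnan(w.pi) or math.isnan(c.pi) or c.pi < floor:
            ratio = float("nan")
        else:
            ratio = w.pi / c.pi
        out.append(RatioWindow(w.start, w.end, w.pi, c.pi, ratio))
    return out


def candidate_regions(ratios: list[RatioWindow], percentile: float = 2.5,
                      group: str = "cultivated") -> list[CandidateRegion]:
    """Top-percentile windows merged into candidate selected regions.

    The cutoff is the (100 - percentile)th percentile (linear
    interpolation) of the defined ratios; windows with ratio >= cutoff are
    selected, so ties at the cutoff are all included.  Overlapping or
    adjacent selected windows merge into one region.
    """
    defined = [r for r in ratios if not math.isnan(r.ratio)]
    if not defined:
        raise ValueError("no defined ratio windows")
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    cutoff = float(np.percentile([r.ratio for r in defined], 100.0 - percentile))
    selected = sorted((r for r in defined if r.ratio >= cutoff),
                      key=lambda r: r.start)
    regions: list[CandidateRegion] = []
    for win in selected:
        if regions and win.start <= regions[-1].end + 1:
            last = regions[-1]
            last.end = max(last.end, win.end)
            last.windows.append(win)
        else:
            regions.append(CandidateRegion(group, win.start, win.end, [win], cutoff))
    return regions
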