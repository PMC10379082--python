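"""Sliding-window bookkeeping shared by the density, diversity and scan stages.

Windows are half-open ``[start, start + window_bp)`` on 1-based starts
``1, 1 + step_bp, ...`` per chromosome — the VCFtools convention, so
window coordinates match what the upstream tools would report.
"""

from __future__ import annotations

import numpy as np


def window_spans(max_pos: int, window_bp: int, step_bp: int) -> np.ndarray:
    """1-based half-open window starts covering positions up to ``max_pos``.

    Returns an array of window start positions; each window spans
    ``[s, s + window_bp)``.  The last window is the last one whose start
    does not exceed ``max_pos``.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    if max_pos < 1:
        return np.empty(0, dtype=np.int64)
    n = (max_pos - 1) // step_bp + 1
    return 1 + step_bp * np.arange(n, dtype=np.int64)


def window_site_slices(pos: np.ndarray, starts: np.ndarray, window_bp: int):
    """For sorted positions, the (lo, hi) index slice of sites in each window."""
    pos = np.asarray(pos)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window_bp, side="left")
    return lo, hi


def per_chrom(vt, order: bool = True):
    """Yield (chrom, index array) in contig order."""
    for c in vt.contigs:
        idx = np.flatnonzero(vt.chrom == c)
        if len(idx):
            yield c, idx
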