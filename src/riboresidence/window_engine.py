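"""Codon windows: unique central occurrences and position-class counting.

For a target codon, a *window* is a span of ``2*half_width + 1`` codons (19 by
default) lying entirely inside a CDS, whose center is the only occurrence of
the target codon in the span.  Footprints of length ``k`` that contain the
center codon fall into exactly one of ``k`` position classes: class ``j``
holds footprints whose ``j``-th codon is the center, i.e. footprints starting
at ``center - j + 1``.  The terminal stop codon is never a window member;
windows that would spill past either CDS end are simply not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .footprint_io import AlignedFootprint
from .genetics import SENSE_CODONS
from .genome_model import CodingRegion, TranscriptomeIndex

__all__ = [
    "WindowConfig",
    "CodonWindow",
    "find_windows",
    "count_classes",
    "qualifies",
    "collect_windows",
    "write_window_dump",
    "read_window_dump",
]


@dataclass(frozen=True)
class WindowConfig:
    """Window qualification thresholds.

    Defaults are the long-footprint settings: +-10 codons, >=20 reads,
    >=3 non-empty classes, footprints of 10 codons.  ``dipeptide_filter``
    optionally restricts windows by whether their translation contains a
    Pro-Pro dipeptide (``exclude_ProPro`` / ``only_ProPro``).
    """

    half_width: int = 10
    min_reads: int = 20
    min_nonempty_classes: int = 3
    k: int = 10
    dipeptide_filter: str = "none"

    def __post_init__(self):
        if self.half_width < self.k - 1:
            raise ValueError(
                f"half_width={self.half_width} too small: all {self.k} position "
                f"classes must fit inside the window (need >= k-1)"
            )
        if self.min_nonempty_classes > self.k:
            raise ValueError("min_nonempty_classes cannot exceed k")
        if self.dipeptide_filter not in ("none", "exclude_ProPro", "only_ProPro"):
            raise ValueError(f"unknown dipeptide_filter {self.dipeptide_filter!r}")


@dataclass
class CodonWindow:
    """One window: a unique central target codon plus its k class counts."""

    region_id: str
    center_codon_index: int  # 1-based along the CDS
    target_codon: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def total(self) -> int:
        return int(self.counts.sum())

    def nonempty_classes(self) -> int:
        return int((self.counts > 0).sum())


def _window_centers(region: CodingRegion, target_codon: str, config: WindowConfig,
                    propro_pair: np.ndarray | None = None) -> np.ndarray:
    """1-based center positions of qualifying windows in one region."""
    codes = region.sense_codons
    n = len(codes)
    hw = config.half_width
    occ = np.array([i for i, c in enumerate(codes) if c == target_codon], dtype=np.int64)
    if occ.size == 0:
        return occ
    keep = np.ones(occ.size, dtype=bool)
    # containment: the full span must lie inside the sense codons
    keep &= (occ - hw >= 0) & (occ + hw <= n - 1)
    # uniqueness within +-half_width
    if occ.size > 1:
        prev = np.empty(occ.size, dtype=np.int64)
        nxt = np.empty(occ.size, dtype=np.int64)
        prev[0], prev[1:] = np.iinfo(np.int64).max, occ[1:] - occ[:-1]
        nxt[-1], nxt[:-1] = np.iinfo(np.int64).max, occ[1:] - occ[:-1]
        keep &= (prev > hw) & (nxt > hw)
    centers = occ[keep]
    if config.dipeptide_filter != "none" and centers.size:
        if propro_pair is None:
            propro_pair = _propro_pairs(region)
        has = np.array(
            [bool(propro_pair[c - hw : c + hw].any()) for c in centers], dtype=bool
        )
        centers = centers[~has] if config.dipeptide_filter == "exclude_ProPro" else centers[has]
    return centers + 1  # to 1-based


def _propro_pairs(region: CodingRegion) -> np.ndarray:
    """Boolean array: position i starts a Pro-Pro dipeptide (sense codons, 0-based)."""
    aa = np.frombuffer(region.amino_acids().encode(), dtype="S1")
    if aa.size < 2:
        return np.zeros(max(aa.size - 1, 0), dtype=bool)
    return (aa[:-1] == b"P") & (aa[1:] == b"P")


def find_windows(
    index: TranscriptomeIndex, target_codon: str, config: WindowConfig = WindowConfig()
) -> list[CodonWindow]:
    """All qualifying window *positions* for one codon (counts zeroed)."""
    out = []
    for region in index.eligible_regions():
        for center in _window_centers(region, target_codon, config):
            out.append(
                CodonWindow(
                    region_id=region.region_id,
                    center_codon_index=int(center),
                    target_codon=target_codon,
                    counts=np.zeros(config.k, dtype=np.int64),
                )
            )
    return out


def count_classes(
    window: CodonWindow, footprints: Iterable[AlignedFootprint], k: int | None = None
) -> CodonWindow:
    """Tabulate footprints into the window's k position classes.

    Class ``j`` (1-based) counts footprints with
    ``start_codon_index == center - j + 1``; everything else is ignored.
    """
    if k is None:
        k = len(window.counts) or 10
    counts = np.zeros(k, dtype=np.int64)
    c = window.center_codon_index
    for fp in footprints:
        if fp.region_id != window.region_id:
            continue
        j = c - fp.start_codon_index + 1
        if 1 <= j <= k:
            counts[j - 1] += 1
    window.counts = counts
    return window


def qualifies(window: CodonWindow, config: WindowConfig = WindowConfig()) -> bool:
    """True iff the window has >= min_reads total and >= min_nonempty_classes."""
    return (
        window.total() >= config.min_reads
        and window.nonempty_classes() >= config.min_nonempty_classes
    )


def _starts_by_region(
    footprints: Sequence[AlignedFootprint], index: TranscriptomeIndex
) -> dict[str, np.ndarray]:
    """Per-region array of footprint-start counts indexed by 1-based codon."""
    out: dict[str, np.ndarray] = {}
    lengths = {rid: index.regions[rid].length_codons for rid in index.regions}
    for fp in footprints:
        n = lengths.get(fp.region_id)
        if n is None:
            continue
        arr = out.get(fp.region_id)
        if arr is None:
            arr = np.zeros(n + 2, dtype=np.int64)
            out[fp.region_id] = arr
        if 1 <= fp.start_codon_index <= n:
            arr[fp.start_codon_index] += 1
    return out


def collect_windows(
    index: TranscriptomeIndex,
    footprints: Sequence[AlignedFootprint],
    config: WindowConfig = WindowConfig(),
    *,
    only_qualifying: bool = True,
) -> dict[str, list[CodonWindow]]:
    """Find, count, and (by default) filter windows for all 61 codons at once.

    Vectorized equivalent of find_windows + count_classes + qualifies; the
    unit tests assert agreement with the per-window primitives.
    """
    k = config.k
    windows: dict[str, list[CodonWindow]] = {c: [] for c in SENSE_CODONS}
    starts = _starts_by_region(footprints, index)
    offsets = np.arange(k, dtype=np.int64)  # class j start = center - (j-1)
    for region in index.eligible_regions():
        arr = starts.get(region.region_id)
        if arr is None:
            arr = np.zeros(region.length_codons + 2, dtype=np.int64)
        present = set(region.sense_codons)
        propro = (
            _propro_pairs(region) if config.dipeptide_filter != "none" else None
        )
        for codon in present:
            if codon not in windows:
                continue
            centers = _window_centers(region, codon, config, propro_pair=propro)
            if centers.size == 0:
                continue
            counts = arr[centers[:, None] - offsets[None, :]]
            for center, cvec in zip(centers, counts):
                win = CodonWindow(
                    region_id=region.region_id,
                    center_codon_index=int(center),
                    target_codon=codon,
                    counts=cvec.copy(),
                )
                if not only_qualifying or qualifies(win, config):
                    windows[codon].append(win)
    return windows


def counts_matrix(windows: Sequence[CodonWindow]) -> np.ndarray:
    """Stack window counts into a (n_windows, k) integer matrix."""
    if not windows:
        return np.zeros((0, 0), dtype=np.int64)
    return np.vstack([w.counts for w in windows])


def write_window_dump(windows_by_codon: dict[str, list[CodonWindow]], path) -> None:
    """TSV dump (region_id, center, target_codon, n_1..n_k) for debugging/oracles."""
    rows = []
    k = None
    for codon in sorted(windows_by_codon):
        for w in windows_by_codon[codon]:
            k = len(w.counts)
            rows.append(
                {
                    "region_id": w.region_id,
                    "center_codon_index": w.center_codon_index,
                    "target_codon": w.target_codon,
                    **{f"n_{j + 1}": int(c) for j, c in enumerate(w.counts)},
                }
            )
    cols = ["region_id", "center_codon_index", "target_codon"] + [
        f"n_{j + 1}" for j in range(k or 0)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_window_dump(path) -> dict[str, list[CodonWindow]]:
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("n_")]
    out: dict[str, list[CodonWindow]] = {}
    for _, row in df.iterrows():
        win = CodonWindow(
            region_id=str(row["region_id"]),
            center_codon_index=int(row["center_codon_index"]),
            target_codon=str(row["target_codon"]),
            counts=np.array([row[c] for c in count_cols], dtype=np.int64),
        )
        out.setdefault(win.target_codon, []).append(win)
    return out
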