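"""One-call orchestration of the window + RRT stages."""

from __future__ import annotations

from typing import Sequence

from .footprint_io import AlignedFootprint
from .genome_model import TranscriptomeIndex
from .rrt_engine import PermutationConfig, RRTProfile, attach_pvalues, rrt_profile
from .window_engine import CodonWindow, WindowConfig, collect_windows

__all__ = ["compute_rrt"]


def compute_rrt(
    index: TranscriptomeIndex,
    footprints: Sequence[AlignedFootprint],
    window_config: WindowConfig = WindowConfig(),
    perm_config: PermutationConfig | None = None,
    aggregator: str = "mean",
    *,
    windows: dict[str, list[CodonWindow]] | None = None,
) -> tuple[RRTProfile, dict[str, list[CodonWindow]]]:
    """Collect qualifying windows, aggregate the RRT profile, optionally test.

    Returns the profile and the window collection (reusable for dumps, the
    shuffle control, or p-value recomputation).  Pass ``windows`` to skip the
    collection step, e.g. after :func:`~riboresidence.simulator.shuffle_codon_assignment`.
    """
    if windows is None:
        windows = collect_windows(index, footprints, window_config)
    profile = rrt_profile(windows, aggregator=aggregator, k=window_config.k)
    if perm_config is not None:
        attach_pvalues(profile, windows, perm_config)
    return profile, windows
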