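"""Shared summary statistics for component scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScoreSummary", "summarize_scores"]


@dataclass(frozen=True)
class ScoreSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "min": self.min,
                "max": self.max, "n": self.n}


def summarize_scores(values, ddof: int = 1) -> ScoreSummary:
    """Mean/SD/min/max of a non-empty score sequence.

    ``ddof=1`` gives the sample SD (default across the whole package,
    config-switchable to population SD via ``ddof=0``). A single value has
    SD 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty score sequence")
    sd = 0.0 if arr.size <= ddof else float(np.std(arr, ddof=ddof))
    return ScoreSummary(
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        n=int(arr.size),
    )
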