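"""Benchmark evaluation of a ranking against a known essential-protein set.

Three protocols: counts of true essentials among the top 1/5/10/15/20/25%
of the ranking (candidate counts use round-half-up), the jackknife
cumulative-hits curve over the whole ranking (with its area normalized to
[0, 1]; 0.5 is chance level), and the precision-recall curve over every
cutoff K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RankedOutput

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _present_essentials(ranking: RankedOutput, essentials: Iterable[str]) -> frozenset[str]:
    present = frozenset(essentials) & frozenset(ranking.protein_ids)
    missing = len(frozenset(essentials)) - len(present)
    if missing:
        logger.info("%d benchmark essentials absent from the ranking are ignored", missing)
    return present


@dataclass(frozen=True)
class EvaluationReport:
    """top_counts maps fraction → (candidates, true positives); jackknife is
    the cumulative hit curve with normalized area; pr_points are (K,
    precision, recall)."""

    top_counts: Mapping[float, tuple[int, int]]
    jackknife: tuple[int, ...]
    jackknife_area: float
    pr_points: tuple[tuple[int, float, float], ...]
    n_ranked: int
    n_essential_present: int

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "top_counts": pd.DataFrame(
                [(f, c, tp) for f, (c, tp) in sorted(self.top_counts.items())],
                columns=["fraction", "candidates", "true_positives"],
            ),
            "jackknife": pd.DataFrame(
                {"rank": np.arange(1, self.n_ranked + 1), "cumulative_hits": self.jackknife}
            ),
            "pr": pd.DataFrame(self.pr_points, columns=["K", "precision", "recall"]),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def top_fraction_hits(
    ranking: RankedOutput,
    essentials: Iterable[str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> dict[float, tuple[int, int]]:
    """For each fraction, the number of candidates (round-half-up of
    fraction·n) and how many of them are true essentials."""
    if len(ranking) == 0:
        raise ValueError("cannot evaluate an empty ranking")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    essentials = frozenset(essentials)
    ids = ranking.protein_ids
    out = {}
    for f in fractions:
        k = _round_half_up(f * len(ids))
        hits = sum(1 for pid in ids[:k] if pid in essentials)
        out[f] = (k, hits)
    return out


def jackknife_curve(
    ranking: RankedOutput, essentials: Iterable[str]
) -> tuple[tuple[int, ...], float]:
    """Cumulative count of true essentials down the ranking, and its area
    normalized by n·|essentials present| (0.5 under a random ordering)."""
    present = _present_essentials(ranking, essentials)
    curve = np.cumsum([pid in present for pid in ranking.protein_ids]).astype(int)
    n = len(curve)
    if n and present:
        area = float(curve.sum()) / (n * len(present))
    else:
        area = float("nan")
    return tuple(int(c) for c in curve), area


def precision_recall_curve(
    ranking: RankedOutput, essentials: Iterable[str]
) -> tuple[tuple[int, float, float], ...]:
    """One (K, precision, recall) point per cutoff K = 1..n; recall is taken
    against the essentials present in the ranking."""
    present = _present_essentials(ranking, essentials)
    if not present:
        raise ValueError("no benchmark essential protein appears in the ranking")
    hits = np.cumsum([pid in present for pid in ranking.protein_ids])
    ks = np.arange(1, len(hits) + 1)
    return tuple(
        (int(k), float(tp) / int(k), float(tp) / len(present))
        for k, tp in zip(ks, hits)
    )


def evaluate_ranking(
    ranking: RankedOutput,
    essentials: Iterable[str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> EvaluationReport:
    """Run all three protocols and bundle the results."""
    essentials = frozenset(essentials)
    curve, area = jackknife_curve(ranking, essentials)
    return EvaluationReport(
        top_counts=top_fraction_hits(ranking, essentials, fractions),
        jackknife=curve,
        jackknife_area=area,
        pr_points=precision_recall_curve(ranking, essentials),
        n_ranked=len(ranking),
        n_essential_present=len(_present_essentials(ranking, essentials)),
    )
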