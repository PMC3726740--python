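"""Alpha diversity and O/E (observed/expected) reference-condition scores.

Four per-sample indices are computed from a count table: taxon richness
S, Shannon diversity H (natural log by default), Pielou's evenness
J = H / ln S, and the Berger-Parker dominance d (relative abundance of
the most abundant taxon). The reference-condition approach compares each
observed index O with an expected value E predicted for the site under
reference conditions (supplied as an input table, e.g. from a
RIVPACS-style model); O/E well below 1 flags reduced diversity at a
potentially impacted site. For display, ratios above 1 are conventionally
capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from geoaxes.geodata import CountTable, GeodataError

__all__ = [
    "AlphaDiversityRow",
    "OEScore",
    "INDEX_NAMES",
    "alpha_diversity",
    "alpha_diversity_frame",
    "oe_scores",
    "oe_frame",
]

INDEX_NAMES = ("richness", "shannon", "pielou", "berger_parker")


@dataclass(frozen=True)
class AlphaDiversityRow:
    """Per-sample alpha-diversity indices.

    ``pielou`` is undefined (None) for single-taxon samples.
    """

    sample_id: str
    richness: int
    shannon: float
    pielou: float | None
    berger_parker: float

    def get(self, index: str) -> float | None:
        if index not in INDEX_NAMES:
            raise KeyError(f"unknown index {index!r}")
        return getattr(self, index)


@dataclass(frozen=True)
class OEScore:
    """Observed/expected ratio for one sample and one diversity index."""

    sample_id: str
    index: str
    observed: float
    expected: float
    ratio: float
    capped_ratio: float
    below_threshold: bool


def alpha_diversity(table: CountTable, log_base: float | None = None
                    ) -> list[AlphaDiversityRow]:
    """Alpha-diversity indices for every sample (row) of a count table.

    Zero-abundance taxa are dropped per sample before computing indices.
    ``log_base`` sets the Shannon logarithm base (natural log when None);
    Pielou's evenness is base-invariant.
    """
    rows = []
    for sample_id, counts in zip(table.sample_ids, table.values):
        n = counts[counts > 0]
        if n.size == 0:
            raise GeodataError(f"sample {sample_id!r} has zero total "
                               "abundance")
        p = n / n.sum()
        h = float(-(p * np.log(p)).sum())
        s = int(n.size)
        if log_base is not None:
            h /= math.log(log_base)
        if s == 1:
            j: float | None = None
            h = 0.0  # exact, avoids -0.0 artifacts
        else:
            # ratio of logs; base cancels
            j = float(-(p * np.log(p)).sum() / math.log(s))
        rows.append(
            AlphaDiversityRow(
                sample_id=sample_id,
                richness=s,
                shannon=h,
                pielou=j,
                berger_parker=float(p.max()),
            )
        )
    return rows


def alpha_diversity_frame(table: CountTable, log_base: float | None = None
                          ) -> pd.DataFrame:
    """Alpha diversity as a DataFrame indexed by sample id."""
    rows = alpha_diversity(table, log_base=log_base)
    return pd.DataFrame(
        {
            "richness": [r.richness for r in rows],
            "shannon": [r.shannon for r in rows],
            "pielou": [np.nan if r.pielou is None else r.pielou
                       for r in rows],
            "berger_parker": [r.berger_parker for r in rows],
        },
        index=pd.Index([r.sample_id for r in rows], name="sample_id"),
    )


def oe_scores(
    observed: Sequence[AlphaDiversityRow] | pd.DataFrame,
    expected: pd.DataFrame,
    cap: bool = True,
    indices: Iterable[str] = INDEX_NAMES,
    threshold: float = 1.0,
) -> list[OEScore]:
    """O/E ratios of observed alpha diversity against expected values.

    ``expected`` is indexed by sample id with one column per index name;
    every requested (sample, index) pair must have a positive expected
    value. ``capped_ratio`` is min(ratio, 1) when ``cap`` is on (both the
    raw and capped ratios are always reported); ``below_threshold`` flags
    ratios under ``threshold`` (default 1.0), the working signal for
    reduced diversity relative to reference condition.
    """
    if isinstance(observed, pd.DataFrame):
        obs_frame = observed
    else:
        obs_frame = pd.DataFrame(
            {idx: [np.nan if r.get(idx) is None else r.get(idx)
                   for r in observed] for idx in INDEX_NAMES},
            index=[r.sample_id for r in observed],
        )
    expected = expected.copy()
    expected.index = expected.index.map(str)
    scores = []
    for sample_id in obs_frame.index.map(str):
        if sample_id not in expected.index:
            raise GeodataError(
                f"no expected values for sample {sample_id!r}"
            )
        for index in indices:
            if index not in obs_frame.columns:
                raise GeodataError(f"observed table lacks index {index!r}")
            if index not in expected.columns:
                raise GeodataError(
                    f"expected table lacks index {index!r}"
                )
            o = float(obs_frame.loc[sample_id, index])
            e = float(expected.loc[sample_id, index])
            if math.isnan(e):
                raise GeodataError(
                    f"missing expected {index!r} for sample {sample_id!r}"
                )
            if e <= 0:
                raise GeodataError(
                    f"nonpositive expected {index!r} for sample "
                    f"{sample_id!r}: {e}"
                )
            if math.isnan(o):
                continue  # undefined observed index (e.g. Pielou at S=1)
            ratio = o / e
            capped = min(ratio, 1.0) if cap else ratio
            scores.append(
                OEScore(
                    sample_id=sample_id,
                    index=index,
                    observed=o,
                    expected=e,
                    ratio=ratio,
                    capped_ratio=capped,
                    below_threshold=ratio < threshold,
                )
            )
    return scores


def oe_frame(scores: Sequence[OEScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "index": [s.index for s in scores],
            "observed": [s.observed for s in scores],
            "expected": [s.expected for s in scores],
            "ratio": [s.ratio for s in scores],
            "capped_ratio": [s.capped_ratio for s in scores],
            "below_threshold": [s.below_threshold for s in scores],
        }
    )
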