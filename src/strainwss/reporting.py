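"""Turn WSS scores + cutoffs into strain calls and summary tables.

Sentinel strings follow the source tables: "CO:NA" = no cutoff assigned for
the species, "NS" = no score observed for the pair.  Calls in either
sentinel state are excluded from percentage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .wss import (
    LABEL_NO_SCORE,
    LABEL_NOT_CLASSIFIABLE,
    LABEL_RELATED,
    LABEL_UNRELATED,
    WSSResult,
    label_for,
)

SENTINEL_NO_CUTOFF = "CO:NA"
SENTINEL_NO_SCORE = "NS"

DEFAULT_GROUP_BY = ("dataset_id", "species_id", "comparison_label")


@dataclass
class StrainCall:
    sample_a: str
    sample_b: str
    species_id: str
    individual_id: str
    score: float | None
    cutoff: float | None
    windows_used: int
    windows_total: int
    label: str
    dataset_id: str = ""
    comparison_label: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


def classify(
    result: WSSResult,
    cutoff: float | None = None,
    dataset_id: str = "",
    comparison_label: str = "",
) -> StrainCall:
    """Label a scored pair: related iff score > cutoff, unrelated iff
    score <= cutoff; no cutoff -> not_classifiable; no score -> no_score.

    ``cutoff`` overrides the cutoff carried on the result when given.
    """
    effective = cutoff if cutoff is not None else result.cutoff
    return StrainCall(
        sample_a=result.sample_a,
        sample_b=result.sample_b,
        species_id=result.species_id,
        individual_id=result.individual_id,
        score=result.score,
        cutoff=effective,
        windows_used=result.windows_used,
        windows_total=result.windows_total,
        label=label_for(result.score, effective),
        dataset_id=dataset_id,
        comparison_label=comparison_label,
    )


def summarize(
    calls: Iterable[StrainCall],
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
) -> pd.DataFrame:
    """Per-group related/unrelated counts and percentages.

    not_classifiable / no_score calls are excluded from the percentage
    denominator but reported in ``n_excluded``.  Groups with no classifiable
    calls carry NaN percentages.
    """
    rows = [
        {key: getattr(c, key) for key in group_by} | {"label": c.label}
        for c in calls
    ]
    if not rows:
        cols = list(group_by) + [
            "n_related", "n_unrelated", "n_excluded", "pct_related", "pct_unrelated",
        ]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    grouped = df.groupby(list(group_by), sort=True)
    out = grouped["label"].agg(
        n_related=lambda s: int((s == LABEL_RELATED).sum()),
        n_unrelated=lambda s: int((s == LABEL_UNRELATED).sum()),
        n_excluded=lambda s: int(s.isin([LABEL_NOT_CLASSIFIABLE, LABEL_NO_SCORE]).sum()),
    ).reset_index()
    total = out["n_related"] + out["n_unrelated"]
    with np.errstate(invalid="ignore"):
        out["pct_related"] = np.where(
            total > 0, 100.0 * out["n_related"] / total.replace(0, np.nan), np.nan
        )
        out["pct_unrelated"] = np.where(
            total > 0, 100.0 * out["n_unrelated"] / total.replace(0, np.nan), np.nan
        )
    return out


def export_plot_table(calls: Iterable[StrainCall]) -> pd.DataFrame:
    """Long-format table behind the score scatter plots, one row per call,
    sorted by (species, individual).  Lossless: see import_plot_table."""
    rows = [
        {
            "individual": c.individual_id,
            "species": c.species_id,
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "score": SENTINEL_NO_SCORE if c.score is None else c.score,
            "cutoff": SENTINEL_NO_CUTOFF if c.cutoff is None else c.cutoff,
            "windows_used": c.windows_used,
            "windows_total": c.windows_total,
            "label": c.label,
            "dataset": c.dataset_id,
            "comparison": c.comparison_label,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "individual", "species", "sample_a", "sample_b", "score", "cutoff",
            "windows_used", "windows_total", "label", "dataset", "comparison",
        ],
    )
    return df.sort_values(["species", "individual", "sample_a", "sample_b"]).reset_index(
        drop=True
    )


def import_plot_table(table: pd.DataFrame) -> list[StrainCall]:
    """Inverse of export_plot_table (sentinels back to absent values)."""

    def num(value) -> float | None:
        if value in (SENTINEL_NO_SCORE, SENTINEL_NO_CUTOFF) or pd.isna(value):
            return None
        return float(value)

    return [
        StrainCall(
            sample_a=row.sample_a,
            sample_b=row.sample_b,
            species_id=row.species,
            individual_id=row.individual,
            score=num(row.score),
            cutoff=num(row.cutoff),
            windows_used=int(row.windows_used),
            windows_total=int(row.windows_total),
            label=row.label,
            dataset_id=row.dataset,
            comparison_label=row.comparison,
        )
        for row in table.itertuples(index=False)
    ]


def unrelated_count_matrix(calls: Iterable[StrainCall]) -> pd.DataFrame:
    """Dataset x species matrix counting individuals with >= 1 unrelated pair
    (an individual contributes at most once per dataset/species cell)."""
    calls = list(calls)
    datasets = sorted({c.dataset_id for c in calls})
    species = sorted({c.species_id for c in calls})
    matrix = pd.DataFrame(0, index=datasets, columns=species, dtype=int)
    seen: set[tuple[str, str, str]] = set()
    for c in calls:
        if c.label != LABEL_UNRELATED:
            continue
        key = (c.dataset_id, c.species_id, c.individual_id)
        if key in seen:
            continue
        seen.add(key)
        matrix.loc[c.dataset_id, c.species_id] += 1
    matrix.index.name = "dataset_id"
    matrix.columns.name = "species_id"
    return matrix
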