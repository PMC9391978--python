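"""Cross-corpus score differences and convergence/divergence classification.

For every concept scored in both corpora the score difference is
diff = FR - PR (forum relatedness minus literature relatedness). With µ and
σ the mean and population standard deviation of the diffs, a concept is

* ``forum_priority``  if diff > µ + 2σ
* ``pubmed_priority`` if diff < µ - 2σ
* ``similar``         otherwise (boundaries inclusive; all concepts when σ=0)

µ and σ are computed over the intersection of the two vocabularies: a
concept absent from one corpus has no score difference, so concepts unique
to one source are reported separately, uncategorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relatedness import RelatednessTable

__all__ = ["ComparisonTable", "score_differences", "classify_concepts"]

CATEGORY_SIMILAR = "similar"
CATEGORY_FORUM = "forum_priority"
CATEGORY_PUBMED = "pubmed_priority"


@dataclass
class ComparisonTable:
    """Per-concept FR, PR, diff and (after classification) category.

    ``df`` columns: concept_id, name, semantic_type, FR, PR, diff, category.
    ``mu``/``sigma`` are the mean and population standard deviation of diff;
    ``only_forum``/``only_pubmed`` list source-exclusive concept ids.
    """

    df: pd.DataFrame
    mu: float
    sigma: float
    condition_id: str
    only_forum: list[str]
    only_pubmed: list[str]
    ddof: int = 0

    @property
    def thresholds(self) -> tuple[float, float]:
        return self.mu - 2.0 * self.sigma, self.mu + 2.0 * self.sigma

    def category_counts(self) -> dict[str, int]:
        if self.df["category"].isna().any():
            raise ValueError("categories not set; run classify_concepts first")
        counts = self.df["category"].value_counts().to_dict()
        return {
            c: int(counts.get(c, 0))
            for c in (CATEGORY_SIMILAR, CATEGORY_FORUM, CATEGORY_PUBMED)
        }


def score_differences(
    rel_forum: RelatednessTable,
    rel_pubmed: RelatednessTable,
    restrict_to: set[str] | None = None,
    ddof: int = 0,
) -> ComparisonTable:
    """Join the two relatedness tables and compute per-concept FR - PR.

    Only concepts present in both tables get a row (``restrict_to``
    optionally narrows further, e.g. to the union of the two top-k
    selections); µ and σ (population by default, ``ddof=1`` for sample) are
    computed over those rows. The condition itself is excluded — its
    relatedness is 1 in both corpora by construction.
    """
    if rel_forum.condition_id != rel_pubmed.condition_id:
        raise ValueError(
            f"condition mismatch: {rel_forum.condition_id!r} vs {rel_pubmed.condition_id!r}"
        )
    cond = rel_forum.condition_id
    f = rel_forum.df.set_index("concept_id")
    p = rel_pubmed.df.set_index("concept_id")
    shared = f.index.intersection(p.index).difference([cond])
    if restrict_to is not None:
        shared = shared.intersection(sorted(restrict_to))
    shared = shared.sort_values()
    if len(shared) == 0:
        raise ValueError("no concepts shared between the two corpora")
    df = pd.DataFrame(
        {
            "concept_id": shared,
            "name": f.loc[shared, "name"].to_numpy(),
            "semantic_type": f.loc[shared, "semantic_type"].to_numpy(),
            "FR": f.loc[shared, "relatedness"].to_numpy(),
            "PR": p.loc[shared, "relatedness"].to_numpy(),
        }
    )
    df["diff"] = df["FR"] - df["PR"]
    df["category"] = pd.NA
    mu = float(df["diff"].mean())
    sigma = float(np.std(df["diff"].to_numpy(), ddof=ddof))
    return ComparisonTable(
        df=df.reset_index(drop=True),
        mu=mu,
        sigma=sigma,
        condition_id=cond,
        only_forum=sorted(f.index.difference(p.index).difference([cond])),
        only_pubmed=sorted(p.index.difference(f.index).difference([cond])),
        ddof=ddof,
    )


def classify_concepts(table: ComparisonTable) -> ComparisonTable:
    """Assign the µ ± 2σ category to every row (strict inequalities).

    Boundary values are ``similar``; σ = 0 makes every concept similar.
    Returns the same table with its category column filled.
    """
    lo, hi = table.thresholds
    diffs = table.df["diff"].to_numpy()
    cats = np.where(
        diffs > hi, CATEGORY_FORUM, np.where(diffs < lo, CATEGORY_PUBMED, CATEGORY_SIMILAR)
    )
    table.df["category"] = cats
    return table
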