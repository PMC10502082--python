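"""Region-transcript linking within +/-50 kb and chi-square cross-validation.

Each accessible region is paired with every gene whose transcription start
site lies within the window of the region summit (inclusive boundary); the
(region, gene) pairs - not regions or genes - are the analysis unit.
Independently derived region categories and transcript categories are then
cross-tabulated over the pairs and tested for association with a Pearson
chi-square test; cells with Pearson residual (O - E)/sqrt(E) above 4 are
reported as strong positive associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LINK_WINDOW", "RESIDUAL_THRESHOLD", "ContingencyResult", "link_regions_to_tss", "chisq_enrichment"]

LINK_WINDOW = 50_000
RESIDUAL_THRESHOLD = 4.0

#: category labels dropped before cross-tabulation
DEFAULT_DROP_LABELS = ("U", "none", "N/A")


def link_regions_to_tss(regions: pd.DataFrame, tss_table: pd.DataFrame, window: int = LINK_WINDOW) -> pd.DataFrame:
    """All (region, gene) pairs with |summit - TSS| <= window on one chromosome.

    ``regions`` needs columns region_id, chrom, summit; ``tss_table`` needs
    gene, chrom, tss.  Pairs are numbered in deterministic sort order
    (chrom, summit, gene).  Duplicate gene ids with conflicting TSS raise.
    """
    for col in ("region_id", "chrom", "summit"):
        if col not in regions.columns:
            raise ValueError(f"regions table lacks column {col!r}")
    for col in ("gene", "chrom", "tss"):
        if col not in tss_table.columns:
            raise ValueError(f"tss table lacks column {col!r}")
    dup = tss_table.groupby("gene")[["chrom", "tss"]].nunique()
    conflicted = dup.index[(dup["chrom"] > 1) | (dup["tss"] > 1)].tolist()
    if conflicted:
        raise ValueError(f"conflicting TSS annotations for genes {conflicted[:3]}")
    tss_table = tss_table.drop_duplicates(subset=["gene"])

    rows = []
    for chrom, genes in tss_table.groupby("chrom"):
        sub = regions[regions["chrom"] == chrom]
        if sub.empty:
            continue
        tss = genes["tss"].to_numpy(dtype=np.int64)
        names = genes["gene"].to_numpy()
        order = np.argsort(tss, kind="stable")
        tss, names = tss[order], names[order]
        for rec in sub.itertuples(index=False):
            s = int(rec.summit)
            lo = np.searchsorted(tss, s - window, side="left")
            hi = np.searchsorted(tss, s + window, side="right")
            for k in range(lo, hi):
                rows.append({"region_id": rec.region_id, "gene": names[k], "chrom": chrom, "distance": int(s - tss[k])})
    pairs = pd.DataFrame(rows, columns=["region_id", "gene", "chrom", "distance"])
    if pairs.empty:
        pairs["pair_id"] = pd.Series(dtype=int)
        return pairs
    pairs = pairs.sort_values(["chrom", "region_id", "gene"], kind="stable").reset_index(drop=True)
    pairs.insert(0, "pair_id", np.arange(1, len(pairs) + 1))
    return pairs


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame
    strong_positive: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed": {r: self.observed.loc[r].to_dict() for r in self.observed.index},
            "expected": {r: self.expected.loc[r].to_dict() for r in self.expected.index},
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
            "residuals": {r: self.residuals.loc[r].to_dict() for r in self.residuals.index},
            "strong_positive": [list(c) for c in self.strong_positive],
        }


def chisq_enrichment(
    pairs: pd.DataFrame,
    region_category: pd.Series,
    transcript_category: pd.Series,
    drop_labels=DEFAULT_DROP_LABELS,
    residual_threshold: float = RESIDUAL_THRESHOLD,
) -> ContingencyResult:
    """Pearson chi-square association between region and transcript classes.

    Categories are mapped onto the pairs; pairs whose label on either axis is
    missing or in ``drop_labels`` are excluded.  No continuity correction is
    applied for any table size.  An empty margin (any expected count of
    zero) raises, naming the margin.
    """
    df = pd.DataFrame(
        {
            "region_cat": region_category.reindex(pairs["region_id"]).to_numpy(),
            "transcript_cat": transcript_category.reindex(pairs["gene"]).to_numpy(),
        }
    ).dropna()
    df = df[~df["region_cat"].isin(drop_labels) & ~df["transcript_cat"].isin(drop_labels)]
    observed = pd.crosstab(df["region_cat"], df["transcript_cat"])
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need >= 2 categories on each axis after dropping excluded labels")
    O = observed.to_numpy(dtype=float)
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    total = O.sum()
    E = row @ col / total
    if np.any(E == 0):
        r_empty = observed.index[np.where(row.ravel() == 0)[0]].tolist()
        c_empty = observed.columns[np.where(col.ravel() == 0)[0]].tolist()
        raise ValueError(f"empty margin: rows {r_empty}, columns {c_empty}")
    resid = (O - E) / np.sqrt(E)
    chi2_stat = float(np.sum(resid**2))
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2_stat, dof))
    residuals = pd.DataFrame(resid, index=observed.index, columns=observed.columns)
    expected = pd.DataFrame(E, index=observed.index, columns=observed.columns)
    strong = [
        (str(r), str(c))
        for r in residuals.index
        for c in residuals.columns
        if residuals.loc[r, c] > residual_threshold
    ]
    return ContingencyResult(observed, expected, chi2_stat, dof, p, residuals, strong)
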