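"""Predicted-metagenome stage: copy-number-normalized projection of OTU
abundances onto gene families, pathway aggregation, taxon contribution
shares, and per-pathway group comparison.

The projection is the standard PICRUSt-style arithmetic: each OTU's read
count is divided by its 16S (SSU) copy number — converting reads to an
organism-abundance scale — and multiplied by its per-gene-family copy
numbers. OTUs absent from the copy-number reference are excluded, and the
excluded fraction of each sample's reads is reported; no nearest-neighbor
imputation of missing reference entries is attempted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import bh_adjust
from .io_tables import GeneCopyTable, OtuTable, SampleMetadata, TaxonomyMap

logger = logging.getLogger(__name__)

UNMAPPED_PATHWAY = "UNMAPPED"


@dataclass(frozen=True)
class FunctionProfile:
    """Predicted per-sample gene-family counts (non-negative reals), plus the
    per-sample fraction of reads belonging to reference-uncovered OTUs."""

    counts: pd.DataFrame  # samples x gene families
    uncovered_read_fraction: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_family_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PathwayProfile:
    counts: pd.DataFrame  # samples x pathways

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.counts.columns)


def predict_metagenome(table: OtuTable, reference: GeneCopyTable) -> FunctionProfile:
    """predicted(sample, family) = sum over covered OTUs of
    (count / ssu_copies) * gene_copy."""
    covered = [o for o in table.otu_ids if reference.covers(o)]
    uncovered = [o for o in table.otu_ids if not reference.covers(o)]
    sizes = table.library_sizes.astype(float)
    if uncovered:
        logger.warning(
            "%d OTU(s) absent from the copy-number reference are excluded "
            "from the predicted metagenome",
            len(uncovered),
        )
        excluded = table.counts[uncovered].sum(axis=1) / sizes.replace(0, np.nan)
        excluded = excluded.fillna(0.0)
    else:
        excluded = pd.Series(0.0, index=table.sample_ids)
    if not covered:
        raise ValueError("no OTU in the table is covered by the reference")
    organism = table.counts[covered].to_numpy(dtype=float) / reference.ssu_copies.loc[
        covered
    ].to_numpy()
    predicted = organism @ reference.gene_copies.loc[covered].to_numpy()
    frame = pd.DataFrame(
        predicted, index=table.sample_ids, columns=reference.gene_family_ids
    )
    zero_rows = frame.index[(frame.sum(axis=1) == 0)].tolist()
    if zero_rows:
        logger.warning("samples with empty predicted profiles: %s", zero_rows)
    return FunctionProfile(counts=frame, uncovered_read_fraction=excluded.rename("uncovered"))


def aggregate_pathways(
    profile: FunctionProfile, pathways: Mapping[str, Iterable[str]]
) -> PathwayProfile:
    """Sum gene families into pathways; a family mapping to several pathways
    counts once in each; families without a mapping land in ``UNMAPPED``."""
    columns: dict[str, np.ndarray] = {}
    values = profile.counts
    for family in profile.gene_family_ids:
        targets = set(pathways.get(family) or ()) or {UNMAPPED_PATHWAY}
        for pathway in targets:
            col = values[family].to_numpy(dtype=float)
            if pathway in columns:
                columns[pathway] = columns[pathway] + col
            else:
                columns[pathway] = col.copy()
    ordered = sorted(columns)
    frame = pd.DataFrame(
        {p: columns[p] for p in ordered}, index=profile.sample_ids
    )
    return PathwayProfile(counts=frame)


def taxon_contribution(
    table: OtuTable,
    reference: GeneCopyTable,
    taxonomy: TaxonomyMap,
    family_set: Sequence[str],
    rank: str = "genus",
    scope_samples: Sequence[str] | None = None,
) -> pd.Series | None:
    """Share of the predicted counts over ``family_set`` contributed by each
    taxon at ``rank``, aggregated over the scope samples.

    Shares sum to 1; returns ``None`` (flagged absent) when the total
    predicted count over the family set is zero.
    """
    family_set = list(family_set)
    if not family_set:
        raise ValueError("family_set must be non-empty")
    missing = [f for f in family_set if f not in reference.gene_family_ids]
    if missing:
        raise KeyError(f"gene families absent from the reference: {missing}")
    sub = table if scope_samples is None else table.subset_samples(list(scope_samples))
    covered = [o for o in sub.otu_ids if reference.covers(o)]
    organism = sub.counts[covered].sum(axis=0).to_numpy(dtype=float) / reference.ssu_copies.loc[
        covered
    ].to_numpy()
    per_otu = organism * reference.gene_copies.loc[covered, family_set].to_numpy().sum(axis=1)
    total = per_otu.sum()
    if total <= 0:
        logger.warning("zero predicted counts over the family set; shares undefined")
        return None
    labels = [
        taxonomy.at_rank(o, rank) if o in taxonomy else "unclassified" for o in covered
    ]
    shares = pd.Series(per_otu / total, index=labels).groupby(level=0).sum()
    return shares.sort_values(ascending=False)


def pathway_group_test(
    profile: PathwayProfile,
    metadata: SampleMetadata | pd.DataFrame,
    group_col: str = "Niche",
) -> pd.DataFrame:
    """One-way ANOVA across groups on per-sample-normalized pathway
    abundances, BH-adjusted across pathways.

    Normalization (cell / sample total) removes per-sample predicted-count
    scale before comparing group means.
    """
    frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    groups = frame.loc[profile.counts.index, group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError(f"pathway test needs >= 2 groups in {group_col!r}")
    totals = profile.counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero predicted totals: {bad}")
    rel = profile.counts.div(totals, axis=0)

    masks = [groups == lvl for lvl in levels]
    n = len(rel)
    df_between = len(levels) - 1
    df_within = n - len(levels)
    if df_within < 1:
        raise ValueError("not enough replication for the pathway ANOVA")
    records = []
    for pathway in rel.columns:
        y = rel[pathway].to_numpy(dtype=float)
        grand = y.mean()
        ss_between = sum(m.sum() * (y[m.to_numpy()].mean() - grand) ** 2 for m in masks)
        ss_within = sum(((y[m.to_numpy()] - y[m.to_numpy()].mean()) ** 2).sum() for m in masks)
        if ss_between <= 1e-15:
            f, p = 0.0, 1.0
        elif ss_within <= 1e-15:
            f, p = np.inf, 0.0
        else:
            f = (ss_between / df_between) / (ss_within / df_within)
            p = float(stats.f.sf(f, df_between, df_within))
        records.append({"pathway": pathway, "F": f, "p_value": p})
    result = pd.DataFrame.from_records(records).set_index("pathway")
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    return result.sort_values("F", ascending=False)
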