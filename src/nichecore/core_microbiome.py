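"""Core-microbiome computation: prevalence sweeps, the stabilization rule for
choosing the core threshold, thresholded core sets, niche set algebra, the
cross-species universal core, and rare-biosphere summaries.

The core microbiome of a scope (a host species crossed with a preparation
type, or all samples of a species) is the set of OTUs detected in at least a
threshold percentage of the scope's samples. Membership is evaluated in
integer arithmetic — an OTU detected in ``k`` of ``n`` samples is in the
``t``%-core iff ``100*k >= t*n`` — so boundary cases like 5/16 at 30% never
depend on floating-point rounding. Sweeping the threshold over a 2% grid and
finding the first grid point at which the core size stops changing, in every
preparation type simultaneously, yields the stabilization threshold used to
separate consistent associates from individual variability.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import OtuTable, TaxonomyMap, UNCLASSIFIED

logger = logging.getLogger(__name__)

#: Scope label used when a species' samples are pooled across preparations.
ALL_NICHES = "ALL"


# ---------------------------------------------------------------------------
# Prevalence and thresholded cores
# ---------------------------------------------------------------------------


def presence_counts(
    table: OtuTable, scope_samples: Sequence[str], min_count: int = 1
) -> pd.Series:
    """Number of scope samples in which each OTU reaches ``min_count`` reads."""
    scope = list(scope_samples)
    if not scope:
        raise ValueError("scope_samples must be non-empty")
    sub = table.subset_samples(scope)
    return sub.presence(min_count=min_count).sum(axis=0).astype(np.int64)


def prevalence(
    table: OtuTable, scope_samples: Sequence[str], min_count: int = 1
) -> pd.Series:
    """Fraction of scope samples in which each OTU is detected."""
    counts = presence_counts(table, scope_samples, min_count=min_count)
    return counts / len(list(scope_samples))


def core_members(presence: Mapping[str, int] | pd.Series, t_percent: int, n_samples: int) -> frozenset[str]:
    """Integer membership rule: OTU in core iff ``100*k >= t*n`` (inclusive)."""
    if not 0 <= t_percent <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {t_percent}")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    items = presence.items() if hasattr(presence, "items") else presence
    return frozenset(
        otu for otu, k in items if int(k) > 0 and 100 * int(k) >= t_percent * n_samples
    )


@dataclass(frozen=True)
class CoreSet:
    """OTUs detected in at least ``threshold_percent`` of the scope's samples."""

    scope: tuple[str, str]  # (species, niche or ALL)
    threshold_percent: int
    n_samples: int
    members: frozenset[str]
    prevalence: Mapping[str, float]  # over members

    def __len__(self) -> int:
        return len(self.members)


def core_at_threshold(
    table: OtuTable,
    scope_samples: Sequence[str],
    t_percent: int,
    scope: tuple[str, str] = ("", ALL_NICHES),
    min_count: int = 1,
) -> CoreSet:
    """Core set of one scope at one threshold, with member prevalences."""
    counts = presence_counts(table, scope_samples, min_count=min_count)
    n = len(list(scope_samples))
    members = core_members(counts, t_percent, n)
    prev = {otu: counts[otu] / n for otu in members}
    return CoreSet(
        scope=tuple(scope),
        threshold_percent=int(t_percent),
        n_samples=n,
        members=members,
        prevalence=prev,
    )


@dataclass(frozen=True)
class PrevalenceCurve:
    """Core size as a function of the prevalence threshold grid (percent)."""

    scope: tuple[str, str]
    thresholds: tuple[int, ...]
    core_size: tuple[int, ...]

    def __post_init__(self):
        if len(self.thresholds) != len(self.core_size):
            raise ValueError("thresholds and core_size must have equal length")
        if any(b > a for a, b in zip(self.core_size, self.core_size[1:])):
            raise ValueError("core_size must be non-increasing in the threshold")

    def size_at(self, t: int) -> int:
        return self.core_size[self.thresholds.index(t)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold_percent": self.thresholds, "core_size": self.core_size}
        )


def prevalence_sweep(
    table: OtuTable,
    scope_samples: Sequence[str],
    scope: tuple[str, str] = ("", ALL_NICHES),
    grid_step: int = 2,
    min_count: int = 1,
) -> PrevalenceCurve:
    """Core size at every threshold ``0, grid_step, ..., 100``."""
    if grid_step < 1 or 100 % grid_step != 0:
        raise ValueError(f"grid_step must divide 100, got {grid_step}")
    counts = presence_counts(table, scope_samples, min_count=min_count)
    n = len(list(scope_samples))
    k = counts.to_numpy()
    k = k[k > 0]
    thresholds = tuple(range(0, 101, grid_step))
    sizes = tuple(int(np.sum(100 * k >= t * n)) for t in thresholds)
    return PrevalenceCurve(scope=tuple(scope), thresholds=thresholds, core_size=sizes)


def stabilization_threshold(curves: Sequence[PrevalenceCurve]) -> int | None:
    """First grid point at which every curve's core size stops changing.

    Returns the minimum threshold ``t`` such that the net change
    ``core_size(t) - core_size(t - step)`` is zero in every supplied curve,
    considering only grid points after some curve has actually changed
    (leading flatness — thresholds too small to move the integer presence
    cutoff — does not count as stabilization). If no curve ever changes the
    core is stable from the first step; if the curves never jointly
    stabilize after changing, returns ``None`` with a warning.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("at least one curve is required")
    grid = curves[0].thresholds
    for curve in curves[1:]:
        if curve.thresholds != grid:
            raise ValueError(
                f"mismatched threshold grids: {grid} vs {curve.thresholds}"
            )
    changed = False
    for i in range(1, len(grid)):
        all_zero = all(c.core_size[i] == c.core_size[i - 1] for c in curves)
        if all_zero and changed:
            return grid[i]
        changed = changed or not all_zero
    if not changed:
        return grid[1] if len(grid) > 1 else None
    logger.warning("no stabilization point: curves never settle after changing")
    return None


def per_curve_stabilization(curves: Sequence[PrevalenceCurve]) -> dict[tuple[str, str], int | None]:
    """Diagnostic variant: the first zero-change step of each curve alone."""
    return {c.scope: stabilization_threshold([c]) for c in curves}


# ---------------------------------------------------------------------------
# Set algebra across niches and species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinedCore:
    """Union of a species' per-preparation cores, with per-OTU provenance.

    Combining per-niche cores recovers consistent associates that the pooled
    whole-community analysis under-samples (e.g. tissue-restricted taxa too
    rare to be detected in crushed whole-colony preparations).
    """

    species: str
    threshold_percent: int
    members: frozenset[str]
    provenance: Mapping[str, frozenset[str]]  # otu -> niches whose core holds it

    def exclusive_to(self, niche: str) -> frozenset[str]:
        return frozenset(o for o, ns in self.provenance.items() if ns == {niche})

    def __len__(self) -> int:
        return len(self.members)


def combine_cores(cores: Mapping[str, CoreSet]) -> CombinedCore:
    """Union per-niche cores of one species; keys are niche names."""
    if not cores:
        raise ValueError("at least one core set is required")
    thresholds = {c.threshold_percent for c in cores.values()}
    if len(thresholds) != 1:
        raise ValueError(f"mixed thresholds in combine_cores: {sorted(thresholds)}")
    species = {c.scope[0] for c in cores.values()}
    if len(species) != 1:
        raise ValueError(f"mixed species in combine_cores: {sorted(species)}")
    provenance: dict[str, set[str]] = {}
    for niche, core in cores.items():
        for otu in core.members:
            provenance.setdefault(otu, set()).add(niche)
    return CombinedCore(
        species=species.pop(),
        threshold_percent=thresholds.pop(),
        members=frozenset(provenance),
        provenance={o: frozenset(ns) for o, ns in provenance.items()},
    )


@dataclass(frozen=True)
class VennSummary:
    """Region counts for three sets: exclusives, pairwise-only overlaps, and
    the triple intersection, plus each set's total."""

    labels: tuple[str, str, str]
    region_counts: Mapping[frozenset[str], int]
    totals: Mapping[str, int]

    @property
    def triple(self) -> int:
        return self.region_counts[frozenset(self.labels)]

    def exclusive(self, label: str) -> int:
        return self.region_counts[frozenset({label})]

    def pairwise_only(self, a: str, b: str) -> int:
        return self.region_counts[frozenset({a, b})]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "regions": {
                "+".join(sorted(k)): v for k, v in self.region_counts.items()
            },
            "totals": dict(self.totals),
        }


def venn(sets: Mapping[str, Iterable[str]]) -> VennSummary:
    """Three-set Venn region counts (exact, by membership enumeration)."""
    if len(sets) != 3:
        raise ValueError(f"venn expects exactly three sets, got {len(sets)}")
    labels = tuple(sets)
    as_sets = {k: frozenset(v) for k, v in sets.items()}
    regions: dict[frozenset[str], int] = {}
    for mask in range(1, 8):
        inside = frozenset(l for i, l in enumerate(labels) if mask >> i & 1)
        region = frozenset.intersection(*(as_sets[l] for l in inside))
        for l in set(labels) - inside:
            region -= as_sets[l]
        regions[inside] = len(region)
    return VennSummary(
        labels=labels,
        region_counts=regions,
        totals={l: len(as_sets[l]) for l in labels},
    )


def venn_of_cores(cores: Mapping[str, CoreSet | CombinedCore]) -> VennSummary:
    return venn({label: core.members for label, core in cores.items()})


def universal_core(
    combined_cores: Mapping[str, CombinedCore],
    taxonomies: Mapping[str, TaxonomyMap],
    match_rank: str = "genus",
) -> frozenset[str]:
    """Taxon labels shared by the combined cores of every species.

    OTU ids are never compared across species (independent runs share no id
    space); matching happens at ``match_rank``, excluding unclassified labels.
    Core members without a taxonomy record are skipped with a warning.
    """
    if len(combined_cores) < 2:
        raise ValueError("universal core needs at least two species")
    per_species: list[frozenset[str]] = []
    for species, combined in combined_cores.items():
        taxonomy = taxonomies[species]
        labels: set[str] = set()
        for otu in combined.members:
            if otu not in taxonomy:
                logger.warning(
                    "core member %s of %s has no taxonomy record; skipped", otu, species
                )
                continue
            label = taxonomy.at_rank(otu, match_rank)
            if label != UNCLASSIFIED:
                labels.add(label)
        per_species.append(frozenset(labels))
    return frozenset.intersection(*per_species)


# ---------------------------------------------------------------------------
# Rare-biosphere summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RareCoreSummary:
    """Core members banded by their mean whole-community relative abundance."""

    cutoffs: tuple[float, ...]
    band_labels: tuple[str, ...]
    band_counts: tuple[int, ...]
    member_abundance: Mapping[str, float]

    @property
    def n_members(self) -> int:
        return sum(self.band_counts)

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "bands": dict(zip(self.band_labels, self.band_counts)),
        }


def rare_core_summary(
    members: Iterable[str],
    table: OtuTable,
    whole_community_samples: Sequence[str],
    cutoffs: Sequence[float] = (0.01, 0.05),
) -> RareCoreSummary:
    """Band each core member by its mean relative abundance across the
    whole-community samples.

    Core membership is decided by prevalence, not abundance; this summary
    quantifies how much of the core sits in the rare biosphere (members below
    1% mean relative abundance, by default). Members absent from the table
    fall into the lowest band with a warning.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(not 0 < c < 1 for c in cutoffs) or list(cutoffs) != sorted(set(cutoffs)):
        raise ValueError(f"cutoffs must be strictly ascending within (0, 1): {cutoffs}")
    members = sorted(set(members))
    if not members:
        raise ValueError("no core members to summarize")
    relab = table.subset_samples(list(whole_community_samples)).relative_abundance()
    mean_relab = relab.mean(axis=0)
    edges = (0.0, *cutoffs, 1.0)
    labels = [f"<{cutoffs[0]:g}"]
    labels += [f"[{lo:g},{hi:g})" for lo, hi in zip(cutoffs, cutoffs[1:])]
    labels.append(f">={cutoffs[-1]:g}")
    counts = [0] * len(labels)
    abundance: dict[str, float] = {}
    for otu in members:
        if otu not in mean_relab.index:
            logger.warning(
                "core member %s absent from the whole-community table; "
                "counted in the lowest abundance band",
                otu,
            )
            abundance[otu] = 0.0
            counts[0] += 1
            continue
        value = float(mean_relab[otu])
        abundance[otu] = value
        band = int(np.searchsorted(np.asarray(cutoffs), value, side="right"))
        counts[band] += 1
    return RareCoreSummary(
        cutoffs=cutoffs,
        band_labels=tuple(labels),
        band_counts=tuple(counts),
        member_abundance=abundance,
    )
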