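"""Synthetic multi-species, multi-niche coral microbial communities with
planted ground truth.

The generator emulates the structure of a mesophotic-coral amplicon study:
three host species, each sampled in three micro-habitat preparations (the
crushed whole-colony "holobiont" community, dissected polyp "tissue", and
either laser-microdissected "endosymbiotic" cell clusters or washed
"skeletal" material), with each species' community dominated by a long rare
tail plus a small planted core and two universal symbiont phylotypes that
are strongly enriched in the endosymbiotic niche but rare in the whole
community.

Per sample, generation proceeds in three stages:

1. presence — planted core OTUs are present with probability
   ``core_prevalence`` inside their scoped niche(s); every other OTU carries
   a per-OTU presence probability drawn once from ``(0, noise_prevalence_max]``;
2. relative abundance — planted symbionts take their fixed niche means; the
   remaining mass is split among the other present OTUs by renormalized
   log-normal(0, sigma^2) draws (a heavy-tailed rare biosphere);
3. counts — one multinomial draw of ``library_size`` reads.

After the multinomial draw, a planted core or symbiont OTU that was present
but received zero reads is given a single read taken from the sample's
largest count, so planted membership is exactly recoverable from counts
while library sizes are preserved. Background OTUs may still drop out, as in
real shallow sequencing; :class:`GroundTruth` therefore records both the
Bernoulli presence draws and the per-OTU probabilities.

OTU identifier spaces are disjoint across species; the planted symbionts
share genus labels (and full lineages) across species, mirroring how real
universal taxa can only be matched taxonomically.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import NICHES, OtuTable, SampleMetadata, TaxonomyMap, GeneCopyTable

__all__ = [
    "PlantedSymbiont",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_community",
    "generate_gene_reference",
]


_SYMBIONT_LINEAGES = {
    "Propionibacterium": (
        "Bacteria",
        "Actinobacteria",
        "Actinobacteria",
        "Actinomycetales",
        "Propionibacteriaceae",
        "Propionibacterium",
    ),
    "Ralstonia": (
        "Bacteria",
        "Proteobacteria",
        "Betaproteobacteria",
        "Burkholderiales",
        "Burkholderiaceae",
        "Ralstonia",
    ),
}


@dataclass(frozen=True)
class PlantedSymbiont:
    """A universal symbiont phylotype with fixed per-niche mean relative
    abundances (fractions of the sample's reads)."""

    genus: str
    niche_mean_relab: Mapping[str, float]

    def mean_in(self, niche: str) -> float:
        return float(self.niche_mean_relab.get(niche, 0.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design and effect parameters for one synthetic run.

    ``samples_per_niche`` may be a single int (every species) or one int per
    species. ``core_scope_all_fraction`` controls how many planted core OTUs
    are core in every niche of their species versus in a single niche only
    (the latter creates the niche-exclusive Venn regions seen in real data).
    """

    species_names: tuple[str, ...] = ("A_granulosa", "M_capitata", "Leptoseris_spp")
    niches_per_species: tuple[tuple[str, ...], ...] = (
        ("holobiont", "tissue", "endosymbiotic"),
        ("holobiont", "tissue", "skeletal"),
        ("holobiont", "tissue", "skeletal"),
    )
    samples_per_niche: int | tuple[int, ...] = (11, 6, 10)
    n_otus: int = 1450
    n_core: int = 60
    core_prevalence: float = 0.9
    noise_prevalence_max: float = 0.28
    core_scope_all_fraction: float = 0.25
    planted_symbionts: tuple[PlantedSymbiont, ...] = (
        PlantedSymbiont(
            "Propionibacterium",
            {"endosymbiotic": 0.42, "tissue": 0.10, "holobiont": 0.003, "skeletal": 0.01},
        ),
        PlantedSymbiont(
            "Ralstonia",
            {"endosymbiotic": 0.22, "tissue": 0.08, "holobiont": 0.04, "skeletal": 0.02},
        ),
    )
    lognormal_sigma: float = 2.0
    library_size: int = 10_000
    seed: int = 0
    depths_per_species: tuple[tuple[float, ...], ...] = ((5.0, 20.0, 40.0), (56.0,), (65.0, 100.0, 125.0))
    sites_per_species: tuple[tuple[str, ...], ...] = (
        ("Mantis", "Lagoon", "Tydeman", "Yonge", "Ribbon5"),
        ("WestMaui",),
        ("Olowalu1", "Olowalu2", "Olowalu3"),
    )
    n_gene_families: int = 24
    n_transport_families: int = 3
    symbiont_transport_share: float = 0.70

    # -- derived helpers ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def samples_for(self, species_index: int) -> int:
        if isinstance(self.samples_per_niche, int):
            return self.samples_per_niche
        return int(self.samples_per_niche[species_index])

    def validate(self) -> None:
        if self.n_species < 1 or len(self.niches_per_species) != self.n_species:
            raise ValueError("need one niche list per species")
        for niches in self.niches_per_species:
            unknown = set(niches) - set(NICHES)
            if unknown:
                raise ValueError(f"unknown niches {sorted(unknown)}; expected {NICHES}")
            if len(set(niches)) != len(niches) or not niches:
                raise ValueError("each species needs a non-empty set of distinct niches")
        for si in range(self.n_species):
            if self.samples_for(si) < 1:
                raise ValueError("samples_per_niche must be >= 1")
        if self.library_size < 1:
            raise ValueError("library_size must be a positive integer")
        if self.n_otus < self.n_core + len(self.planted_symbionts):
            raise ValueError("n_otus must cover planted core OTUs and symbionts")
        if not 0 < self.core_prevalence <= 1:
            raise ValueError("core_prevalence must lie in (0, 1]")
        if not 0 < self.noise_prevalence_max < self.core_prevalence:
            raise ValueError("need 0 < noise_prevalence_max < core_prevalence")
        if not 0 <= self.core_scope_all_fraction <= 1:
            raise ValueError("core_scope_all_fraction must lie in [0, 1]")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        if not 0 < self.symbiont_transport_share < 1:
            raise ValueError("symbiont_transport_share must lie in (0, 1)")
        if self.n_gene_families < self.n_transport_families + 1:
            raise ValueError("need more gene families than transport families")
        for niches in self.niches_per_species:
            for niche in niches:
                total = sum(s.mean_in(niche) for s in self.planted_symbionts)
                if total >= 1:
                    raise ValueError(
                        f"symbiont mean relative abundances sum to {total} >= 1 "
                        f"in niche {niche!r}"
                    )


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The study-shaped default design (three species, ~1450 OTUs each)."""
    spec = replace(SyntheticSpec(), seed=seed, **overrides)
    spec.validate()
    return spec


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure and realized presence, the acceptance surface of the
    generator.

    ``presence`` holds the Bernoulli presence draws (samples x OTUs); an OTU
    may be present yet unobserved in the counts if the multinomial assigned
    it zero reads (background OTUs only — planted core/symbiont OTUs are
    protected). ``mean_relab`` is the model-implied expected relative
    abundance per niche (exact for symbionts, a concentration approximation
    for the log-normal tail).
    """

    planted_core: Mapping[tuple[str, str], frozenset[str]]
    planted_symbionts: Mapping[str, Mapping[str, str]]  # species -> genus -> otu
    presence_prob: pd.DataFrame  # otu x niche
    mean_relab: pd.DataFrame  # otu x niche
    presence: pd.DataFrame  # samples x otus, bool

    def symbiont_ids(self, species: str) -> frozenset[str]:
        return frozenset(self.planted_symbionts[species].values())

    def core_and_symbionts(self, species: str, niche: str) -> frozenset[str]:
        return self.planted_core[(species, niche)] | self.symbiont_ids(species)


# ---------------------------------------------------------------------------
# Deterministic per-species model (shared by community and gene reference)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SpeciesModel:
    name: str
    niches: tuple[str, ...]
    otu_ids: tuple[str, ...]
    symbiont_ids: tuple[str, ...]  # aligned with spec.planted_symbionts
    core_ids: tuple[str, ...]
    core_scope: Mapping[str, tuple[str, ...]]  # core otu -> niches where core
    background_prob: pd.Series  # per-OTU background presence probability
    presence_prob: pd.DataFrame  # otu x niche
    lineages: Mapping[str, tuple[str, ...]]


_PHYLA = (
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Endozoicomonadaceae"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae"),
    ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae"),
    ("Cyanobacteria", "Synechococcophycideae", "Synechococcales", "Synechococcaceae"),
)


def _species_model(spec: SyntheticSpec, si: int) -> _SpeciesModel:
    rng = np.random.default_rng([spec.seed, 10 + si])
    name = spec.species_names[si]
    niches = tuple(spec.niches_per_species[si])
    prefix = name.replace(" ", "_")
    otu_ids = tuple(f"{prefix}_OTU{i:04d}" for i in range(spec.n_otus))
    n_sym = len(spec.planted_symbionts)
    symbiont_ids = otu_ids[:n_sym]
    core_ids = otu_ids[n_sym : n_sym + spec.n_core]

    # Background presence probabilities in (0, noise_prevalence_max].
    u = rng.random(spec.n_otus)
    background = pd.Series((1.0 - u) * spec.noise_prevalence_max, index=list(otu_ids))

    n_all = int(round(spec.n_core * spec.core_scope_all_fraction))
    core_scope: dict[str, tuple[str, ...]] = {}
    for j, otu in enumerate(core_ids):
        if j < n_all:
            core_scope[otu] = niches
        else:
            core_scope[otu] = (niches[(j - n_all) % len(niches)],)

    prob = pd.DataFrame(
        {niche: background.to_numpy().copy() for niche in niches}, index=list(otu_ids)
    )
    for otu, scoped in core_scope.items():
        for niche in scoped:
            prob.loc[otu, niche] = spec.core_prevalence
    # Planted universal symbionts are ubiquitous: present in every sample,
    # so their observed niche-mean relative abundances equal the spec means.
    for otu in symbiont_ids:
        prob.loc[otu, list(niches)] = 1.0

    lineages: dict[str, tuple[str, ...]] = {}
    genus_pool = [f"{prefix}_g{m:03d}" for m in range(40)]
    for i, otu in enumerate(otu_ids):
        if i < n_sym:
            genus = spec.planted_symbionts[i].genus
            base = _SYMBIONT_LINEAGES.get(
                genus,
                ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "unclassified", genus),
            )
            lineages[otu] = tuple(base) + ("unclassified",)
        else:
            phylum, klass, order, family = _PHYLA[i % len(_PHYLA)]
            genus = genus_pool[i % len(genus_pool)]
            lineages[otu] = ("Bacteria", phylum, klass, order, family, genus, "unclassified")

    return _SpeciesModel(
        name=name,
        niches=niches,
        otu_ids=otu_ids,
        symbiont_ids=symbiont_ids,
        core_ids=core_ids,
        core_scope=core_scope,
        background_prob=background,
        presence_prob=prob,
        lineages=lineages,
    )


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------


def generate_community(
    spec: SyntheticSpec,
) -> tuple[OtuTable, TaxonomyMap, SampleMetadata, GroundTruth]:
    """Draw the full multi-species community; deterministic for a fixed seed."""
    spec.validate()
    models = [_species_model(spec, si) for si in range(spec.n_species)]

    all_otus: list[str] = []
    lineages: dict[str, tuple[str, ...]] = {}
    for model in models:
        all_otus.extend(model.otu_ids)
        lineages.update(model.lineages)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_blocks: list[np.ndarray] = []
    presence_blocks: list[np.ndarray] = []
    block_otus: list[tuple[str, ...]] = []

    planted_core: dict[tuple[str, str], frozenset[str]] = {}
    planted_symbionts: dict[str, dict[str, str]] = {}
    prob_frames: list[pd.DataFrame] = []
    mean_frames: list[pd.DataFrame] = []

    for si, model in enumerate(models):
        rng = np.random.default_rng([spec.seed, 100 + si])
        n_per = spec.samples_for(si)
        n_otus = len(model.otu_ids)
        sym_index = np.arange(len(model.symbiont_ids))
        otu_pos = {o: k for k, o in enumerate(model.otu_ids)}
        depths = spec.depths_per_species[si % len(spec.depths_per_species)]
        sites = spec.sites_per_species[si % len(spec.sites_per_species)]

        planted_symbionts[model.name] = {
            s.genus: otu for s, otu in zip(spec.planted_symbionts, model.symbiont_ids)
        }
        for niche in model.niches:
            scoped = frozenset(
                otu for otu, ns in model.core_scope.items() if niche in ns
            )
            planted_core[(model.name, niche)] = scoped

        counts_rows: list[np.ndarray] = []
        presence_rows: list[np.ndarray] = []
        prob = model.presence_prob.to_numpy()
        sym_means_by_niche = {
            niche: np.array([s.mean_in(niche) for s in spec.planted_symbionts])
            for niche in model.niches
        }
        protected_by_niche = {
            niche: np.array(
                sorted(
                    otu_pos[o]
                    for o in set(model.symbiont_ids) | planted_core[(model.name, niche)]
                ),
                dtype=np.int64,
            )
            for niche in model.niches
        }

        for hi, niche in enumerate(model.niches):
            sym_means = sym_means_by_niche[niche]
            protected = protected_by_niche[niche]
            for k in range(n_per):
                present = rng.random(n_otus) < prob[:, hi]
                if not present.any():
                    present[int(np.argmax(prob[:, hi]))] = True
                shares = np.zeros(n_otus)
                sym_present = present[sym_index]
                shares[sym_index[sym_present]] = sym_means[sym_present]
                remaining = 1.0 - shares.sum()
                others = present.copy()
                others[sym_index] = False
                n_others = int(others.sum())
                if n_others > 0 and remaining > 0:
                    w = rng.lognormal(0.0, spec.lognormal_sigma, size=n_others)
                    shares[others] = remaining * w / w.sum()
                elif shares.sum() > 0:
                    shares /= shares.sum()
                counts = rng.multinomial(spec.library_size, shares)
                # Protect planted membership: a present core/symbiont OTU with
                # zero reads receives one read from the largest cell.
                starved = protected[present[protected] & (counts[protected] == 0)]
                for idx in starved:
                    donor = int(np.argmax(counts))
                    counts[donor] -= 1
                    counts[idx] = 1
                counts_rows.append(counts)
                presence_rows.append(present)
                sample_id = f"{model.name}.{niche}.{k:02d}"
                sample_ids.append(sample_id)
                meta_rows.append(
                    {
                        "SampleID": sample_id,
                        "Species": model.name,
                        "Niche": niche,
                        "Depth": float(depths[k % len(depths)]),
                        "Site": sites[k % len(sites)],
                    }
                )
        count_blocks.append(np.vstack(counts_rows))
        presence_blocks.append(np.vstack(presence_rows))
        block_otus.append(model.otu_ids)

        prob_frames.append(model.presence_prob)
        mean = _expected_relab(spec, model)
        mean_frames.append(mean)

    # Assemble the combined table: block-diagonal across species.
    n_samples = len(sample_ids)
    counts = np.zeros((n_samples, len(all_otus)), dtype=np.int64)
    presence = np.zeros((n_samples, len(all_otus)), dtype=bool)
    row0 = 0
    col0 = 0
    for block, pres, otus in zip(count_blocks, presence_blocks, block_otus):
        r, c = block.shape
        counts[row0 : row0 + r, col0 : col0 + c] = block
        presence[row0 : row0 + r, col0 : col0 + c] = pres
        row0 += r
        col0 += c

    table = OtuTable.from_arrays(counts, sample_ids, all_otus)
    taxonomy = TaxonomyMap(lineages)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("SampleID")[["Species", "Niche", "Depth", "Site"]]
    )
    truth = GroundTruth(
        planted_core=planted_core,
        planted_symbionts={s: dict(g) for s, g in planted_symbionts.items()},
        presence_prob=pd.concat(prob_frames),
        mean_relab=pd.concat(mean_frames),
        presence=pd.DataFrame(presence, index=sample_ids, columns=all_otus),
    )
    return table, taxonomy, metadata, truth


def _expected_relab(spec: SyntheticSpec, model: _SpeciesModel) -> pd.DataFrame:
    """Model-implied expected relative abundance per (OTU, niche).

    Exact for symbionts; for the log-normal tail the remaining mass is
    spread proportionally to presence probability (E[1/K] approximated by
    1/E[K], accurate because hundreds of OTUs are present per sample).
    """
    out = pd.DataFrame(0.0, index=list(model.otu_ids), columns=list(model.niches))
    prob = model.presence_prob
    n_sym = len(model.symbiont_ids)
    for niche in model.niches:
        sym_means = np.array([s.mean_in(niche) for s in spec.planted_symbionts])
        sym_mass = float((sym_means * spec.core_prevalence).sum())
        out.loc[list(model.symbiont_ids), niche] = sym_means * spec.core_prevalence
        p_others = prob[niche].to_numpy()[n_sym:]
        expected_k = p_others.sum()
        if expected_k > 0:
            out.loc[list(model.otu_ids[n_sym:]), niche] = (
                p_others * (1.0 - sym_mass) / expected_k
            )
    return out


# ---------------------------------------------------------------------------
# Gene copy-number reference
# ---------------------------------------------------------------------------


def transport_family_ids(spec: SyntheticSpec) -> list[str]:
    return [f"F{j:03d}" for j in range(spec.n_transport_families)]


def generate_gene_reference(spec: SyntheticSpec) -> GeneCopyTable:
    """Per-OTU SSU copy numbers and sparse gene-family copy vectors.

    The planted symbionts receive transporter-family copy numbers calibrated
    (by a short Monte-Carlo pass over the generative model, independent of
    the data draw) so that their expected contribution share over the
    transport families equals ``spec.symbiont_transport_share`` in the
    endosymbiotic niche.
    """
    spec.validate()
    models = [_species_model(spec, si) for si in range(spec.n_species)]
    rng = np.random.default_rng([spec.seed, 2])

    all_otus: list[str] = []
    for model in models:
        all_otus.extend(model.otu_ids)
    n_total = len(all_otus)

    families = [f"F{j:03d}" for j in range(spec.n_gene_families)]
    transport = families[: spec.n_transport_families]

    ssu = pd.Series(rng.integers(1, 11, size=n_total).astype(float), index=all_otus)
    for model in models:
        # fixed rRNA operon count for the planted symbionts (typical for
        # Actinobacteria / Burkholderiales genomes), so the symbiont
        # organism-abundance scale does not vary across runs
        ssu.loc[list(model.symbiont_ids)] = 3.0
    copies = (
        (rng.random((n_total, spec.n_gene_families)) < 0.3)
        * rng.integers(1, 5, size=(n_total, spec.n_gene_families))
    ).astype(float)
    gene_copies = pd.DataFrame(copies, index=all_otus, columns=families)

    # Planted symbionts are transport specialists: a fixed transport-dominant
    # profile (6 copies per transport family, 2 per housekeeping family).
    # The background transport copies are then rescaled so the symbionts'
    # expected contribution share over the transport families equals the
    # target in the endosymbiotic niche.
    housekeeping = families[
        spec.n_transport_families : min(2 * spec.n_transport_families, len(families) - 1)
    ]
    symbiont_rows: list[str] = []
    for model in models:
        symbiont_rows.extend(model.symbiont_ids)
    gene_copies.loc[symbiont_rows, :] = 0.0
    gene_copies.loc[symbiont_rows, housekeeping] = 2.0
    gene_copies.loc[symbiont_rows, transport] = 6.0
    scale = _calibrate_background_transport(spec, models, ssu, gene_copies, transport)
    background_rows = [o for o in all_otus if o not in set(symbiont_rows)]
    gene_copies.loc[background_rows, transport] *= scale

    pathways: dict[str, frozenset[str]] = {}
    other_pathways = (
        "Amino acid metabolism",
        "Energy metabolism",
        "DNA repair",
        "Secretion system",
    )
    for fam in transport:
        pathways[fam] = frozenset({"Transporters", "ABC transporters"})
    mapped_others = families[spec.n_transport_families : -1]  # last family unmapped
    for j, fam in enumerate(mapped_others):
        pathways[fam] = frozenset({other_pathways[j % len(other_pathways)]})

    return GeneCopyTable(ssu_copies=ssu, gene_copies=gene_copies, pathways=pathways)


def _calibrate_background_transport(
    spec: SyntheticSpec,
    models: Sequence[_SpeciesModel],
    ssu: pd.Series,
    gene_copies: pd.DataFrame,
    transport: Sequence[str],
    n_reps: int = 1024,
) -> float:
    """Scale factor for background transport copies solving
    share = L_sym / (L_sym + scale * L_bg) = target for the calibration
    niche, with L_bg estimated by Monte Carlo over the generative model
    (a stream independent of the data draw)."""
    target = spec.symbiont_transport_share
    # Calibrate in the endosymbiotic niche of the first species that has one.
    si, niche = 0, None
    for i, model in enumerate(models):
        if "endosymbiotic" in model.niches:
            si, niche = i, "endosymbiotic"
            break
    model = models[si]
    if niche is None:
        niche = model.niches[0]

    rng = np.random.default_rng([spec.seed, 3])
    n_sym = len(model.symbiont_ids)
    prob = model.presence_prob[niche].to_numpy()
    sym_means = np.array([s.mean_in(niche) for s in spec.planted_symbionts])
    sym_ssu = ssu.loc[list(model.symbiont_ids)].to_numpy()
    bg_ids = list(model.otu_ids[n_sym:])
    bg_prob = prob[n_sym:]
    bg_load_per_otu = gene_copies.loc[bg_ids, list(transport)].to_numpy().sum(axis=1) / ssu.loc[
        bg_ids
    ].to_numpy()

    bg_total = 0.0
    remaining = 1.0 - sym_means.sum()  # symbionts are present in every sample
    for _ in range(n_reps):
        present = rng.random(len(bg_ids)) < bg_prob
        k = int(present.sum())
        if k > 0 and remaining > 0:
            w = rng.lognormal(0.0, spec.lognormal_sigma, size=k)
            shares = remaining * w / w.sum()
            bg_total += float((shares * bg_load_per_otu[present]).sum())
    l_bg = bg_total / n_reps
    l_sym = float(
        (
            (sym_means / sym_ssu)[:, None]
            * gene_copies.loc[list(model.symbiont_ids), list(transport)].to_numpy()
        ).sum()
    )
    if l_sym <= 0:
        raise ValueError("symbionts carry no mass in the calibration niche")
    if l_bg <= 0:
        return 1.0  # no background transport: the share is 1 regardless
    return l_sym * (1.0 - target) / (target * l_bg)
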