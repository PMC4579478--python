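"""End-to-end orchestration: simulate or load tables, sweep prevalence
thresholds, build and combine cores, Venn and universal-core summaries,
community statistics, differential abundance, functional prediction, and a
single deterministic JSON run report.

Every stage is rerunnable from its on-disk inputs; all randomness funnels
through the run seed (sub-stage seeds are derived deterministically), and a
rerun with the same config and seed produces byte-identical outputs. The
report carries headline numbers and warnings; timings go to the log only, so
the report stays reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_stats as cs
from . import core_microbiome as core
from . import function_predict as fp
from . import io_tables as io
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable; flags override)."""

    outdir: Path
    synthetic: synth.SyntheticSpec | None = None
    otu_table: Path | None = None
    taxonomy: Path | None = None
    metadata: Path | None = None
    gene_reference: Path | None = None
    pathway_map: Path | None = None
    grid_step: int = 2
    levels: tuple[int, ...] = (30, 50, 75, 90)
    core_level: int = 30
    match_rank: str = "genus"
    n_perm: int = 999
    seed: int | None = None
    min_count: int = 1
    contribution_pathway: str = "Transporters"

    def validate(self) -> None:
        if self.synthetic is None and (self.otu_table is None or self.metadata is None):
            raise ValueError("need either a synthetic spec or otu_table + metadata paths")
        if self.grid_step < 1 or 100 % self.grid_step != 0:
            raise ValueError(f"grid_step must divide 100, got {self.grid_step}")
        for level in (*self.levels, self.core_level):
            if not (isinstance(level, int) and 0 <= level <= 100):
                raise ValueError(f"core annotation level out of range [0, 100]: {level}")
        if self.match_rank not in io.RANKS:
            raise ValueError(f"match_rank must be one of {io.RANKS}")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.seed is None and (self.n_perm > 0 or self.synthetic is not None):
            raise ValueError("a seed is required when stochastic stages run")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        spec = raw.pop("synthetic", None)
        if isinstance(spec, Mapping):
            spec = spec_from_mapping(spec)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outdir", "otu_table", "taxonomy", "metadata", "gene_reference", "pathway_map"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "levels" in raw and raw["levels"] is not None:
            raw["levels"] = tuple(int(v) for v in raw["levels"])
        return cls(synthetic=spec, **raw)


def spec_from_mapping(raw: Mapping) -> synth.SyntheticSpec:
    """Build a SyntheticSpec from plain YAML structures."""
    raw = dict(raw)
    symbionts = raw.pop("planted_symbionts", None)
    spec = synth.SyntheticSpec(**_tupled(raw))
    if symbionts is not None:
        spec = dataclasses.replace(
            spec,
            planted_symbionts=tuple(
                synth.PlantedSymbiont(s["genus"], dict(s["niche_mean_relab"]))
                for s in symbionts
            ),
        )
    spec.validate()
    return spec


def _tupled(raw: Mapping) -> dict:
    out = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        out[key] = value
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(str(x) for x in items)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "MANIFEST"
    completed: list[str] = []
    report: dict = {"stages": {}, "warnings": [], "outputs": {}}
    report["config"] = _jsonable(
        {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "synthetic"
            },
            "synthetic": dataclasses.asdict(config.synthetic)
            if config.synthetic is not None
            else None,
        }
    )

    def record_output(name: str, path: Path):
        report["outputs"][name] = str(path)

    def finish_stage(name: str):
        completed.append(name)
        manifest.write_text("".join(f"{s}\n" for s in completed))

    current_stage = "setup"
    try:
        # -- inputs ---------------------------------------------------------
        current_stage = "inputs"
        if config.synthetic is not None:
            spec = config.synthetic
            if config.seed is not None:
                spec = dataclasses.replace(spec, seed=int(config.seed))
            table, taxonomy, metadata, truth = synth.generate_community(spec)
            reference = synth.generate_gene_reference(spec)
            io.write_otu_table(table, outdir / "otu_table.tsv")
            io.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
            io.write_sample_metadata(metadata, outdir / "metadata.tsv")
            io.write_gene_reference(
                reference, outdir / "gene_reference.tsv", outdir / "pathway_map.tsv"
            )
            for name in ("otu_table", "taxonomy", "metadata", "gene_reference", "pathway_map"):
                record_output(name, outdir / f"{name}.tsv")
            report["stages"]["inputs"] = {
                "source": "synthetic",
                "seed": spec.seed,
                "n_samples": table.n_samples,
                "n_otus": table.n_otus,
            }
        else:
            truth = None
            table = io.read_otu_table(config.otu_table)
            taxonomy = io.read_taxonomy(config.taxonomy) if config.taxonomy else io.TaxonomyMap()
            metadata = io.read_sample_metadata(config.metadata)
            reference = (
                io.read_gene_reference(config.gene_reference, config.pathway_map)
                if config.gene_reference
                else None
            )
            report["stages"]["inputs"] = {
                "source": "files",
                "n_samples": table.n_samples,
                "n_otus": table.n_otus,
            }
        metadata.require_covers(table)
        species_list = [s for s in metadata.species_names() if s in set(metadata.species)]
        finish_stage("inputs")

        # -- prevalence sweeps and stabilization ----------------------------
        current_stage = "sweep"
        curves: dict[str, dict[str, core.PrevalenceCurve]] = {}
        stabilization: dict[str, int | None] = {}
        sweep_rows = []
        for species in species_list:
            curves[species] = {}
            for niche in metadata.niches_of(species):
                samples = metadata.samples_where(species=species, niche=niche)
                curve = core.prevalence_sweep(
                    table, samples, scope=(species, niche),
                    grid_step=config.grid_step, min_count=config.min_count,
                )
                curves[species][niche] = curve
                for t, size in zip(curve.thresholds, curve.core_size):
                    sweep_rows.append(
                        {"species": species, "niche": niche, "threshold_percent": t, "core_size": size}
                    )
            t_star = core.stabilization_threshold(list(curves[species].values()))
            stabilization[species] = t_star
            if t_star is None:
                report["warnings"].append(f"no stabilization point for {species}")
        pd.DataFrame(sweep_rows).to_csv(outdir / "prevalence_curves.tsv", sep="\t", index=False)
        record_output("prevalence_curves", outdir / "prevalence_curves.tsv")
        report["stages"]["sweep"] = {
            "grid_step": config.grid_step,
            "stabilization_threshold": stabilization,
        }
        finish_stage("sweep")

        # -- cores, combination, venn, universal ----------------------------
        current_stage = "cores"
        core_rows = []
        per_level_sizes: dict[str, dict[str, dict[int, int]]] = {}
        combined: dict[str, core.CombinedCore] = {}
        for species in species_list:
            per_level_sizes[species] = {}
            niche_cores_at_level: dict[str, core.CoreSet] = {}
            for niche in metadata.niches_of(species):
                samples = metadata.samples_where(species=species, niche=niche)
                per_level_sizes[species][niche] = {}
                for level in sorted(set((*config.levels, config.core_level))):
                    cset = core.core_at_threshold(
                        table, samples, level, scope=(species, niche),
                        min_count=config.min_count,
                    )
                    per_level_sizes[species][niche][level] = len(cset)
                    for otu in sorted(cset.members):
                        core_rows.append(
                            {
                                "species": species,
                                "niche": niche,
                                "level_percent": level,
                                "otu_id": otu,
                                "prevalence": cset.prevalence[otu],
                            }
                        )
                    if level == config.core_level:
                        niche_cores_at_level[niche] = cset
            combined[species] = core.combine_cores(niche_cores_at_level)
        pd.DataFrame(core_rows).to_csv(outdir / "core_membership.tsv", sep="\t", index=False)
        record_output("core_membership", outdir / "core_membership.tsv")

        combined_rows = []
        for species, comb in combined.items():
            for otu in sorted(comb.members):
                combined_rows.append(
                    {
                        "species": species,
                        "otu_id": otu,
                        "niches": ",".join(sorted(comb.provenance[otu])),
                    }
                )
        pd.DataFrame(combined_rows).to_csv(outdir / "combined_core.tsv", sep="\t", index=False)
        record_output("combined_core", outdir / "combined_core.tsv")

        venns = {}
        for species in species_list:
            niches = metadata.niches_of(species)
            if len(niches) == 3:
                cores3 = {
                    n: core.core_at_threshold(
                        table,
                        metadata.samples_where(species=species, niche=n),
                        config.core_level,
                        scope=(species, n),
                        min_count=config.min_count,
                    )
                    for n in niches
                }
                venns[species] = core.venn_of_cores(cores3).to_dict()

        universal = None
        if len(species_list) >= 2:
            universal = sorted(
                core.universal_core(
                    combined,
                    {s: taxonomy for s in species_list},
                    match_rank=config.match_rank,
                )
            )

        rare = {}
        for species in species_list:
            whole = metadata.samples_where(species=species, niche="holobiont")
            if not whole:
                whole = metadata.samples_where(species=species)
            summary = core.rare_core_summary(combined[species].members, table, whole)
            rare[species] = summary.to_dict()

        report["stages"]["cores"] = {
            "core_level": config.core_level,
            "sizes_per_level": per_level_sizes,
            "combined_core_size": {s: len(c) for s, c in combined.items()},
            "venn": venns,
            "universal_taxa": universal,
            "match_rank": config.match_rank,
            "rare_core_summary": rare,
        }
        # Newick export of each species' combined core.
        if len(taxonomy) > 0:
            newick_path = outdir / "combined_core_taxa.nwk"
            with newick_path.open("w") as fh:
                for species in species_list:
                    members = [o for o in sorted(combined[species].members) if o in taxonomy]
                    if members:
                        fh.write(io.export_taxonomy_newick(taxonomy, members))
            record_output("combined_core_taxa", newick_path)
        finish_stage("cores")

        # -- diversity -------------------------------------------------------
        current_stage = "diversity"
        rich = cs.richness(table, min_count=config.min_count)
        shan = cs.shannon(table)
        div_frame = pd.DataFrame({"richness": rich, "shannon": shan})
        div_frame.index.name = "sample_id"
        div_frame.to_csv(outdir / "diversity.tsv", sep="\t")
        record_output("diversity", outdir / "diversity.tsv")

        diversity_tests = {}
        for species in species_list:
            samples = metadata.samples_where(species=species)
            sub_meta = metadata.subset(samples)
            terms = _variable_terms(sub_meta, ("Niche", "Depth"))
            if not terms:
                report["warnings"].append(
                    f"no variable metadata terms for diversity model of {species}"
                )
                continue
            entry = {}
            for name, values in (("richness", rich), ("shannon", shan)):
                model = cs.diversity_model(values.loc[samples].astype(float), sub_meta, terms)
                entry[name] = {
                    t: {"F": model.loc[t, "F"], "p": model.loc[t, "p_value"]} for t in terms
                }
            entry["terms"] = list(terms)
            diversity_tests[species] = entry
        report["stages"]["diversity"] = diversity_tests
        finish_stage("diversity")

        # -- ordination and permutation tests -------------------------------
        current_stage = "ordination"
        ordination = {}
        for k, species in enumerate(species_list):
            samples = metadata.samples_where(species=species)
            if len(samples) < 3:
                continue
            dm = cs.bray_curtis(table.subset_samples(samples), relative=True)
            result = cs.pcoa(dm)
            coords = result.coordinates.iloc[:, : min(4, result.coordinates.shape[1])]
            path = outdir / f"pcoa_{species}.tsv"
            coords.to_csv(path, sep="\t", index_label="sample_id")
            record_output(f"pcoa_{species}", path)
            ordination[species] = {
                "proportion_explained": [float(v) for v in result.proportion_explained[:4]],
                "negative_eigenvalue_mass": float(result.negative_eigenvalue_mass),
            }
        report["stages"]["ordination"] = ordination
        finish_stage("ordination")

        current_stage = "permanova"
        permanova_results = {}
        anosim_results = {}
        for k, species in enumerate(species_list):
            samples = metadata.samples_where(species=species)
            sub_meta = metadata.subset(samples)
            niches = sub_meta.niche.unique()
            if len(samples) < 6 or len(niches) < 2:
                continue
            dm = cs.bray_curtis(table.subset_samples(samples), relative=True)
            terms = _variable_terms(sub_meta, ("Niche", "Depth"))
            if "Niche" in terms and "Depth" in terms:
                terms = [*terms, "Niche:Depth"]
            res = cs.permanova(
                dm, sub_meta, terms, n_perm=config.n_perm, seed=[config.seed, 40 + k]
            )
            permanova_results[species] = {
                "terms": {
                    t: {
                        "pseudo_F": res.table.loc[t, "pseudo_F"],
                        "R2": res.table.loc[t, "R2"],
                        "p": res.table.loc[t, "p_value"],
                    }
                    for t in terms
                },
                "n_permutations": res.n_permutations,
            }
            ano = cs.anosim(
                dm, sub_meta.niche, n_perm=config.n_perm, seed=[config.seed, 60 + k]
            )
            anosim_results[species] = {"R": ano.r, "p": ano.p_value}
        report["stages"]["permanova"] = permanova_results
        report["stages"]["anosim"] = anosim_results
        finish_stage("permanova")

        # -- differential abundance -----------------------------------------
        current_stage = "diffabund"
        diff_summary = {}
        for species in species_list:
            samples = metadata.samples_where(species=species)
            sub_meta = metadata.subset(samples)
            if len(sub_meta.niche.unique()) < 2:
                continue
            sub = table.subset_samples(samples)
            keep = [o for o in sub.otu_ids if sub.counts[o].sum() > 0]
            sub = io.OtuTable(sub.counts[keep])
            res = cs.diff_abundance(sub, sub_meta, terms=("Niche",))
            path = outdir / f"diffabund_{species}.tsv"
            res.table.to_csv(path, sep="\t")
            record_output(f"diffabund_{species}", path)
            ok = res.table[res.table["status"] == "ok"]
            top = ok.nsmallest(5, "q_value")
            diff_summary[species] = {
                "n_tested": int(len(ok)),
                "n_significant_q05": int((ok["q_value"] <= 0.05).sum()),
                "top_otus": list(top.index),
            }
        report["stages"]["diffabund"] = diff_summary
        finish_stage("diffabund")

        # -- functional prediction ------------------------------------------
        current_stage = "predict"
        if reference is not None:
            profile = fp.predict_metagenome(table, reference)
            profile.counts.to_csv(outdir / "predicted_functions.tsv", sep="\t", index_label="sample_id")
            record_output("predicted_functions", outdir / "predicted_functions.tsv")
            pathway_profile = fp.aggregate_pathways(profile, reference.pathways)
            pathway_profile.counts.to_csv(outdir / "predicted_pathways.tsv", sep="\t", index_label="sample_id")
            record_output("predicted_pathways", outdir / "predicted_pathways.tsv")

            predict_summary = {"pathway_tests": {}, "taxon_contribution": {}}
            transport_families = sorted(
                f for f, ps in reference.pathways.items() if config.contribution_pathway in ps
            )
            for species in species_list:
                samples = metadata.samples_where(species=species)
                sub_meta = metadata.subset(samples)
                if len(sub_meta.niche.unique()) >= 2:
                    sub_profile = fp.PathwayProfile(counts=pathway_profile.counts.loc[samples])
                    tests = fp.pathway_group_test(sub_profile, sub_meta)
                    path = outdir / f"pathway_tests_{species}.tsv"
                    tests.to_csv(path, sep="\t")
                    record_output(f"pathway_tests_{species}", path)
                    predict_summary["pathway_tests"][species] = {
                        "top_pathway": tests.index[0],
                        "n_significant_q05": int((tests["q_value"] <= 0.05).sum()),
                    }
                if transport_families:
                    endo = metadata.samples_where(species=species, niche="endosymbiotic")
                    if endo:
                        shares = fp.taxon_contribution(
                            table, reference, taxonomy, transport_families,
                            rank=config.match_rank, scope_samples=endo,
                        )
                        if shares is not None:
                            predict_summary["taxon_contribution"][species] = {
                                str(k): float(v) for k, v in shares.head(5).items()
                            }
            report["stages"]["predict"] = predict_summary
        finish_stage("predict")

    except Exception as exc:  # re-tag with the failing stage
        manifest.write_text(
            "".join(f"{s}\n" for s in completed) + f"INCOMPLETE at stage {current_stage}\n"
        )
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n")
    record_output("report", report_path)
    return report


def _variable_terms(metadata: io.SampleMetadata, candidates: Sequence[str]) -> list[str]:
    """Keep only terms with >= 2 distinct values in this scope (a species
    sampled at a single depth contributes no depth term)."""
    terms = []
    for term in candidates:
        values = metadata.frame[term]
        if len(pd.unique(values)) >= 2:
            terms.append(term)
    return terms
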