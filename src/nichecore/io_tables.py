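"""Readers and writers for the classic microbiome table formats.

Everything downstream works from three plain-text artifacts: an OTU count
table (classic tab-separated, OTUs in rows, samples in columns — the layout
QIIME 1 and the "classic" BIOM dialect write), a two-column GreenGenes-style
taxonomy file, and a QIIME mapping file carrying per-sample species, niche
(preparation type), depth and site. A fourth, the per-OTU gene-family
copy-number reference used by the functional-prediction stage, is a simple
wide TSV.

In memory the canonical orientation is samples x OTUs, which matches the
per-sample statistics computed downstream; files keep the field-standard
OTU x sample layout and are transposed on load.
"""

from __future__ import annotations

import logging
import numbers
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of host micro-habitats (preparation types).
NICHES = ("holobiont", "tissue", "endosymbiotic", "skeletal")

#: Taxonomic ranks, outermost first, in GreenGenes prefix order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNCLASSIFIED = "unclassified"

OTU_TABLE_DIALECTS = ("classic_tsv", "biom_classic")
_TAXONOMY_COLUMN_NAMES = {"taxonomy", "consensus lineage", "consensuslineage"}


class TableFormatError(ValueError):
    """A file does not follow the expected dialect (structure-level problem)."""


class TableValidationError(ValueError):
    """A parsed table violates an invariant (content-level problem)."""


# ---------------------------------------------------------------------------
# OTU count table
# ---------------------------------------------------------------------------


class OtuTable:
    """Integer count matrix, samples in rows and OTUs in columns.

    Wraps a :class:`pandas.DataFrame`; identifiers are opaque, case-sensitive
    strings and must be unique along both axes.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise TableValidationError("OtuTable needs at least one sample and one OTU")
        index = counts.index.astype(str)
        columns = counts.columns.astype(str)
        if index.has_duplicates:
            dupes = index[index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dupes}")
        if columns.has_duplicates:
            dupes = columns[columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate OTU identifiers: {dupes}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise TableValidationError("counts must be finite")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative count at sample {index[i]!r}, OTU {columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise TableValidationError(
                f"non-integer count at sample {index[i]!r}, OTU {columns[j]!r}"
            )
        self._counts = pd.DataFrame(
            np.asarray(np.round(values), dtype=np.int64), index=index, columns=columns
        )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_arrays(cls, counts, sample_ids, otu_ids) -> "OtuTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(sample_ids), columns=list(otu_ids)))

    # -- accessors ----------------------------------------------------------

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def n_samples(self) -> int:
        return self._counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self._counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        return self._counts.sum(axis=1)

    def presence(self, min_count: int = 1) -> pd.DataFrame:
        """Boolean samples x OTUs matrix of detection at ``min_count`` reads."""
        return self._counts >= int(min_count)

    def relative_abundance(self) -> pd.DataFrame:
        sizes = self.library_sizes
        if (sizes == 0).any():
            bad = sizes.index[sizes == 0].tolist()
            raise TableValidationError(f"zero library size for samples {bad}")
        return self._counts.div(sizes, axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self._counts.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return OtuTable(self._counts.loc[wanted])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self._counts.equals(other._counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<OtuTable {self.n_samples} samples x {self.n_otus} OTUs>"


def _split_header(line: str, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 2:
        raise TableFormatError(
            f"line {lineno}: header must contain an OTU-id column and at least "
            f"one sample column, got {line.rstrip()!r}"
        )
    return fields


def read_otu_table(path, dialect: str = "classic_tsv") -> OtuTable:
    """Read an OTU x sample TSV and return the transposed, validated table.

    Samples with zero library size are dropped with a logged warning; no
    count is ever altered.
    """
    table, _ = read_otu_table_with_taxonomy(path, dialect)
    return table


def read_otu_table_with_taxonomy(
    path, dialect: str = "classic_tsv"
) -> tuple[OtuTable, "TaxonomyMap | None"]:
    """Like :func:`read_otu_table` but also returns the trailing taxonomy
    column of the classic-BIOM dialect, split into a :class:`TaxonomyMap`
    (``None`` when the column is absent)."""
    if dialect not in OTU_TABLE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {OTU_TABLE_DIALECTS}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file")

    header_idx = 0
    if dialect == "biom_classic":
        # Leading '#' lines are comments; the last of them is the header row.
        while header_idx + 1 < len(lines) and lines[header_idx + 1].startswith("#"):
            header_idx += 1
        if not lines[header_idx].startswith("#"):
            header_idx = 0
    header = _split_header(lines[header_idx], header_idx + 1)
    sample_ids = header[1:]

    tax_column = None
    if sample_ids and sample_ids[-1].strip().lower() in _TAXONOMY_COLUMN_NAMES:
        tax_column = {}
        sample_ids = sample_ids[:-1]
        if not sample_ids:
            raise TableFormatError(f"line {header_idx + 1}: no sample columns before taxonomy")
    if len(set(sample_ids)) != len(sample_ids):
        raise TableValidationError(f"duplicate sample identifiers in header: {sample_ids}")

    otu_ids: list[str] = []
    rows: list[list[int]] = []
    n_cols = len(header)
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise TableFormatError(
                f"line {lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        otu_id = fields[0]
        if otu_id in set(otu_ids):
            raise TableValidationError(f"line {lineno}: duplicate OTU identifier {otu_id!r}")
        values = fields[1 : len(sample_ids) + 1]
        row = []
        for col, (sample, token) in enumerate(zip(sample_ids, values), start=2):
            try:
                value = float(token)
            except ValueError:
                raise TableValidationError(
                    f"line {lineno}, column {col} (sample {sample!r}): "
                    f"non-numeric count {token!r}"
                ) from None
            if value < 0:
                raise TableValidationError(
                    f"line {lineno}, column {col} (sample {sample!r}): negative count {token}"
                )
            row.append(value)
        otu_ids.append(otu_id)
        rows.append(row)
        if tax_column is not None:
            tax_column[otu_id] = parse_lineage(fields[-1])
    if not rows:
        raise TableFormatError(f"{path}: no data rows")

    frame = pd.DataFrame(rows, index=otu_ids, columns=sample_ids).T  # -> samples x OTUs
    table = OtuTable(frame)
    sizes = table.library_sizes
    empty = sizes.index[sizes == 0].tolist()
    if empty:
        logger.warning("dropping %d sample(s) with zero library size: %s", len(empty), empty)
        keep = [s for s in table.sample_ids if s not in set(empty)]
        if not keep:
            raise TableValidationError(f"{path}: every sample has zero library size")
        table = table.subset_samples(keep)
    taxonomy = TaxonomyMap(tax_column) if tax_column else None
    return table, taxonomy


def write_otu_table(
    table: OtuTable,
    path,
    dialect: str = "classic_tsv",
    taxonomy: "TaxonomyMap | None" = None,
) -> None:
    """Write in OTU x sample orientation; ``biom_classic`` adds the standard
    comment line and, when a taxonomy is given, a trailing taxonomy column."""
    if dialect not in OTU_TABLE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {OTU_TABLE_DIALECTS}")
    path = Path(path)
    out = table.counts.T  # OTU x sample
    with path.open("w") as fh:
        if dialect == "biom_classic":
            fh.write("# Constructed from classic OTU table\n")
        header = ["#OTU ID", *out.columns]
        if dialect == "biom_classic" and taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for otu_id, row in out.iterrows():
            fields = [str(otu_id), *(str(int(v)) for v in row)]
            if dialect == "biom_classic" and taxonomy is not None:
                fields.append(format_lineage(taxonomy.get(otu_id)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a GreenGenes prefixed lineage string into a 7-tuple of rank names.

    Missing, empty, or bare-prefix tokens become ``"unclassified"``. A token
    with an unknown prefix is kept verbatim at its positional rank, with a
    warning.
    """
    ranks = [UNCLASSIFIED] * len(RANKS)
    if text is None:
        return tuple(ranks)
    tokens = [t.strip() for t in str(text).split(";")]
    if tokens == [""]:
        return tuple(ranks)
    for i, token in enumerate(tokens[: len(RANKS)]):
        if not token:
            continue
        if token[:3] == RANK_PREFIXES[i]:
            name = token[3:].strip()
            ranks[i] = name if name else UNCLASSIFIED
        elif token[:3] in RANK_PREFIXES:
            # Known prefix, wrong position: honor the prefix's rank.
            j = RANK_PREFIXES.index(token[:3])
            name = token[3:].strip()
            ranks[j] = name if name else UNCLASSIFIED
        else:
            logger.warning(
                "unknown rank prefix in token %r; keeping it at the %s rank",
                token,
                RANKS[i],
            )
            ranks[i] = token
    return tuple(ranks)


def format_lineage(lineage: tuple[str, ...] | None) -> str:
    """Canonical GreenGenes form: all seven ranks, ``"; "``-separated, with
    unclassified ranks rendered as a bare prefix."""
    if lineage is None:
        lineage = (UNCLASSIFIED,) * len(RANKS)
    parts = []
    for prefix, name in zip(RANK_PREFIXES, lineage):
        parts.append(prefix if name == UNCLASSIFIED else prefix + name)
    return "; ".join(parts)


class TaxonomyMap(Mapping):
    """otu_id -> 7-tuple lineage (kingdom .. species), ``"unclassified"`` for
    missing ranks."""

    def __init__(self, lineages: Mapping[str, tuple[str, ...]] | None = None):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for otu_id, lineage in (lineages or {}).items():
            self._lineages[str(otu_id)] = self._normalize(lineage)

    @staticmethod
    def _normalize(lineage) -> tuple[str, ...]:
        if isinstance(lineage, str):
            return parse_lineage(lineage)
        lineage = tuple(str(x) for x in lineage)
        if len(lineage) > len(RANKS):
            raise TableValidationError(f"lineage has more than {len(RANKS)} ranks: {lineage}")
        return lineage + (UNCLASSIFIED,) * (len(RANKS) - len(lineage))

    def __getitem__(self, otu_id: str) -> tuple[str, ...]:
        return self._lineages[otu_id]

    def __iter__(self):
        return iter(self._lineages)

    def __len__(self) -> int:
        return len(self._lineages)

    def at_rank(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self._lineages[otu_id][RANKS.index(rank)]

    def merged_with(self, other: "TaxonomyMap") -> "TaxonomyMap":
        merged = dict(self._lineages)
        merged.update(other._lineages)
        return TaxonomyMap(merged)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column otu_id <tab> lineage file (no header)."""
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TableFormatError(f"{path} line {lineno}: expected otu_id<TAB>lineage")
        otu_id = fields[0]
        if otu_id in lineages:
            raise TableValidationError(f"{path} line {lineno}: duplicate OTU id {otu_id!r}")
        lineages[otu_id] = parse_lineage(fields[1])
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with Path(path).open("w") as fh:
        for otu_id in taxonomy:
            fh.write(f"{otu_id}\t{format_lineage(taxonomy[otu_id])}\n")


def export_taxonomy_newick(taxonomy: TaxonomyMap, tip_set: Iterable[str]) -> str:
    """Rank-nested Newick tree over ``tip_set``.

    Internal nodes are taxon names (path-scoped, so two "unclassified"
    families under different orders stay distinct clades); tips are OTU ids.
    """
    from skbio import TreeNode

    tips = sorted(set(tip_set))
    if not tips:
        raise ValueError("tip_set must be non-empty")
    missing = [t for t in tips if t not in taxonomy]
    if missing:
        raise KeyError(f"tips without taxonomy: {missing}")

    root = TreeNode(name="root")
    index: dict[tuple[str, ...], object] = {(): root}
    for otu_id in tips:
        path: tuple[str, ...] = ()
        parent = root
        for name in taxonomy[otu_id]:
            path = path + (name,)
            node = index.get(path)
            if node is None:
                node = TreeNode(name=name)
                parent.append(node)
                index[path] = node
            parent = node
        parent.append(TreeNode(name=otu_id))
    import io as _io

    buffer = _io.StringIO()
    root.write(buffer, format="newick")
    return buffer.getvalue().strip() + "\n"


# ---------------------------------------------------------------------------
# Sample metadata (QIIME mapping convention)
# ---------------------------------------------------------------------------

REQUIRED_METADATA_COLUMNS = ("Species", "Niche", "Depth")


class SampleMetadata:
    """Per-sample species, niche (preparation type), depth (m) and site.

    Backed by a DataFrame indexed by sample id; extra columns are preserved
    verbatim.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dupes}")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise TableValidationError(f"metadata missing required columns: {missing}")
        bad_niche = sorted(set(frame["Niche"]) - set(NICHES))
        if bad_niche:
            raise TableValidationError(
                f"niche values outside the closed vocabulary {NICHES}: {bad_niche}"
            )
        depth = pd.to_numeric(frame["Depth"], errors="coerce")
        if depth.isna().any():
            bad = frame.index[depth.isna()].tolist()
            raise TableValidationError(f"non-numeric Depth for samples {bad}")
        if (depth < 0).any():
            bad = frame.index[depth < 0].tolist()
            raise TableValidationError(f"negative Depth for samples {bad}")
        frame["Depth"] = depth.astype(float)
        if "Site" not in frame.columns:
            frame["Site"] = ""
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def species(self) -> pd.Series:
        return self._frame["Species"]

    @property
    def niche(self) -> pd.Series:
        return self._frame["Niche"]

    @property
    def depth(self) -> pd.Series:
        return self._frame["Depth"]

    def samples_where(self, species: str | None = None, niche: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self._frame.index)
        if species is not None:
            mask &= self._frame["Species"] == species
        if niche is not None:
            mask &= self._frame["Niche"] == niche
        return list(self._frame.index[mask])

    def species_names(self) -> list[str]:
        seen: list[str] = []
        for s in self._frame["Species"]:
            if s not in seen:
                seen.append(s)
        return seen

    def niches_of(self, species: str) -> list[str]:
        sub = self._frame.loc[self._frame["Species"] == species, "Niche"]
        seen: list[str] = []
        for n in sub:
            if n not in seen:
                seen.append(n)
        return seen

    def require_covers(self, table: OtuTable) -> None:
        missing = [s for s in table.sample_ids if s not in self._frame.index]
        if missing:
            raise TableValidationError(f"samples without metadata records: {missing}")

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self._frame.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self._frame.equals(other._frame)


def read_sample_metadata(path) -> SampleMetadata:
    """Read a QIIME-style mapping file ('#SampleID' first header column)."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if not header[0].lstrip("#") == "SampleID":
        raise TableFormatError(
            f"{path} line 1: mapping file must start with a '#SampleID' column, "
            f"got {header[0]!r}"
        )
    columns = header[1:]
    records = []
    ids = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TableFormatError(
                f"{path} line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        ids.append(fields[0])
        records.append(fields[1:])
    frame = pd.DataFrame(records, columns=columns, index=ids)
    return SampleMetadata(frame)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    frame = metadata.frame
    with Path(path).open("w") as fh:
        fh.write("#SampleID\t" + "\t".join(frame.columns) + "\n")
        for sample_id, row in frame.iterrows():
            fields = [str(sample_id)]
            for col, v in zip(frame.columns, row):
                if col == "Depth" and isinstance(v, numbers.Real):
                    v = f"{float(v):g}"
                fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene-family copy-number reference
# ---------------------------------------------------------------------------


@dataclass
class GeneCopyTable:
    """Per-OTU 16S copy number and gene-family copy counts, plus the
    gene-family -> pathway map used for pathway aggregation.

    ``gene_copies`` is OTU x gene-family (non-negative reals); ``ssu_copies``
    is per-OTU and must be >= 1 (it divides the read counts, normalizing for
    rRNA operon multiplicity).
    """

    ssu_copies: pd.Series
    gene_copies: pd.DataFrame
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.ssu_copies = self.ssu_copies.astype(float)
        self.ssu_copies.index = self.ssu_copies.index.astype(str)
        self.gene_copies = self.gene_copies.astype(float)
        self.gene_copies.index = self.gene_copies.index.astype(str)
        if self.ssu_copies.index.has_duplicates or self.gene_copies.index.has_duplicates:
            raise TableValidationError("duplicate OTU identifiers in gene reference")
        if not self.ssu_copies.index.equals(self.gene_copies.index):
            raise TableValidationError("ssu_copies and gene_copies must index the same OTUs")
        if (self.ssu_copies < 1).any() or not np.isfinite(self.ssu_copies).all():
            bad = self.ssu_copies.index[~(self.ssu_copies >= 1)].tolist()
            raise TableValidationError(f"ssu_copies must be finite and >= 1; offending: {bad}")
        values = self.gene_copies.to_numpy()
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise TableValidationError("gene copy numbers must be finite and non-negative")
        self.pathways = {str(g): frozenset(ps) for g, ps in self.pathways.items()}

    @property
    def otu_ids(self) -> list[str]:
        return list(self.ssu_copies.index)

    @property
    def gene_family_ids(self) -> list[str]:
        return list(self.gene_copies.columns)

    def covers(self, otu_id: str) -> bool:
        return otu_id in self.ssu_copies.index


def read_gene_reference(path, pathway_path=None) -> GeneCopyTable:
    """Reference TSV: columns ``otu_id``, ``ssu_copies``, then one column per
    gene family; optional two-column family<TAB>pathway map alongside."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "ssu_copies" not in frame.columns:
        raise TableFormatError(f"{path}: missing required 'ssu_copies' column")
    pathways: dict[str, frozenset[str]] = {}
    if pathway_path is not None:
        pathways = {g: frozenset(ps) for g, ps in read_pathway_map(pathway_path).items()}
    return GeneCopyTable(
        ssu_copies=frame["ssu_copies"],
        gene_copies=frame.drop(columns=["ssu_copies"]),
        pathways=pathways,
    )


def write_gene_reference(reference: GeneCopyTable, path, pathway_path=None) -> None:
    frame = reference.gene_copies.copy()
    frame.insert(0, "ssu_copies", reference.ssu_copies)
    frame.index.name = "otu_id"
    frame.to_csv(path, sep="\t")
    if pathway_path is not None:
        write_pathway_map(reference.pathways, pathway_path)


def read_pathway_map(path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise TableFormatError(f"{path} line {lineno}: expected family<TAB>pathway")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def write_pathway_map(pathways: Mapping[str, Iterable[str]], path) -> None:
    with Path(path).open("w") as fh:
        for family in sorted(pathways):
            for pathway in sorted(pathways[family]):
                fh.write(f"{family}\t{pathway}\n")
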