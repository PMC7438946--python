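"""Readers and writers for the formats the pipeline touches.

Containers are deliberately thin: an OTU table is sample-major count matrix
plus a per-OTU ranked taxonomy; genotypes are diploid allele dosages (0/1/2,
NaN for missing); trees are :class:`skbio.TreeNode`. All readers preserve
file order and all writers round-trip through their reader.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import skbio
from skbio import TreeNode

logger = logging.getLogger("phylosym")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """A file does not conform to the accepted dialect."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant."""


class EmptyInputError(ValueError):
    """An operation received an input with nothing to work on."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Sample x OTU abundance matrix with per-OTU ranked taxonomy.

    ``counts`` is integer-valued before rarefaction averaging but floats are
    accepted (averaged tables, pooled relative-abundance profiles).
    ``taxonomy`` maps otu_id -> 7-tuple of rank labels (kingdom..species),
    empty string for unassigned ranks; it may be empty if no taxonomy is
    known.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus)
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite counts")
        for otu in self.taxonomy:
            if otu not in set(self.otu_ids):
                raise ValidationError(f"taxonomy for unknown OTU {otu!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def grand_total(self) -> float:
        return float(self.counts.sum())

    def subset_otus(self, keep: Sequence[str]) -> "OtuTable":
        """New table restricted to ``keep`` OTUs, preserving their order."""
        keep = list(keep)
        idx = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in keep]
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=keep,
            counts=self.counts[:, cols].copy(),
            taxonomy={o: self.taxonomy[o] for o in keep if o in self.taxonomy},
        )

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]


class NormalizedTable(OtuTable):
    """OTU table after log2 z-normalization: real-valued, each sample row has
    mean 0 and standard deviation 1 over the retained OTUs."""

    def __post_init__(self) -> None:  # values may be negative
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError("values shape does not match id lists")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite values")


@dataclass
class GroupingMap:
    """sample_id -> lineage label."""

    assignments: dict[str, str]

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    def groups(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def require_cover(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites, diploid ALT-allele dosages.

    ``genotypes`` holds 0.0/1.0/2.0 with NaN for missing calls.
    """

    individual_ids: list[str]
    site_ids: list[str]
    genotypes: np.ndarray  # (n_individuals, n_sites)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        if self.genotypes.shape != (len(self.individual_ids), len(self.site_ids)):
            raise ValidationError("genotype shape does not match id lists")
        observed = self.genotypes[~np.isnan(self.genotypes)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValidationError("genotype dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


# ---------------------------------------------------------------------------
# taxonomy strings
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a GreenGenes-style ``k__X; p__Y; ...`` string into 7 rank labels.

    Unprefixed, semicolon-separated strings are mapped positionally from
    kingdom downward. Missing trailing ranks become empty strings.
    """
    parts = [p.strip() for p in lineage.split(";")] if lineage.strip() else []
    out = [""] * len(RANKS)
    for i, part in enumerate(parts):
        if len(part) >= 3 and part[:3] in _RANK_PREFIXES:
            pos = _RANK_PREFIXES.index(part[:3])
            out[pos] = part[3:].strip()
        elif i < len(RANKS):
            out[i] = part
    return tuple(out)


def format_lineage(ranks: Sequence[str]) -> str:
    return "; ".join(pref + name for pref, name in zip(_RANK_PREFIXES, ranks))


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage", "consensuslineage"}


def read_otu_table(path: str | Path, format: str = "auto") -> OtuTable:
    """Read an OTU table from classic QIIME TSV or BIOM JSON.

    The TSV dialect is auto-oriented: a header starting with ``#OTU ID``
    marks OTU-major rows (optionally with a trailing taxonomy column);
    otherwise rows are samples. ``format`` may be ``tsv``, ``biom-json`` or
    ``auto`` (sniffed from the first non-blank character).
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        stripped = text.lstrip()
        format = "biom-json" if stripped.startswith("{") else "tsv"
    if format == "biom-json":
        return _read_biom_json(text)
    if format == "tsv":
        return _read_otu_tsv(text, path)
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_otu_tsv(text: str, path: Path) -> OtuTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    # classic dialect allows a leading "# Constructed from biom file" comment
    while lines and lines[0].startswith("#") and not _is_header(lines[0]):
        lines.pop(0)
    if not lines:
        raise FormatError(f"{path}: no header row found")
    header = lines[0].split("\t")
    first = header[0].lstrip("#").strip().lower()
    otu_major = first in {"otu id", "otu_id", "otuid"}

    has_taxonomy = header[-1].strip().lower() in _TAXONOMY_HEADERS
    col_ids = header[1:-1] if has_taxonomy else header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise FormatError(f"{path}: duplicate ids in header: {lines[0]!r}")
    if not col_ids:
        raise FormatError(f"{path}: header has no data columns: {lines[0]!r}")

    row_ids: list[str] = []
    rows: list[list[float]] = []
    taxonomy: dict[str, tuple[str, ...]] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        expected = 1 + len(col_ids) + (1 if has_taxonomy else 0)
        if len(cells) != expected:
            raise FormatError(f"{path}: row has {len(cells)} fields, expected {expected}: {ln!r}")
        row_ids.append(cells[0].strip())
        try:
            vals = [float(c) for c in cells[1:1 + len(col_ids)]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in row {cells[0]!r}: {exc}") from None
        rows.append(vals)
        if has_taxonomy:
            taxonomy[cells[0].strip()] = parse_lineage(cells[-1])

    counts = np.array(rows, dtype=float) if rows else np.zeros((0, len(col_ids)))
    if otu_major:
        return OtuTable(sample_ids=col_ids, otu_ids=row_ids, counts=counts.T,
                        taxonomy=taxonomy)
    return OtuTable(sample_ids=row_ids, otu_ids=col_ids, counts=counts)


def _is_header(line: str) -> bool:
    first = line.split("\t")[0].lstrip("#").strip().lower()
    return first in {"otu id", "otu_id", "otuid", "sample id", "sample_id", ""} or "\t" in line and not line.startswith("# ")


def _read_biom_json(text: str) -> OtuTable:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid BIOM JSON: {exc}") from None
    otu_ids = [r["id"] for r in obj["rows"]]
    sample_ids = [c["id"] for c in obj["columns"]]
    n_otus, n_samples = obj["shape"]
    counts = np.zeros((n_samples, n_otus))
    if obj.get("matrix_type") == "dense":
        for i, row in enumerate(obj["data"]):
            counts[:, i] = row
    else:
        for i, j, v in obj["data"]:
            counts[j, i] = v
    taxonomy = {}
    for r in obj["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is not None:
            if isinstance(tax, str):
                taxonomy[r["id"]] = parse_lineage(tax)
            else:
                taxonomy[r["id"]] = parse_lineage("; ".join(tax))
    return OtuTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts,
                    taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    """Write classic OTU-major TSV (default) or BIOM JSON."""
    path = Path(path)
    if format == "tsv":
        with_tax = bool(table.taxonomy)
        lines = ["#OTU ID\t" + "\t".join(table.sample_ids) + ("\ttaxonomy" if with_tax else "")]
        for j, otu in enumerate(table.otu_ids):
            vals = "\t".join(_fmt_count(v) for v in table.counts[:, j])
            row = f"{otu}\t{vals}"
            if with_tax:
                row += "\t" + format_lineage(table.taxonomy.get(otu, ("",) * len(RANKS)))
            lines.append(row)
        path.write_text("\n".join(lines) + "\n")
    elif format == "biom-json":
        obj = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "phylosym",
            "matrix_type": "sparse",
            "matrix_element_type": "float",
            "shape": [table.n_otus, table.n_samples],
            "rows": [
                {"id": o, "metadata": (
                    {"taxonomy": list(table.taxonomy[o])} if o in table.taxonomy else None)}
                for o in table.otu_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [
                [j, i, float(table.counts[i, j])]
                for j in range(table.n_otus)
                for i in range(table.n_samples)
                if table.counts[i, j] != 0
            ],
        }
        path.write_text(json.dumps(obj))
    else:
        raise ValueError(f"unknown OTU table format {format!r}")


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree; multifurcations are preserved, absent branch
    lengths stay ``None`` rather than being coerced to zero."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except (skbio.io.FormatIdentificationWarning, Exception) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"{path}: invalid Newick: {exc}") from None
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate leaf labels")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field only, biallelic SNP records) or a
    plain individuals-x-sites dosage TSV.

    Multiallelic and non-SNP VCF records are skipped; the skip count is
    logged. GT ``0/0 -> 0``, ``0/1``/``1/0 -> 1``, ``1/1 -> 2``,
    ``./. -> missing``.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "matrix-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix-tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    site_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            skipped += 1
            continue
        col = np.empty(len(individuals))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        site_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic/non-SNP records", skipped)
    if not columns:
        raise EmptyInputError(f"{path}: no biallelic SNP records")
    g = GenotypeMatrix(individual_ids=individuals, site_ids=site_ids,
                       genotypes=np.column_stack(columns))
    g.n_skipped_records = skipped  # type: ignore[attr-defined]
    return g


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty genotype matrix")
    header = lines[0].split("\t")
    site_ids = header[1:]
    individuals, rows = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: ragged row {cells[0]!r}")
        individuals.append(cells[0])
        rows.append([np.nan if c in {"NA", ".", ""} else float(c) for c in cells[1:]])
    return GenotypeMatrix(individual_ids=individuals, site_ids=site_ids,
                          genotypes=np.array(rows))


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "matrix-tsv") -> None:
    path = Path(path)
    if format == "matrix-tsv":
        lines = ["individual\t" + "\t".join(g.site_ids)]
        for i, ind in enumerate(g.individual_ids):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in g.genotypes[i]]
            lines.append(ind + "\t" + "\t".join(cells))
        path.write_text("\n".join(lines) + "\n")
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=phylosym",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.individual_ids),
    ]
    for j, site in enumerate(g.site_ids):
        gts = "\t".join(
            "./." if np.isnan(v) else _GT[v] for v in g.genotypes[:, j]
        )
        lines.append(f"1\t{j + 1}\t{site}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# grouping files
# ---------------------------------------------------------------------------

def read_grouping(path: str | Path) -> GroupingMap:
    """Two-column TSV: sample_id <TAB> lineage label. A header row whose
    first cell is 'sample' / '#SampleID'-like is skipped."""
    assignments: dict[str, str] = {}
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    for k, ln in enumerate(lines):
        cells = ln.split("\t")
        if len(cells) < 2:
            raise FormatError(f"{path}: expected 2 columns: {ln!r}")
        sid, grp = cells[0].strip(), cells[1].strip()
        if k == 0 and sid.lstrip("#").lower() in {"sample", "sample id", "sampleid", "sample_id"}:
            continue
        if sid in assignments:
            raise ValidationError(f"{path}: duplicate sample id {sid!r}")
        assignments[sid] = grp
    if not assignments:
        raise EmptyInputError(f"{path}: no sample assignments")
    return GroupingMap(assignments)


def write_grouping(groups: GroupingMap | Mapping[str, str], path: str | Path) -> None:
    assignments = groups.assignments if isinstance(groups, GroupingMap) else dict(groups)
    lines = ["sample_id\tgroup"] + [f"{s}\t{g}" for s, g in assignments.items()]
    Path(path).write_text("\n".join(lines) + "\n")
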