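"""Readers, writers and validated containers for every external table.

All tables are plain tab-separated text.  Expression matrices follow the
GEO series-matrix layout (probes in the first column, samples in the
header); lines starting with ``!`` — the series-matrix preamble — are
ignored.  Interaction files follow the BioGRID TAB dialect with
configurable column names.  Gene sets use GMT.  Gene symbols are
normalised to uppercase on ingestion so expression, interactome and
gene-set sources match case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("comonet")

#: Default column names for BioGRID TAB-style interaction files.
BIOGRID_COLUMNS = {
    "symbol_a": "Official Symbol Interactor A",
    "symbol_b": "Official Symbol Interactor B",
    "system_type": "Experimental System Type",
    "organism_a": "Organism Interactor A",
    "organism_b": "Organism Interactor B",
}


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Numeric probe × sample table.

    ``data`` is a DataFrame indexed by probe id with sample ids as
    columns.  Identifiers must be unique, all values finite, and at
    least two samples present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.data.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleGroups:
    """Mapping of sample id to group label; every group non-empty."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) < 2:
            raise FormatError("need at least 2 distinct group labels")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.labels.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        members = [s for s, g in self.labels.items() if g == group]
        if not members:
            raise KeyError(f"unknown group: {group!r}")
        return members

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.labels]
        if missing:
            raise FormatError(f"samples without a group label: {missing[:5]}")


@dataclass
class ProbeAnnotation:
    """Probe id → gene symbol (empty string means unannotated)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {p: s.strip().upper() for p, s in self.mapping.items()}


class InteractionRecord(NamedTuple):
    symbol_a: str
    symbol_b: str
    organism_a: int
    organism_b: int
    system_type: str  # "physical" | "genetic"


class InteractionRecords(list):
    """List of :class:`InteractionRecord` with the count of skipped rows."""

    def __init__(self, records: Iterable[InteractionRecord] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")
        self.members = tuple(m.upper() for m in self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets; names unique, members non-empty."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene set name: {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class CtTable:
    """Gene × animal matrix of qPCR quantification cycles.

    ``data`` is indexed by gene with animal ids as columns; ``groups``
    maps each animal to its experimental group; ``reference_genes`` are
    the endogenous controls used for normalisation.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    reference_genes: list[str]

    def __post_init__(self) -> None:
        self.reference_genes = [g for g in self.reference_genes]
        missing = [g for g in self.reference_genes if g not in self.data.index]
        if missing:
            raise FormatError(f"reference genes absent from Ct table: {missing}")
        values = self.data.to_numpy()
        if not (np.isfinite(values).all() and (values > 0).all()):
            raise FormatError("Ct values must be finite and > 0")
        unlabelled = [a for a in self.data.columns if a not in self.groups]
        if unlabelled:
            raise FormatError(f"animals without a group label: {unlabelled}")

    @property
    def target_genes(self) -> list[str]:
        refs = set(self.reference_genes)
        return [g for g in self.data.index if g not in refs]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if not ln.startswith("!")]


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a probe × sample table; first column probe ids, header sample ids.

    Raises :class:`FormatError` naming the offending probe for duplicate
    ids, and citing row and column for any non-numeric cell.
    """
    lines = _read_table_lines(path)
    if not lines:
        raise FormatError(f"empty expression file: {path}")
    rows = [ln.split(delimiter) for ln in lines]
    header = rows[0]
    sample_ids = header[1:]
    probe_ids = [r[0] for r in rows[1:]]
    seen: set[str] = set()
    for p in probe_ids:
        if p in seen:
            raise FormatError(f"duplicate probe id: {p!r}")
        seen.add(p)
    values = np.empty((len(probe_ids), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"row {probe_ids[i]!r} has {len(row) - 1} values, expected {len(sample_ids)}"
            )
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {cell!r} at probe {probe_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(df)


def read_sample_groups(path, delimiter: str = "\t") -> SampleGroups:
    """Two-column table: sample id, group label (header optional via 'sample')."""
    lines = _read_table_lines(path)
    labels: dict[str, str] = {}
    for ln in lines:
        parts = ln.split(delimiter)
        if len(parts) < 2:
            raise FormatError(f"malformed group line: {ln!r}")
        if parts[0].lower() in {"sample", "sample_id"}:
            continue
        labels[parts[0]] = parts[1]
    return SampleGroups(labels)


def read_probe_annotation(path, delimiter: str = "\t") -> ProbeAnnotation:
    """Two-column table: probe id, gene symbol (may be empty)."""
    lines = _read_table_lines(path)
    mapping: dict[str, str] = {}
    for ln in lines:
        parts = ln.split(delimiter)
        probe = parts[0]
        if probe.lower() in {"probe", "probe_id", "id"}:
            continue
        if probe in mapping:
            raise FormatError(f"duplicate probe id in annotation: {probe!r}")
        mapping[probe] = parts[1] if len(parts) > 1 else ""
    return ProbeAnnotation(mapping)


def read_interactions(path, columns: Mapping[str, str] | None = None) -> InteractionRecords:
    """Read a BioGRID TAB-style interaction table.

    Rows missing either interactor symbol are skipped; the skip count is
    logged and exposed as ``.n_skipped`` on the returned list.
    """
    colmap = dict(BIOGRID_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(
            f"interaction file lacks columns {missing}; expected "
            f"{sorted(colmap.values())}"
        )
    records = InteractionRecords()
    cols = zip(
        df[colmap["symbol_a"]].str.strip().str.upper(),
        df[colmap["symbol_b"]].str.strip().str.upper(),
        df[colmap["organism_a"]],
        df[colmap["organism_b"]],
        df[colmap["system_type"]].str.strip().str.lower(),
    )
    for a, b, org_a, org_b, system in cols:
        if not a or not b or a == "-" or b == "-":
            records.n_skipped += 1
            continue
        records.append(InteractionRecord(a, b, int(org_a), int(org_b), system))
    if records.n_skipped:
        logger.info("read_interactions: skipped %d rows lacking a symbol", records.n_skipped)
    return records


def map_probes_to_genes(probes: Sequence[str], ann: ProbeAnnotation) -> list[str]:
    """Translate probe ids to unique gene symbols.

    Probes with an empty or missing annotation are dropped; duplicate
    symbols collapse to their first appearance, preserving order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for p in probes:
        symbol = ann.mapping.get(p, "")
        if symbol and symbol not in seen:
            seen.add(symbol)
            out.append(symbol)
    return out


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            parts = ln.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise FormatError(f"GMT line for {parts[0]!r} has no members")
            coll.add(GeneSet(parts[0], parts[1], tuple(p for p in parts[2:] if p.strip())))
    return coll


def read_ct_table(path, reference_genes: Sequence[str], delimiter: str = "\t") -> CtTable:
    """Read a Ct table: header = animal ids, a 'group' row, then gene rows."""
    lines = _read_table_lines(path)
    if len(lines) < 3:
        raise FormatError("Ct table needs a header, a group row and gene rows")
    header = lines[0].split(delimiter)
    animals = header[1:]
    group_row = lines[1].split(delimiter)
    if group_row[0].lower() != "group":
        raise FormatError("second line of a Ct table must be the 'group' row")
    groups = dict(zip(animals, group_row[1:]))
    genes, values = [], []
    for ln in lines[2:]:
        parts = ln.split(delimiter)
        genes.append(parts[0])
        try:
            values.append([float(x) for x in parts[1:]])
        except ValueError:
            raise FormatError(f"non-numeric Ct value in row {parts[0]!r}") from None
    df = pd.DataFrame(values, index=genes, columns=animals, dtype=float)
    return CtTable(df, groups, list(reference_genes))


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_expression_matrix(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.data.to_csv(path, sep=delimiter, index_label="probe_id", float_format="%.17g")


def write_sample_groups(groups: SampleGroups, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample{delimiter}group\n")
        for s, g in groups.labels.items():
            fh.write(f"{s}{delimiter}{g}\n")


def write_probe_annotation(ann: ProbeAnnotation, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"probe{delimiter}symbol\n")
        for p, s in ann.mapping.items():
            fh.write(f"{p}{delimiter}{s}\n")


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    cols = BIOGRID_COLUMNS
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                [
                    cols["symbol_a"],
                    cols["symbol_b"],
                    cols["system_type"],
                    cols["organism_a"],
                    cols["organism_b"],
                ]
            )
            + "\n"
        )
        for r in records:
            fh.write(
                f"{r.symbol_a}\t{r.symbol_b}\t{r.system_type}\t{r.organism_a}\t{r.organism_b}\n"
            )


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_ct_table(ct: CtTable, path, delimiter: str = "\t") -> None:
    animals = list(ct.data.columns)
    with open(path, "w") as fh:
        fh.write(delimiter.join(["gene", *animals]) + "\n")
        fh.write(delimiter.join(["group", *[ct.groups[a] for a in animals]]) + "\n")
        for gene in ct.data.index:
            row = delimiter.join("%.17g" % v for v in ct.data.loc[gene])
            fh.write(f"{gene}{delimiter}{row}\n")
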