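"""Readers, writers and core in-memory containers.

Every on-disk artifact of the pipeline passes through this module: elution
(protein x fraction) abundance matrices as TSV with a JSON metadata sidecar,
complex catalogs as GMT, protein -> subcompartment annotations as two-column
TSV, scored edge lists as four-column TSV, and structured reports as JSON.

All writers are deterministic (stable row/column ordering, fixed float
formatting) so outputs are diffable; all readers reject malformed input
rather than coercing it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: Mitochondrial subcompartment vocabulary used by the plausibility filter.
COMPARTMENTS = ("OMM", "IMS", "matrix", "inner_membrane", "non_mito")

#: Unordered compartment label pairs considered biologically implausible for
#: a direct physical interaction (outer membrane-matrix, IMS-matrix).
FORBIDDEN_PAIRS = frozenset({
    frozenset({"OMM", "matrix"}),
    frozenset({"IMS", "matrix"}),
})

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed on-disk input."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ElutionMatrix:
    """Protein x fraction abundance table for one (genotype, extract, engine).

    ``data`` holds non-negative abundances (spectral counts or averaged
    log2 intensities); rows are proteins, columns fraction labels. NaN cells
    mean "not measured" and are only legal before zero-imputation.
    """

    data: pd.DataFrame
    genotype: str = ""
    extract: str = ""
    engine: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate protein identifier {dup!r}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise FormatError("negative abundance value")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def fractions(self) -> list[str]:
        return list(self.data.columns)

    def copy_with(self, data: pd.DataFrame) -> "ElutionMatrix":
        return ElutionMatrix(data, self.genotype, self.extract, self.engine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElutionMatrix):
            return NotImplemented
        return (
            (self.genotype, self.extract, self.engine)
            == (other.genotype, other.extract, other.engine)
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(
                self.data.to_numpy(dtype=float),
                other.data.to_numpy(dtype=float),
                equal_nan=True,
                rtol=0,
                atol=1e-9,
            )
        )


@dataclass
class ComplexCatalog:
    """Named protein sets: a reference gold standard, predictions, or planted truth."""

    complexes: dict[str, frozenset[str]]
    source: str = "reference"

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise FormatError(f"complex {name!r} has no members")
            self.complexes[name] = frozenset(members)

    def members(self) -> set[str]:
        out: set[str] = set()
        for m in self.complexes.values():
            out |= m
        return out

    def intra_pairs(self) -> set[tuple[str, str]]:
        """All unordered within-complex protein pairs, each counted once."""
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            srt = sorted(members)
            for i, a in enumerate(srt):
                for b in srt[i + 1:]:
                    pairs.add((a, b))
        return pairs

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class ScoredNetwork:
    """Weighted undirected PPI network after score thresholding.

    Edges are stored canonically as (a, b) with a < b; retained edges carry
    score >= threshold.
    """

    edges: dict[tuple[str, str], float]
    threshold: float = 0.0
    genotype: str = ""
    extract: str = ""

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), s in self.edges.items():
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            key = (a, b) if a < b else (b, a)
            if key in canon and not math.isclose(canon[key], s):
                raise FormatError(f"duplicate edge {key} with conflicting scores")
            canon[key] = float(s)
        self.edges = canon

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Elution matrices (TSV + JSON metadata sidecar)
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_matrix(path: str | Path, genotype: str = "", extract: str = "",
                engine: str = "") -> ElutionMatrix:
    """Read a protein x fraction TSV.

    Header row = fraction labels, first column = protein ids. Empty cells and
    "NA" become explicit missing values. A sidecar ``<name>.meta.json``
    written by :func:`write_matrix` overrides the metadata arguments.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    fractions = header[1:]
    n_cols = len(header)
    rows: list[list[float]] = []
    ids: list[str] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} fields, expected {n_cols})")
        pid = cells[0]
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        seen.add(pid)
        vals: list[float] = []
        for cell in cells[1:]:
            cell = cell.strip()
            if cell == "" or cell.upper() == "NA":
                vals.append(np.nan)
            else:
                v = float(cell)
                if v < 0:
                    raise FormatError(f"{path}:{lineno}: negative value {v} for {pid!r}")
                vals.append(v)
        ids.append(pid)
        rows.append(vals)
    if not ids:
        raise FormatError(f"{path}: no proteins")
    df = pd.DataFrame(rows, index=ids, columns=fractions, dtype=float)
    meta = {"genotype": genotype, "extract": extract, "engine": engine}
    side = _meta_path(path)
    if side.exists():
        meta.update(json.loads(side.read_text()))
    return ElutionMatrix(df, meta["genotype"], meta["extract"], meta["engine"])


def write_matrix(matrix: ElutionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                       index_label="protein", na_rep="NA")
    meta = {"genotype": matrix.genotype, "extract": matrix.extract,
            "engine": matrix.engine, "schema_version": SCHEMA_VERSION}
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Complex catalogs (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str = "reference") -> ComplexCatalog:
    """Parse a GMT file: ``name TAB description TAB member...`` per line."""
    path = Path(path)
    complexes: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        name = fields[0]
        if name in complexes:
            raise FormatError(f"{path}:{lineno}: duplicate complex name {name!r}")
        complexes[name] = frozenset(m for m in fields[2:] if m)
    return ComplexCatalog(complexes, source=source)


def write_gmt(catalog: ComplexCatalog, path: str | Path) -> None:
    lines = []
    for name in sorted(catalog.complexes):
        members = sorted(catalog.complexes[name])
        lines.append("\t".join([name, catalog.source] + members))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Compartment annotations
# ---------------------------------------------------------------------------

def read_compartments(path: str | Path,
                      vocabulary: Iterable[str] = COMPARTMENTS) -> dict[str, str]:
    """Read a two-column protein TAB compartment TSV into a total mapping."""
    vocab = set(vocabulary)
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields")
        protein, label = fields
        if label not in vocab:
            raise FormatError(f"{path}:{lineno}: unknown compartment {label!r}")
        if protein in out and out[protein] != label:
            raise FormatError(
                f"{path}:{lineno}: conflicting labels for {protein!r} "
                f"({out[protein]!r} vs {label!r})")
        out[protein] = label
    return out


def write_compartments(compartments: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{p}\t{compartments[p]}" for p in sorted(compartments)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def write_edges(network: ScoredNetwork, path: str | Path,
                kept: bool = True) -> None:
    """Write a 4-column edge TSV (protein_a, protein_b, score, kept_flag)."""
    lines = ["protein_a\tprotein_b\tscore\tkept"]
    for (a, b) in sorted(network.edges):
        s = network.edges[(a, b)]
        lines.append(f"{a}\t{b}\t{FLOAT_FMT % s}\t{int(kept)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges(path: str | Path, genotype: str = "", extract: str = "",
               threshold: float = 0.0) -> ScoredNetwork:
    edges: dict[tuple[str, str], float] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        a, b, score, kept = fields
        if int(kept):
            key = canonical_pair(a, b)
            if key in edges:
                raise FormatError(f"{path}:{lineno}: duplicate edge {key}")
            edges[key] = float(score)
    return ScoredNetwork(edges, threshold=threshold, genotype=genotype,
                         extract=extract)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(report: Mapping, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(report)
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_jsonable) + "\n")


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
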