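"""Readers and writers for every on-disk artifact, with strict validation.

Canonical tabular dialect is TSV (UTF-8). Gene identifiers are opaque strings;
no identifier translation is attempted. Gene sets travel as GMT (one set per
line: name, description, members...), term hierarchies as two-column
parent->child TSV edge lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SEXES = ("F", "M")
VALID_DIETS = ("C", "P")


class FormatError(ValueError):
    """Malformed on-disk artifact (bad counts, bad GMT line, duplicate ids)."""


class ConsistencyError(ValueError):
    """Counts and metadata disagree (missing/extra samples, bad factor levels)."""


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with sample metadata.

    ``counts`` is genes x samples; ``samples`` is indexed by sample id with
    columns ``sex`` (F/M), ``diet`` (C/P) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise FormatError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        if set(c.columns) != set(self.samples.index):
            missing = set(c.columns) ^ set(self.samples.index)
            raise ConsistencyError(
                f"counts/metadata sample mismatch: {sorted(missing)[:5]}"
            )
        if self.samples.index.duplicated().any():
            raise ConsistencyError("duplicate sample ids in metadata")
        for col in ("sex", "diet"):
            if col not in self.samples.columns:
                raise ConsistencyError(f"metadata lacks required column {col!r}")
        bad_sex = set(self.samples["sex"]) - set(VALID_SEXES)
        bad_diet = set(self.samples["diet"]) - set(VALID_DIETS)
        if bad_sex:
            raise ConsistencyError(f"invalid sex levels {bad_sex}; expected F/M")
        if bad_diet:
            raise ConsistencyError(f"invalid diet levels {bad_diet}; expected C/P")
        # harmonize sample order: metadata follows count columns
        self.samples = self.samples.loc[list(c.columns)]
        self.counts.index.name = "gene"
        self.samples.index.name = "sample"

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples.copy())

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.samples.loc[samples])

    def subset_sex(self, sex: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["sex"] == sex]
        return self.subset_samples(keep)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class TermHierarchy:
    """Directed acyclic parent->child edges over term names."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self._children: dict[str, set[str]] = {}
        for parent, child in self.edges:
            self._children.setdefault(parent, set()).add(child)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if seen.get(node) == 1:
                return
            if node in stack:
                raise FormatError(f"hierarchy contains a cycle through {node!r}")
            for ch in self._children.get(node, ()):
                visit(ch, stack + (node,))
            seen[node] = 1

        for parent in list(self._children):
            visit(parent, ())

    def children(self, term: str) -> set[str]:
        return set(self._children.get(term, set()))

    def descendants(self, term: str) -> set[str]:
        """All strict descendants of ``term`` (transitive closure)."""
        out: set[str] = set()
        frontier = [term]
        while frontier:
            node = frontier.pop()
            for ch in self._children.get(node, ()):
                if ch not in out:
                    out.add(ch)
                    frontier.append(ch)
        return out

    def terms(self) -> set[str]:
        out = set()
        for p, c in self.edges:
            out.add(p)
            out.add(c)
        return out


# ---------------------------------------------------------------------------
# readers


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Read a gene x sample count TSV and a sample metadata TSV.

    The counts file has gene ids in the first column; the metadata file has
    columns ``sample``, ``sex``, ``diet``, ``replicate``. Sample order is
    harmonized; malformed values raise rather than coerce.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, dtype={0: str})
    for col in counts.columns:
        vals = counts[col]
        if vals.isna().any():
            raise FormatError(f"missing count values in sample {col!r}")
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError(f"non-numeric counts in sample {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise FormatError("metadata must have a 'sample' column")
    meta = meta.set_index("sample")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample").to_csv(metadata_path, sep="\t")


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r}")
            uniq = set(members)
            if len(uniq) < len(members):
                logger.warning(
                    "gene set %s: removed %d duplicate members",
                    name,
                    len(members) - len(uniq),
                )
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_hierarchy(path) -> TermHierarchy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError("hierarchy TSV must have exactly two columns")
    edges = [(str(p), str(c)) for p, c in df.itertuples(index=False)]
    return TermHierarchy(edges)


def write_hierarchy(hierarchy: TermHierarchy, path) -> None:
    df = pd.DataFrame(hierarchy.edges, columns=["parent", "child"])
    df.to_csv(path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir, params: dict | None = None,
                  seeds: dict | None = None) -> pd.DataFrame:
    """Write one TSV per result table plus a run manifest.

    Returns the manifest DataFrame (name, file, n_rows) also written to
    ``manifest.tsv``; parameters and seeds are recorded in ``manifest.tsv`` as
    extra key=value rows of a companion ``run_info.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False)
        rows.append({"name": name, "file": fname, "n_rows": len(table)})
    manifest = pd.DataFrame(rows, columns=["name", "file", "n_rows"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    info_rows = []
    for key, val in (params or {}).items():
        info_rows.append({"kind": "param", "key": key, "value": repr(val)})
    for key, val in (seeds or {}).items():
        info_rows.append({"kind": "seed", "key": key, "value": repr(val)})
    pd.DataFrame(info_rows, columns=["kind", "key", "value"]).to_csv(
        out_dir / "run_info.tsv", sep="\t", index=False
    )
    return manifest
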