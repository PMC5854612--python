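"""Domain containers and plain-text readers/writers.

The framework exchanges three kinds of files:

* gene sets / modules — GMT (``name<TAB>description<TAB>gene...``),
* regulatory networks — TSV edge lists (``regulator<TAB>target[<TAB>weight]``),
* expression matrices — TSV with sample ids on the first row and gene ids in
  the first column.

All writers emit LF line endings and preserve input order, so every
``write -> read`` round trip reproduces the in-memory object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Module",
    "ModuleSet",
    "RegulatoryNetwork",
    "ExpressionMatrix",
    "MembershipMatrix",
    "read_modules",
    "write_modules",
    "read_network",
    "write_network",
    "read_expression",
    "write_expression",
    "filter_low_variance",
    "threshold_memberships",
]


def _check_gene(token: str) -> str:
    if not token or "\t" in token or "\n" in token:
        raise ValueError(f"invalid gene id {token!r}: must be non-empty, no tab/newline")
    return token


@dataclass(frozen=True)
class Module:
    """A named gene set. Genes are an unordered set; equality is exact-string."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"module {self.name!r} is empty")
        for g in self.genes:
            _check_gene(g)

    def __len__(self) -> int:
        return len(self.genes)


class ModuleSet:
    """An ordered collection of named, possibly overlapping gene sets.

    Modules may overlap and need not cover every gene (non-exhaustive
    detectors leave genes unassigned). An optional ``universe`` records the
    full gene background the modules were drawn from.
    """

    def __init__(self, modules: Iterable, universe: Iterable | None = None):
        mods = []
        for m in modules:
            if not isinstance(m, Module):
                name, genes = m
                m = Module(str(name), frozenset(genes))
            mods.append(m)
        names = [m.name for m in mods]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate module names: {dup}")
        self.modules: list = mods
        self.universe = frozenset(universe) if universe is not None else None

    @property
    def names(self) -> list:
        return [m.name for m in self.modules]

    @property
    def genes(self) -> frozenset:
        """Union of all module genes."""
        out: set = set()
        for m in self.modules:
            out |= m.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def __getitem__(self, key):
        if isinstance(key, str):
            for m in self.modules:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.modules[key]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return self.modules == other.modules

    def __repr__(self) -> str:
        return f"ModuleSet({len(self.modules)} modules, {len(self.genes)} genes)"

    def as_sets(self) -> list:
        return [m.genes for m in self.modules]

    def indicator(self, gene_order: Sequence) -> np.ndarray:
        """Boolean genes x modules membership matrix in the given gene order."""
        index = {g: i for i, g in enumerate(gene_order)}
        out = np.zeros((len(gene_order), len(self.modules)), dtype=bool)
        for j, m in enumerate(self.modules):
            for g in m.genes:
                if g in index:
                    out[index[g], j] = True
        return out


@dataclass
class RegulatoryNetwork:
    """Directed regulator -> target edges with optional finite weights.

    ``edges`` maps (regulator, target) to a weight or ``None`` (unweighted
    edge). Duplicate pairs are impossible by construction; self-edges are kept
    but listed under :attr:`self_edges`.
    """

    edges: dict = field(default_factory=dict)

    def __post_init__(self):
        for (r, t), w in self.edges.items():
            _check_gene(r)
            _check_gene(t)
            if w is not None and not math.isfinite(w):
                raise ValueError(f"non-finite weight on edge {r}->{t}")

    @property
    def regulators(self) -> frozenset:
        return frozenset(r for r, _ in self.edges)

    @property
    def targets(self) -> frozenset:
        return frozenset(t for _, t in self.edges)

    @property
    def nodes(self) -> frozenset:
        return self.regulators | self.targets

    @property
    def self_edges(self) -> list:
        return sorted((r, t) for r, t in self.edges if r == t)

    @property
    def is_weighted(self) -> bool:
        return bool(self.edges) and all(w is not None for w in self.edges.values())

    def __len__(self) -> int:
        return len(self.edges)

    def regulons(self) -> dict:
        """Regulator -> set of its targets."""
        out: dict = {}
        for r, t in self.edges:
            out.setdefault(r, set()).add(t)
        return out


class ExpressionMatrix:
    """Genes x samples real-valued matrix backed by a pandas DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if frame.columns.duplicated().any():
            dup = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {frame.index[i]!r}, "
                f"sample {frame.columns[j]!r}"
            )
        self._frame = frame.astype(float)

    @classmethod
    def from_arrays(cls, genes: Sequence, samples: Sequence, values) -> "ExpressionMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=list(genes), columns=list(samples)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> list:
        return self._frame.index.tolist()

    @property
    def samples(self) -> list:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def shape(self) -> tuple:
        return self._frame.shape

    def subset_genes(self, genes: Iterable) -> "ExpressionMatrix":
        genes = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self._frame.loc[genes])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


class MembershipMatrix:
    """Genes x modules matrix of non-negative membership strengths.

    Produced by fuzzy module detectors; converted to crisp (but possibly
    overlapping) modules with :func:`threshold_memberships`.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("membership values must be finite")
        if (values < 0).any():
            raise ValueError("membership values must be non-negative")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list:
        return self.frame.index.tolist()

    @property
    def module_names(self) -> list:
        return self.frame.columns.tolist()


# ---------------------------------------------------------------------------
# Readers / writers


def read_modules(path) -> ModuleSet:
    """Read a GMT file (one module per line: name, description, genes...).

    Duplicate genes within a line are dropped; duplicate module names are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"module file not found: {path}")
    modules = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene (got {len(fields)} fields)"
                )
            name, _desc, genes = fields[0], fields[1], fields[2:]
            modules.append((name, frozenset(genes)))
    return ModuleSet(modules)


def write_modules(ms: ModuleSet, path) -> None:
    """Write a ModuleSet as GMT; the description field is written as 'na'."""
    with Path(path).open("w", newline="\n") as fh:
        for m in ms:
            fh.write("\t".join([m.name, "na", *sorted(m.genes)]) + "\n")


def read_network(path) -> RegulatoryNetwork:
    """Read a TSV edge list (regulator, target[, weight]).

    Lines starting with '#' are comments/headers. Duplicate (regulator,
    target) pairs collapse to the maximum weight.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    edges: dict = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(fields)}"
                )
            r, t = fields[0], fields[1]
            w = None
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}")
                if not math.isfinite(w):
                    raise ValueError(f"{path}:{lineno}: non-finite weight")
            key = (r, t)
            if key in edges:
                old = edges[key]
                if w is not None and (old is None or w > old):
                    edges[key] = w
            else:
                edges[key] = w
    return RegulatoryNetwork(edges)


def write_network(net: RegulatoryNetwork, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("#regulator\ttarget\tweight\n" if net.is_weighted else "#regulator\ttarget\n")
        for (r, t), w in net.edges.items():
            if w is None:
                fh.write(f"{r}\t{t}\n")
            else:
                fh.write(f"{r}\t{t}\t{w!r}\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column gene ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    bad = frame.map(lambda v: not isinstance(v, (int, float)) or not math.isfinite(float(v)))
    # pd.read_csv leaves non-numeric columns as object; locate the offender
    if frame.select_dtypes(exclude="number").shape[1] or bad.to_numpy().any():
        arr = bad.to_numpy()
        if arr.any():
            i, j = np.argwhere(arr)[0]
            raise ValueError(
                f"non-numeric expression value {frame.iloc[i, j]!r} at gene "
                f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
            )
    return ExpressionMatrix(frame)


def write_expression(expr: ExpressionMatrix, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        expr.frame.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


# ---------------------------------------------------------------------------
# Generic filtering / post-processing


def filter_low_variance(expr: ExpressionMatrix, min_sd: float) -> ExpressionMatrix:
    """Keep genes whose sample standard deviation (ddof=1) is >= ``min_sd``.

    Mirrors the common pre-filter of expression compendia (e.g. a minimal
    standard deviation of 0.5) that removes flat, uninformative genes before
    module detection.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be non-negative")
    sds = expr.frame.std(axis=1, ddof=1)
    keep = sds[sds >= min_sd].index
    if len(keep) == 0:
        raise ValueError(
            f"no gene has sd >= {min_sd}; lower the threshold (max observed sd "
            f"{sds.max():.4g})"
        )
    return ExpressionMatrix(expr.frame.loc[keep])


def threshold_memberships(mm: MembershipMatrix, cutoff: float) -> ModuleSet:
    """Crisp modules from a fuzzy membership matrix: gene in module iff
    membership >= cutoff. Empty modules are dropped; overlap is expected."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    modules = []
    values = mm.frame.to_numpy()
    genes = np.asarray(mm.genes, dtype=object)
    for j, name in enumerate(mm.module_names):
        members = genes[values[:, j] >= cutoff]
        if len(members):
            modules.append((str(name), frozenset(members)))
    return ModuleSet(modules)
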