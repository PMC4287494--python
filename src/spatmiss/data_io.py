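"""Areal data containers, file readers/writers and pre-model diagnostics.

The analysis operates on a set of contiguous administrative regions (an
areal lattice). Two inputs define a study: a region table holding the
outcome (case counts), population denominators and covariates, and an
adjacency structure saying which regions share a border. Missing covariate
cells are first-class citizens: they are tracked with an explicit boolean
mask and never encoded as magic numbers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the canonical region table.
COVARIATE_NAMES = ("ses", "over45", "overweight", "smokers", "inactive", "fruit", "veg")

#: Survey-derived covariates centred by default; the ordinal SES score is not.
DEFAULT_CENTER_SUBSET = ("over45", "overweight", "smokers", "inactive", "fruit", "veg")


class DataValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass(frozen=True)
class RegionLattice:
    """Symmetric adjacency structure over an ordered set of regions.

    ``neighbors[i]`` is the set of 0-based indices adjacent to region ``i``
    and ``m[i] = |neighbors[i]|`` is the neighbour count that scales the
    conditional variance of intrinsic CAR fields. Island regions (``m == 0``)
    are rejected at construction: an island has no neighbourhood to borrow
    strength from, so it cannot participate in a CAR model.
    """

    region_ids: tuple[str, ...]
    neighbors: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise DataValidationError("duplicate region ids in lattice")
        if len(self.neighbors) != n:
            raise DataValidationError("neighbors length does not match region count")
        for i, nbr in enumerate(self.neighbors):
            if i in nbr:
                raise DataValidationError(f"region {self.region_ids[i]} is its own neighbour")
            if not nbr:
                raise DataValidationError(
                    f"region {self.region_ids[i]} has no neighbours (islands are excluded "
                    "from CAR analysis; remove it or supply its adjacency)"
                )
            for k in nbr:
                if not 0 <= k < n:
                    raise DataValidationError(f"neighbour index {k} out of range")
                if i not in self.neighbors[k]:
                    raise DataValidationError(
                        f"adjacency not symmetric: {self.region_ids[i]} -> {self.region_ids[k]}"
                    )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def m(self) -> np.ndarray:
        """Per-region neighbour counts."""
        return np.array([len(nbr) for nbr in self.neighbors], dtype=int)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix W."""
        n = self.n_regions
        W = np.zeros((n, n))
        for i, nbr in enumerate(self.neighbors):
            for k in nbr:
                W[i, k] = 1.0
        return W

    def icar_precision(self) -> np.ndarray:
        """Unit-variance intrinsic CAR precision matrix ``diag(m) - W``.

        Singular with null vector 1 on a connected graph; all CAR machinery
        works either on the sum-to-zero subspace or conditionally on
        observed components.
        """
        return np.diag(self.m.astype(float)) - self.adjacency_matrix()

    def is_connected(self) -> bool:
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for k in self.neighbors[i]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == self.n_regions

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges as (i, k) with i < k."""
        return [
            (i, k)
            for i, nbr in enumerate(self.neighbors)
            for k in sorted(nbr)
            if i < k
        ]

    @classmethod
    def from_edges(
        cls, region_ids: "list[str] | tuple[str, ...]", edges: "list[tuple[str, str]]"
    ) -> "RegionLattice":
        index = {r: i for i, r in enumerate(region_ids)}
        nbr: list[set[int]] = [set() for _ in region_ids]
        for a, b in edges:
            if a not in index or b not in index:
                unknown = a if a not in index else b
                raise DataValidationError(f"edge references unknown region {unknown!r}")
            i, k = index[a], index[b]
            if i == k:
                raise DataValidationError(f"self-edge on region {a!r}")
            nbr[i].add(k)
            nbr[k].add(i)
        return cls(tuple(region_ids), tuple(frozenset(s) for s in nbr))


@dataclass
class RegionDataset:
    """Outcome, denominators and covariates for every region on a lattice.

    ``X`` carries ``nan`` at missing cells and ``mask`` is True exactly
    there; arithmetic on covariates must always consult the mask. ``Y`` may
    also carry ``nan`` where the outcome was not reported. ``E`` (expected
    counts under internal standardisation) exists only after
    :func:`spatmiss.model.expected_counts` has been applied.
    """

    region_ids: tuple[str, ...]
    Y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    mask: np.ndarray
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    lattice: "RegionLattice | None" = None
    E: "np.ndarray | None" = None
    centered: "np.ndarray | None" = None
    center_offsets: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.n = np.asarray(self.n)
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        p = len(self.covariate_names)
        N = len(self.region_ids)
        if len(set(self.region_ids)) != N:
            dupes = {r for r in self.region_ids if list(self.region_ids).count(r) > 1}
            raise DataValidationError(f"duplicate region id(s): {sorted(dupes)}")
        if self.X.shape != (N, p) or self.mask.shape != (N, p):
            raise DataValidationError("X/mask shape does not match regions x covariates")
        if np.any(self.n <= 0):
            bad = int(np.argmax(self.n <= 0))
            raise DataValidationError(
                f"non-positive population in row {bad} (region {self.region_ids[bad]})"
            )
        obs = ~np.isnan(self.Y)
        if np.any(self.Y[obs] < 0):
            raise DataValidationError("negative case count")
        if not np.array_equal(np.isnan(self.X), self.mask):
            raise DataValidationError("mask must be True exactly at unset X cells")
        if self.lattice is not None and self.lattice.n_regions != N:
            raise DataValidationError("lattice size does not match dataset")
        if self.centered is None:
            self.centered = np.zeros(p, dtype=bool)
        if self.center_offsets is None:
            self.center_offsets = np.zeros(p)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def copy(self) -> "RegionDataset":
        return RegionDataset(
            region_ids=self.region_ids,
            Y=self.Y.copy(),
            n=self.n.copy(),
            X=self.X.copy(),
            mask=self.mask.copy(),
            covariate_names=self.covariate_names,
            lattice=self.lattice,
            E=None if self.E is None else self.E.copy(),
            centered=self.centered.copy(),
            center_offsets=self.center_offsets.copy(),
        )

    def covariate_index(self, name: str) -> int:
        try:
            return self.covariate_names.index(name)
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"region_id": self.region_ids})
        df["population"] = self.n
        df["cases"] = self.Y
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations between covariates on observed data.

    ``pairs`` holds one record per unordered covariate pair with ``r`` =
    Pearson correlation over pairwise-complete observations (``None`` when
    fewer than 3 complete pairs exist). The screen flags how many pairs
    exceed the threshold in absolute value — a gauge of how much a
    multivariate imputation model has to work with.
    """

    pairs: tuple[tuple[str, str, "float | None"], ...]
    threshold: float
    min_pairs: int = 3

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_above_threshold(self) -> int:
        return sum(1 for _, _, r in self.pairs if r is not None and abs(r) > self.threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["covariate_a", "covariate_b", "r"])

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "threshold": self.threshold,
            "n_above_threshold": self.n_above_threshold,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary())


# ---------------------------------------------------------------------------
# readers / writers


def read_region_table(path) -> RegionDataset:
    """Read the canonical region-table CSV.

    Expected header: ``region_id,population,cases,<covariates...>``. Empty
    cells and the token ``NA`` denote missing values; populations must be
    positive and counts non-negative. Row order in the file is canonical and
    preserved.
    """
    df = pd.read_csv(
        path,
        dtype={"region_id": str},
        na_values=["NA"],
        keep_default_na=True,
        float_precision="round_trip",
    )
    required = {"region_id", "population", "cases"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"region table must contain columns {sorted(required)}")
    cov_cols = tuple(c for c in df.columns if c not in required)
    if df["population"].isna().any():
        row = int(df["population"].isna().idxmax())
        raise DataValidationError(f"missing population in row {row}")
    X = df[list(cov_cols)].to_numpy(dtype=float)
    return RegionDataset(
        region_ids=tuple(df["region_id"]),
        Y=df["cases"].to_numpy(dtype=float),
        n=df["population"].to_numpy(),
        X=X,
        mask=np.isnan(X),
        covariate_names=cov_cols,
    )


def write_region_table(data: RegionDataset, path) -> None:
    """Write a dataset back to the canonical CSV (missing cells left empty).

    Floats use shortest round-trip representation so a write/read cycle
    reproduces values bit-exactly.
    """
    data.to_frame().to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_adjacency(path, region_ids) -> RegionLattice:
    """Read an adjacency file as an edge list or a GAL-style neighbour file.

    Edge-list format: one ``a b`` pair of region labels per line; symmetric
    closure is applied. GAL format: a header line with the region count,
    then per region a ``label count`` line followed by a line of neighbour
    labels. All labels must appear in ``region_ids``; the returned lattice
    follows the order of ``region_ids``, not the file.
    """
    region_ids = tuple(str(r) for r in region_ids)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise DataValidationError("empty adjacency file")
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        return _read_gal(lines, region_ids)
    edges = []
    for ln in lines:
        parts = ln.split()
        if len(parts) != 2:
            raise DataValidationError(f"malformed edge line: {ln!r}")
        edges.append((parts[0], parts[1]))
    return RegionLattice.from_edges(region_ids, edges)


def _read_gal(lines: list[str], region_ids: tuple[str, ...]) -> RegionLattice:
    declared = int(lines[0].split()[0])
    edges = []
    i = 1
    seen = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise DataValidationError(f"malformed GAL region header: {lines[i]!r}")
        label, count = head[0], int(head[1])
        if count > 0:
            if i + 1 >= len(lines):
                raise DataValidationError(f"GAL file truncated after region {label!r}")
            nbrs = lines[i + 1].split()
            if len(nbrs) != count:
                raise DataValidationError(
                    f"region {label!r} declares {count} neighbours but lists {len(nbrs)}"
                )
            edges.extend((label, b) for b in nbrs)
            i += 2
        else:
            i += 1
        seen += 1
    if seen != declared:
        raise DataValidationError(f"GAL header declares {declared} regions, found {seen}")
    return RegionLattice.from_edges(region_ids, edges)


def write_adjacency(lattice: RegionLattice, path) -> None:
    """Write the lattice as a plain edge list of region labels."""
    with open(path, "w") as fh:
        for i, k in lattice.edge_list():
            fh.write(f"{lattice.region_ids[i]} {lattice.region_ids[k]}\n")


# ---------------------------------------------------------------------------
# pre-model diagnostics


def center_covariates(
    data: RegionDataset, which: "tuple[str, ...] | None" = None
) -> RegionDataset:
    """Centre selected covariates about their observed mean.

    Centring improves mixing of the intercept and coefficient samplers.
    The default subset is the six survey/age covariates; the ordinal SES
    score is left on its native 1-10 scale (pass it in ``which`` to centre
    it too). Missing cells and the mask are untouched; offsets are stored so
    reports can be back-transformed. Idempotent: centring twice equals
    centring once.
    """
    if which is None:
        which = tuple(c for c in DEFAULT_CENTER_SUBSET if c in data.covariate_names)
    out = data.copy()
    for name in which:
        j = out.covariate_index(name)
        if out.centered[j]:
            continue  # exact idempotence: re-centring would add rounding noise
        obs = ~out.mask[:, j]
        if not obs.any():
            raise DataValidationError(f"covariate {name!r} has no observed entries to centre")
        mu = out.X[obs, j].mean()
        out.X[obs, j] -= mu
        out.center_offsets[j] += mu
        out.centered[j] = True
    return out


def pearson_correlation_screen(data: RegionDataset, threshold: float = 0.2) -> CorrelationReport:
    """Pairwise-complete Pearson correlations between all covariate pairs.

    Runs on observed data (before any imputation). Pairs with fewer than 3
    pairwise-complete observations are reported with ``r = None``.
    """
    p = data.n_covariates
    records = []
    for a, b in itertools.combinations(range(p), 2):
        both = ~data.mask[:, a] & ~data.mask[:, b]
        if both.sum() < 3:
            r = None
        else:
            x, y = data.X[both, a], data.X[both, b]
            with np.errstate(invalid="ignore"):
                r_mat = np.corrcoef(x, y)
            r = float(r_mat[0, 1])
            if np.isnan(r):
                r = None  # zero-variance column on the complete subset
        records.append((data.covariate_names[a], data.covariate_names[b], r))
    return CorrelationReport(pairs=tuple(records), threshold=threshold)
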